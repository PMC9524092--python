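"""Theme proportions and the attack-description subcorpus.

Computes per-text theme proportions from the sentence-level annotations and
prints the per-group medians (the generator targets ~30% attack
description, ~17% treatment).  Then extracts the attack-description
subcorpus: 112 of the 121 records carry that theme, mirroring the corpus
reduction the classifier works on.
"""

import headache_nlp as h

corpus, annotations, _ = h.generate_corpus(h.GeneratorConfig(seed=17))
docs = h.tokenize_corpus(corpus)

props = [h.theme_proportions(docs[rid], annotations[rid]) for rid in docs]
table = h.summarize_themes(props, corpus.labels())
print((100 * table[["full_cohort_median", "full_cohort_q1",
                    "full_cohort_q3"]]).round(1))

attacks = h.extract_theme_subcorpus(corpus, annotations, docs,
                                    "attack_description")
print(f"\nattack-description subcorpus: {len(attacks)} of {len(corpus)} "
      f"records ({attacks.label_counts})")
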