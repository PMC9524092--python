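"""Chi-square keyness: which words distinguish cluster headache narratives.

Preprocesses the synthetic corpus (blocklist + stop-word filtering), builds
the per-type frequency table and prints the top keyness rows.  The injected
class keywords (oog, pijn, terug, ... vs hoofdpijn, stress, ...) should
dominate the ranking with tier *** — each row shows the 2x2 counts, the
Yates-corrected chi-square and the significance tier.
"""

import headache_nlp as h

corpus, _, _ = h.generate_corpus(h.GeneratorConfig(seed=17))
docs = h.preprocess_corpus(
    corpus, blocklist=h.default_blocklist(), stopwords=h.default_stopwords()
)
labels = corpus.labels()
table = h.build_frequency_table(
    [d for rid, d in docs.items() if labels[rid] == "cluster_headache"],
    [d for rid, d in docs.items() if labels[rid] == "migraine"],
)
print(f"{'word':<16}{'a':>6}{'b':>6}{'chi2':>10}  dir        tier")
for row in h.rank_keywords(table, min_count=5)[:12]:
    print(
        f"{row.word:<16}{row.a:>6}{row.b:>6}{row.chi2:>10.1f}  "
        f"{row.direction:<9}  {row.tier}"
    )
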