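"""Lexicon-cascade sentiment scoring of the narratives.

Builds the four-lexicon cascade from the generated fixtures (first match
wins, valences normalised to [-1, +1]), scores every narrative as the plain
sum of matched token valences (stop words retained, label mentions removed)
and prints the per-group polarity split — by construction ~90% of
documents carry net negative sentiment.
"""

import headache_nlp as h

config = h.GeneratorConfig(seed=17)
corpus, _, _ = h.generate_corpus(config)
cascade = h.LexiconCascade.from_lexicons(h.generate_lexicon_fixtures(config))
print("cascade order:", " -> ".join(cascade.names))

docs = h.preprocess_corpus(corpus, blocklist=h.default_blocklist(),
                           stopwords=None)
results = h.score_corpus(docs, cascade)
one = results[0]
print(f"example: {one.record_id} score {one.score:+.2f} "
      f"({one.n_matched} matched tokens) -> {one.polarity}")

print(h.polarity_distribution(results, corpus.labels()).round(1))
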