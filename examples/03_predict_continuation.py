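"""Predict the next tone of an excerpt with both models and score it.

Both predictors rank the same 25 candidates (±12 semitones around the
last heard pitch); the pattern model scores candidates by the best
match-relevance weight, the adjusted expectancy model by the mean of five
normalised Implication-Realization criteria.
"""

import numpy as np

from melex import (
    GeneratorConfig,
    adjusted_ir_predict,
    generate_corpus,
    generate_fixture_excerpts,
    learn_hierarchy,
    predict_chm,
    reciprocal_rank,
)
from melex.synth import CorpusManifest
from melex.tonality import resolve_context

config = GeneratorConfig(scale="major", n_songs=100, seed=7)
corpus, manifest = generate_corpus(config)
model = learn_hierarchy(corpus[:80])

held = CorpusManifest(config=config, songs=manifest.songs[80:])
excerpt = generate_fixture_excerpts(corpus[80:], held, np.random.default_rng(1), n=4)[0]

print(f"excerpt ({excerpt.completeness}): {excerpt.melody.pitches}")
print(f"true continuation: {excerpt.true_continuation}")

for name, prediction in [
    ("pattern model", predict_chm(model, excerpt)),
    ("adjusted expectancy model", adjusted_ir_predict(excerpt, resolve_context(excerpt.melody))),
]:
    rr = reciprocal_rank(prediction, excerpt.true_continuation)
    top3 = [(p, round(prediction.candidates[p], 3)) for p in prediction.ranking[:3]]
    print(f"\n{name}: top candidates {top3}")
    print(f"  truth ranked {prediction.rank_of(excerpt.true_continuation)} "
          f"(reciprocal rank {rr:.3f})")

# A reciprocal rank of 1.0 means the model's top candidate is the actual
# next tone; 1/n means the truth sat at rank n of the 25-candidate window.
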