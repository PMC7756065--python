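"""Cross-training grid: does scale-matched training help the pattern model?

Two corpora are generated — diatonic major and anhemitonic pentatonic —
and the pattern model is trained on each and tested on excerpts of both.
The expectancy model needs no training, so it serves as the
culture-agnostic reference.
"""

from melex import GeneratorConfig, RunConfig, run

config = RunConfig(
    corpus=GeneratorConfig(scale="major", n_songs=100, seed=11),
    corpus_b=GeneratorConfig(scale="pentatonic", tonic=10, n_songs=100, seed=12),
    model="chm",
    n_excerpts=20,
    seed=42,
)
reports = run(config)
for key in ("a/a", "a/b", "b/a", "b/b"):
    train, test = key.split("/")
    print(f"\ntrain {train} / test {test}  "
          f"(a = major corpus, b = pentatonic corpus)")
    print(reports[key].format_table())

print(
    "\nThe diagonal (matched training) should beat the off-diagonal on "
    "strict accuracy and MRR: patterns learned from the same scale system "
    "transfer; foreign ones rarely match."
)
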