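"""Learn a compositional hierarchy of melodic patterns from a corpus.

Patterns are relatively encoded (semitone offsets from their first
event), so one pattern covers all its transpositions; each is matched as
a gapped regular expression.
"""

from melex import GeneratorConfig, generate_corpus, learn_hierarchy, pattern_to_regex

config = GeneratorConfig(scale="major", n_songs=100, seed=7)
corpus, manifest = generate_corpus(config)
model = learn_hierarchy(corpus)

print(f"learned {len(model.patterns)} patterns over {model.n_layers} layers")
print("\nmost supported patterns:")
for pattern in sorted(model.patterns, key=lambda p: -p.support)[:5]:
    print(f"  offsets {pattern.offsets}  support {pattern.support}  layer {pattern.layer}")

motif = config.motif_bank[0]
found = [p for p in model.patterns if p.offsets == motif]
print(f"\nplanted motif {motif}: "
      + (f"recovered with support {found[0].support}" if found else "not recovered exactly"))
print(f"its gapped regex: {pattern_to_regex(found[0]) if found else '-'}")

# Support counts occurrences across the corpus; the planted motif should
# appear with support comparable to the number of manifest plantings.
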