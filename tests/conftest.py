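import numpy as np
import pytest

from melex import GeneratorConfig, Melody, NoteEvent, generate_corpus


def make_melody(pitches, durations=None, melody_id="m", phrase_ends=None, tempo=100.0):
    durations = durations or [1.0] * len(pitches)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    events = [
        NoteEvent(onset=float(o), pitch=int(p), duration=float(d))
        for o, p, d in zip(onsets, pitches, durations)
    ]
    return Melody(id=melody_id, events=events, phrase_ends=phrase_ends, tempo=tempo)


@pytest.fixture(scope="session")
def major_corpus():
    """A small seeded diatonic corpus with its ground-truth manifest."""
    config = GeneratorConfig(scale="major", n_songs=30, seed=2024)
    corpus, manifest = generate_corpus(config)
    return config, corpus, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
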