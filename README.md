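# melex

Symbolic melody-continuation prediction for monophonic folk melodies:
given a truncated melody, rank the 25 candidate pitches within ±12
semitones of the last heard tone and judge the ranking against the true
continuation. The package is aimed at computational music-cognition work
that compares *learned familiarity* (a corpus-trained pattern model)
against *built-in expertise* (a rule-based melodic-expectancy model) on
the same footing.

## What it implements

**Pattern model (compositional hierarchy).** From a training corpus the
learner builds layers of relatively-encoded melodic patterns: layer 1 is
the single-event leaf; each next layer joins pairs of part occurrences
that co-occur at a fixed pitch offset within a bounded event gap,
keeping compositions with support ≥ `min_support` and inhibiting parts
whose occurrences a longer retained part already covers. A pattern with
offsets `{0, 5, −3, 0}` becomes the gapped regular expression

```
0[0a-zA-Z]*E[0a-zA-Z]*c[0a-zA-Z]*0
```

(offset 0 → `0`, +k → k-th upper-case letter, −k → k-th lower-case
letter; `[0a-zA-Z]*` absorbs interpolated events). Matching all but the
final pattern event against an excerpt yields a predicted pitch with
relevance weight

```
w = N_events / (L − a + 1)
```

where `N_events` is the pattern length (continuation slot included), `L`
the excerpt length plus the prediction slot, and `a` the 0-based anchor
of the match — longer patterns and matches nearer the excerpt's end
weigh more.

**Expectancy model (Implication-Realization).** Candidates are scored
from the implicative interval i (penultimate → last tone) and the
realized interval r (last tone → candidate). The five original
bottom-up criteria (registral direction, registral return, intervallic
difference, proximity, closure) plus five extensions (consonance,
tonality from the Krumhansl probe-tone profiles, melodic attraction,
tessitura, mobility) are implemented; the *adjusted* predictor averages
the min–max-normalised registral return, proximity, tonality, melodic
attraction and tessitura.

**Evaluation.** Strict correctness is exact pitch; relaxed correctness
is membership of the candidate's pitch class in the excerpt's tonal
hierarchy — 7 admissible classes in major, 9 in minor (natural minor
plus raised 6̂/7̂), 5 in anhemitonic pentatonic. Rankings are summarised
by the mean reciprocal rank, MRR = (1/|Q|) Σ 1/rankᵢ. Chance baselines:
4% for a uniform guess over the window, 100/15 ≈ 6.7% (major window) and
100/11 ≈ 9.1% (pentatonic window) for uniform guessing over in-scale
candidates.

**Synthetic corpora.** A seeded generator emulates short folk phrases
(≈15 events per phrase, tonal range ≈12 semitones, mostly stepwise
motion, cadences on tonic/dominant) with repeated motifs planted at
manifest-recorded positions, so training, key estimation and evaluation
are all testable against exact ground truth without external data.

## Worked example

```
python examples/03_predict_continuation.py
```

prints, for one held-out complete excerpt of a 100-song seeded major
corpus:

```
excerpt (complete): [60, 67, 65, 64, 62, 60, 64, 67, 67, 65, 60, 60, 67, 65, 64, 62, 60, 60, 67, 65, 64, 62, 60]
true continuation: 60

pattern model: top candidates [(60, 0.889), (64, 0.875), (67, 0.875)]
  truth ranked 1 (reciprocal rank 1.000)

adjusted expectancy model: top candidates [(60, 0.95), (62, 0.594), (64, 0.58)]
  truth ranked 1 (reciprocal rank 1.000)
```

Both models put the actual next tone (the tonic, 60) first; the pattern
model's score is the best match weight, the expectancy model's the mean
of its five normalised criteria. `examples/04_familiarity_grid.py` runs
the 2×2 cross-training grid (train/test on major vs pentatonic corpora)
and shows the familiarity effect: scale-matched training wins on strict
accuracy and MRR.

A thin CLI covers the same stages:

```
melex simulate --scale major --n-songs 100 --seed 7 --out-dir fixtures/
melex train --csv-dir fixtures/ --out model.json
melex make-excerpts --csv-dir fixtures/ --n 20 --seed 3 --out dataset.jsonl
melex predict --model model.json --excerpts dataset.jsonl --out preds.jsonl
melex evaluate --preds preds.jsonl --excerpts dataset.jsonl
melex key --csv fixtures/major-7-000.csv
melex convert --midi-in song.mid --csv-out song.csv
```

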