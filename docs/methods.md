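# Methods

This note documents the models, the numerical conventions, and the
design choices taken where the problem was genuinely open, together with
what the synthetic corpora do and do not establish.

## Data model

A melody is an ordered, monophonic sequence of note events `(onset,
pitch, duration)` with onsets and durations in beats (quarter note = 1).
Beats, not seconds, are the native unit because folk-song MIDI is
metrical and beat arithmetic is exact; an optional tempo (BPM) converts
to seconds where a wall-clock duration criterion needs it (default
100 BPM when unset). Event-list CSV uses the field order
`onset,pitch,duration`, comma-separated, no quoting, `.` decimals, with
an optional header tolerated on read; numbers are rendered losslessly so
write → read → write is byte-stable. The MIDI codec reads format 0/1
files with metrical division and writes format 0; note overlaps up to
1/64 beat are treated as sloppy note-offs and truncated, larger overlaps
are monophony errors naming the offending pair.

## Excerpts

A *complete* excerpt keeps events `0 .. e−1` where `e` is a phrase-final
index; the removed phrase-final tone is the prediction target. An
*incomplete* excerpt cuts at an index drawn uniformly from
`[min_len, final_phrase_end)` excluding phrase-final positions, so the
two classes are disjoint by construction. `min_len` defaults to 5: both
predictors need context, and realistic phrase material starts around 7
events. Datasets mix classes 75/25 and drop excerpts whose balance
criteria (event count, largest adjacent interval, tonal range, duration
in seconds) leave the mean ± 2·SD band; the SD is the population SD of
the pre-filter pool, and because statistics are frozen on that pool the
filter is idempotent on its own output.

## Tonal context

The major/minor probe-tone profiles ship as constants; key estimation
Pearson-correlates the duration-weighted pitch-class distribution with
all 24 rotations and takes the argmax (ties: higher fit, then major,
then lower tonic). Duration weighting is used because stable tones tend
to be held longer; melodies using a single pitch class have no defined
fit and require an explicit scale hint. Anhemitonic pentatonic contexts
are detected structurally (pitch-class-set inclusion in a rotation of
{0, 2, 4, 7, 9}; lowest fitting reference class wins) since no
pentatonic probe-tone profile exists; where a pentatonic tonality rating
is needed the major profile rotated to the reference stands in.
An annotated scale hint always overrides estimation — scale systems
belong to repertoires, not individual excerpts. Relaxed evaluation
admits 7 pitch classes in major, 9 in minor (natural minor plus the
raised 6th and 7th of the melodic/harmonic forms), 5 in pentatonic.

## Pattern model

Training is fully deterministic. Layer 1 holds the single-event leaf
part. Layer n+1 joins ordered pairs of existing part activations in the
same melody whose second anchor follows the first part's last matched
event by at most `max_gap` (default 2) intervening events, grouped by
(left part, right part, anchor pitch offset) and kept at support ≥
`min_support` (default 3). Activations are deduplicated to
(melody, anchor, end) spans: distinct internal gap assignments of the
same shape over the same span are one occurrence, which is what keeps
the search tractable. Two further controls bound growth:

* **Part selection** — at most `max_parts_per_layer` (default 200) new
  shapes are retained per layer, best-supported first (longer shapes win
  ties). Without it the number of gapped shape variants grows
  exponentially with depth; repeated planted material has far higher
  support than coincidental shapes, so selection keeps exactly the
  structure worth keeping.
* **Inhibition** — after each layer a part is removed when a retained
  strictly longer part covers ≥ 80% of the events its activations span,
  pruning patterns subsumed by their own extensions.

Layering stops at `max_layers` (default 5, pattern length ≤ 16 leaves)
or when no new shape reaches support. All surviving patterns vote at
prediction time.

Prediction encodes the excerpt suffix from every anchor as offsets from
the anchor pitch (0 → `0`, ±k → k-th upper/lower-case letter, range
±26) and matches each pattern's first k−1 symbols as an anchored gapped
regex whose trailing gap absorbs the remainder; a success predicts
`anchor_pitch + offsets[k−1]` with weight `k / (L − a + 1)`, `L` =
excerpt events + 1 (the prediction slot) and `a` the 0-based anchor.
This segment-length convention is the one that reproduces every printed
worked example of the formula simultaneously; the weight is provably
< 1 under it (a guard warns if a caller ever exceeds 1). Gap-stretched
matches are not separately penalised: a gap forces an earlier anchor,
which the denominator already punishes. Per candidate the maximum
weight over contributing matches is kept — weights are relevances of
individual pattern instances, not independent evidence to accumulate.
Candidates outside the ±12-semitone window are discarded; ranking is by
score, then smaller |interval from last pitch|, then lower pitch, making
every downstream rank statistic deterministic.

## Expectancy model

The five original criteria implement the prose thresholds exactly
(direction change implied above 8 semitones; registral return within 2
semitones of the implicative interval's first tone; the 2/3-semitone
slack of intervallic difference; graded proximity `max(0, 6 − |r|)`;
closure on reversal or a ≥3-semitone interval shrink), with `sign(0)`
treated as compatible with either direction (a repeated tone preserves
direction). The extensions use standard formulations: consonance for
unison/fourth/fifth/octave; tonality as the probe-tone rating of the
candidate's pitch class; melodic attraction as the anchoring-strength
ratio of candidate to last tone (basic-space levels: tonic 4, triad
tones 3, scale tones 2, others 1) damped by 1/max(1, |r|)²; tessitura as
negated distance from the median pitch in units of the (population) SD;
mobility as a lag-1-autocorrelation extrapolation of the pitch series
(provided for completeness; unused by the adjusted predictor). The
adjusted predictor min–max-normalises registral return, proximity,
tonality, melodic attraction and tessitura across the 25 candidates
(constant columns fall back to 0.5 so they carry no signal) and averages
them with equal weights — the normalisation and weighting were not
specified anywhere, so the simplest symmetric choice is used and frozen.
The unadjusted predictor does the same over the five original criteria
and exhibits the documented failure mode: the unison uniquely maximises
proximity, so repeating the last tone is almost always top-ranked.

## Evaluation

Reciprocal rank uses the deterministic ranking; a truth outside the
candidate window (impossible for the human task, possible for arbitrary
data) is ranked one past the window (26) and flagged rather than
erroring, keeping MRR total. The scale-notes baseline counts the window
candidates whose pitch class is admissible for a window centred on an
admissible pitch — 2·|admissible| + 1 for the two-octave-plus-centre
window — giving 100/15 and 100/11 for the major and pentatonic windows.
Percentages are reported to one decimal.

## Synthetic corpora

The generator emulates the descriptive statistics of short folk-song
phrases: phrase lengths drawn from a clipped normal (mean 15, SD 3.5,
range 7–24), two phrases per song, pitches from a first-order walk over
scale tones in a ±7-semitone compass whose transition weight is the
tonal-hierarchy rating of the target class times `step_bias^|interval|`
(default 0.6, favouring steps), interior cadences on tonic or dominant
and the final cadence on the tonic, phrase-final tones held (duration
2 beats). Minor-mode songs are generated from the natural-minor scale —
the raised 6th/7th of the 9-class admissible set are evaluation
leniency, not typical melodic material. Motifs (per-scale banks, default
two per system, disjoint across systems) are planted verbatim at
Poisson(`motif_rate` = 2) per song, anchored on tonic-class pitches,
avoiding cadences and each other; the manifest records every placement,
key and phrase end as ground truth. Under these defaults a 200-song
corpus shows ≈15 events/phrase, mean tonal range ≈11–12 semitones and
leaps rarely beyond an octave, and profile-correlation key estimation
recovers the generating key in ≥ 90/100 major-mode songs.

What the generator does *not* emulate: real phrase syntax and meter,
motif variation (an optional ±1-semitone perturbation mode exercises the
gap tolerance but is off by default), modulation, rhythmic motifs, or
the idiom of any particular national repertoire. Passing tests therefore
establish internal correctness and the direction of the familiarity
effect under controlled conditions, not performance on real corpora.

## Problem sizes

The shipped tests and scripts use desk-scale sizes chosen once: corpora
of 100 songs (≈3 000 events) for training and behavioural properties,
200 songs for distributional checks, 20-excerpt evaluation sets mixed
75/25. Training on 100 songs takes a few seconds; the full suite runs
in well under a minute.

## Known limitations

* The hierarchy approximates the original part-based learner: gap
  tolerance on matching (insertions) is implemented, activation-level
  deletions/changes are not; part selection is a support heuristic, not
  a probabilistic model.
* Pattern supports are inflated by overlapping gapped occurrences of
  frequent shapes; they are comparable between shapes, not calibrated
  counts.
* One printed worked example of the weight formula (the "last four
  events" case) is internally inconsistent in its source — its own
  fraction 4/5 equals 0.80, not the printed 0.60 — and the formula
  reproduces the fraction, not the misprinted decimal.
* Key estimation assumes a single global key per melody; modulation and
  per-phrase hierarchies are out of scope, as is automatic
  phrase-boundary detection (phrase ends come from annotation or the
  generator).
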