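"""Monophonic symbolic-score I/O: note events, MIDI files, event-list CSV.

A melody is an ordered, non-overlapping sequence of ``NoteEvent`` objects
timed in beats (quarter note = 1).  Two interchange formats are supported:

* Standard MIDI Files (format 0/1), via the built-in codec in
  :mod:`melex._smf`; onsets are converted to beats using the file's
  ticks-per-quarter division.
* Event-list CSV with one line per note, fields in the order
  ``onset,pitch,duration`` (an optional header with exactly those names is
  tolerated on read).  Numbers are rendered losslessly, so a write → read
  round trip reproduces the melody exactly.

Beats, not seconds, are the native time unit: folk-song MIDI is metrical
and beats keep the arithmetic exact.  A ``tempo`` field (BPM) on the
melody enables conversion to seconds where a wall-clock duration is
needed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from ._smf import RawNote, SMFError, read_smf, write_smf

#: Overlaps up to this many beats are treated as sloppy note-offs and
#: truncated; anything larger is a genuine polyphony error.
MONOPHONY_TOLERANCE = 1.0 / 64.0


class ScoreFormatError(ValueError):
    """A file could not be parsed in the expected symbolic-score format."""


class MonophonyError(ValueError):
    """A note stream contains overlapping notes beyond tolerance."""


class EmptyInputError(ValueError):
    """An operation received a melody or track with no note events."""


@dataclass(frozen=True)
class NoteEvent:
    """A single note: onset (beats), MIDI pitch, duration (beats)."""

    onset: float
    pitch: int
    duration: float

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"onset must be non-negative, got {self.onset}")


@dataclass
class Melody:
    """An ordered monophonic note sequence with optional annotations.

    ``phrase_ends`` holds event indices of phrase-final tones;
    ``scale_hint`` (a :class:`melex.tonality.ScaleContext`) overrides key
    estimation downstream; ``tempo`` is beats per minute.
    """

    id: str
    events: list[NoteEvent]
    phrase_ends: Optional[list[int]] = None
    scale_hint: Optional[object] = None
    tempo: Optional[float] = None

    def __post_init__(self) -> None:
        self.events = validate_monophony(self.events)
        if self.phrase_ends is not None:
            if any(b <= a for a, b in zip(self.phrase_ends, self.phrase_ends[1:])):
                raise ValueError("phrase_ends must be strictly increasing")
            if self.phrase_ends and self.phrase_ends[-1] >= len(self.events):
                raise ValueError("phrase_end index beyond final event")

    @property
    def pitches(self) -> list[int]:
        return [e.pitch for e in self.events]

    def __len__(self) -> int:
        return len(self.events)

    def duration_beats(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration - self.events[0].onset

    def duration_seconds(self, default_tempo: float = 100.0) -> float:
        bpm = self.tempo if self.tempo else default_tempo
        return self.duration_beats() * 60.0 / bpm

    def transposed(self, semitones: int) -> "Melody":
        events = [replace(e, pitch=e.pitch + semitones) for e in self.events]
        return Melody(
            id=f"{self.id}+{semitones:+d}",
            events=events,
            phrase_ends=list(self.phrase_ends) if self.phrase_ends else None,
            tempo=self.tempo,
        )


def validate_monophony(events: Sequence[NoteEvent], tolerance: float = MONOPHONY_TOLERANCE) -> list[NoteEvent]:
    """Sort events by onset and enforce non-overlap.

    Overlaps within ``tolerance`` beats are repaired by truncating the
    earlier note; larger overlaps raise :class:`MonophonyError` naming the
    first offending pair.
    """
    ordered = sorted(events, key=lambda e: (e.onset, e.pitch))
    out: list[NoteEvent] = []
    for nxt in ordered:
        if out:
            prev = out[-1]
            overlap = (prev.onset + prev.duration) - nxt.onset
            if overlap > tolerance:
                raise MonophonyError(
                    f"events overlap by {overlap:g} beats: "
                    f"({prev.onset}, {prev.pitch}) and ({nxt.onset}, {nxt.pitch})"
                )
            if overlap > 0:
                new_dur = nxt.onset - prev.onset
                if new_dur <= 0:
                    raise MonophonyError(
                        f"simultaneous events at onset {prev.onset}: "
                        f"pitches {prev.pitch} and {nxt.pitch}"
                    )
                out[-1] = replace(prev, duration=new_dur)
        out.append(nxt)
    return out


# ---------------------------------------------------------------------------
# MIDI


def read_midi_melody(path: str, track_policy: str = "first_nonempty", melody_id: Optional[str] = None) -> Melody:
    """Read a monophonic melody from a Standard MIDI File.

    ``track_policy`` selects the track: ``"first_nonempty"`` (default) or
    an integer index given as a string / int.  Onsets and durations are
    converted to beats via the file's division.  Monophony is validated
    strictly (tolerance one tick beyond :data:`MONOPHONY_TOLERANCE`).
    """
    try:
        division, tracks = read_smf(path)
    except (SMFError, OSError) as exc:
        raise ScoreFormatError(f"{path}: {exc}") from exc
    if track_policy == "first_nonempty":
        selected = next((t for t in tracks if t), None)
    else:
        index = int(track_policy)
        selected = tracks[index] if 0 <= index < len(tracks) else None
    if not selected:
        raise EmptyInputError(f"{path}: no note events in selected track")
    events = [
        NoteEvent(
            onset=note.onset_ticks / division,
            pitch=note.pitch,
            duration=note.duration_ticks / division,
        )
        for note in selected
    ]
    return Melody(id=melody_id or path, events=events)


def write_midi_melody(melody: Melody, path: str, ticks_per_quarter: int = 480) -> None:
    """Write a melody to a format-0 Standard MIDI File."""
    notes = [
        RawNote(
            onset_ticks=round(e.onset * ticks_per_quarter),
            pitch=e.pitch,
            duration_ticks=max(1, round(e.duration * ticks_per_quarter)),
        )
        for e in melody.events
    ]
    write_smf(path, notes, ticks_per_quarter)


# ---------------------------------------------------------------------------
# Event-list CSV

_HEADER = ("onset", "pitch", "duration")


def _render(value: float) -> str:
    # repr round-trips floats exactly; integers drop the trailing ".0"
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def write_event_csv(melody: Melody, path: str) -> None:
    """Write one ``onset,pitch,duration`` line per event."""
    with open(path, "w", newline="") as handle:
        for event in melody.events:
            handle.write(f"{_render(event.onset)},{event.pitch},{_render(event.duration)}\n")


def read_event_csv(path: str, melody_id: Optional[str] = None) -> Melody:
    """Read an event-list CSV back into a :class:`Melody`."""
    events: list[NoteEvent] = []
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and tuple(f.strip().lower() for f in row) == _HEADER:
                continue
            if len(row) != 3:
                raise ScoreFormatError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                onset, pitch, duration = float(row[0]), float(row[1]), float(row[2])
            except ValueError as exc:
                raise ScoreFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            if pitch != int(pitch):
                raise ScoreFormatError(f"{path}:{lineno}: pitch must be an integer, got {row[1]}")
            events.append(NoteEvent(onset=onset, pitch=int(pitch), duration=duration))
    if not events:
        raise EmptyInputError(f"{path}: no note events")
    return Melody(id=melody_id or path, events=events)
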