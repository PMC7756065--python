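"""Minimal Standard MIDI File (SMF) codec for monophonic note streams.

Supports format 0 and format 1 files with metrical division (ticks per
quarter note).  Only note-on/note-off events are interpreted; every other
channel or meta event is skipped while its delta time is accumulated, so
onsets stay correct in the presence of tempo maps, program changes, etc.
SMPTE divisions are rejected — folk-song MIDI is metrical.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass


class SMFError(ValueError):
    """Raised when a file is not a parseable Standard MIDI File."""


@dataclass(frozen=True)
class RawNote:
    """A note with tick-resolution timing, as stored in the file."""

    onset_ticks: int
    pitch: int
    duration_ticks: int
    velocity: int = 64


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise SMFError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise ValueError("negative delta time")
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes) -> list[RawNote]:
    notes: list[RawNote] = []
    open_notes: dict[tuple[int, int], tuple[int, int]] = {}  # (ch, pitch) -> (onset, vel)
    pos = 0
    tick = 0
    running_status: int | None = None
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running_status = status
        else:
            if running_status is None:
                raise SMFError("data byte with no running status")
            status = running_status
        kind = status & 0xF0
        channel = status & 0x0F
        if kind in (0x80, 0x90):
            pitch, velocity = data[pos], data[pos + 1]
            pos += 2
            is_on = kind == 0x90 and velocity > 0
            key = (channel, pitch)
            if is_on:
                # restrike of an already sounding pitch closes the first note
                if key in open_notes:
                    onset, vel = open_notes.pop(key)
                    notes.append(RawNote(onset, pitch, max(1, tick - onset), vel))
                open_notes[key] = (tick, velocity)
            elif key in open_notes:
                onset, vel = open_notes.pop(key)
                notes.append(RawNote(onset, pitch, max(1, tick - onset), vel))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            pos += length
            if meta_type == 0x2F:
                break
        elif status in (0xF0, 0xF7):
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            raise SMFError(f"unsupported status byte 0x{status:02x}")
    for (channel, pitch), (onset, vel) in open_notes.items():
        notes.append(RawNote(onset, pitch, max(1, tick - onset), vel))
    notes.sort(key=lambda n: (n.onset_ticks, n.pitch))
    return notes


def read_smf(path: str) -> tuple[int, list[list[RawNote]]]:
    """Parse an SMF file, returning (ticks_per_quarter, tracks of notes)."""
    with open(path, "rb") as handle:
        data = handle.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise SMFError("not a Standard MIDI File (missing MThd)")
    header_len = struct.unpack(">I", data[4:8])[0]
    if header_len < 6:
        raise SMFError("malformed MThd chunk")
    fmt, n_tracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise SMFError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise SMFError("SMPTE time division is not supported")
    if division == 0:
        raise SMFError("zero ticks-per-quarter division")
    tracks: list[list[RawNote]] = []
    pos = 8 + header_len
    while pos + 8 <= len(data) and len(tracks) < n_tracks:
        chunk_id = data[pos : pos + 4]
        chunk_len = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        body = data[pos + 8 : pos + 8 + chunk_len]
        pos += 8 + chunk_len
        if chunk_id == b"MTrk":
            tracks.append(_parse_track(body))
    if not tracks:
        raise SMFError("file contains no MTrk chunk")
    return division, tracks


def write_smf(path: str, notes: list[RawNote], ticks_per_quarter: int = 480) -> None:
    """Write a single-track (format 0) SMF file from tick-timed notes."""
    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for note in notes:
        on = bytes((0x90, note.pitch, note.velocity))
        off = bytes((0x80, note.pitch, 0))
        events.append((note.onset_ticks, 1, on))
        events.append((note.onset_ticks + note.duration_ticks, 0, off))
    events.sort(key=lambda item: (item[0], item[1]))
    body = bytearray()
    tick = 0
    for when, _, message in events:
        body += _write_varlen(when - tick)
        body += message
        tick = when
    body += _write_varlen(0) + bytes((0xFF, 0x2F, 0x00))
    with open(path, "wb") as handle:
        handle.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_quarter))
        handle.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
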