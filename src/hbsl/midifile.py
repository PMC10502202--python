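"""Minimal Standard MIDI File (SMF) reader/writer.

Supports format 0/1 files with note-on/note-off and set-tempo events, which
is all a monophonic melody needs. Running status and variable-length
quantities are handled; other channel/meta/sysex events are parsed and
skipped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field


class MidiFormatError(ValueError):
    """Raised when a file is not a usable Standard MIDI File."""


@dataclass
class RawNote:
    pitch: int
    tick_on: int
    tick_off: int


@dataclass
class MidiData:
    ticks_per_beat: int
    tempo_us_per_beat: int  # first set-tempo found, else 500000 (120 bpm)
    notes: list[RawNote] = field(default_factory=list)


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes, track_index: int) -> tuple[list[RawNote], int | None]:
    notes: list[RawNote] = []
    tempo: int | None = None
    active: dict[int, int] = {}  # pitch -> tick_on
    tick = 0
    pos = 0
    status = 0
    try:
        while pos < len(data):
            delta, pos = _read_varlen(data, pos)
            tick += delta
            byte = data[pos]
            if byte & 0x80:
                status = byte
                pos += 1
            elif status == 0:
                raise MidiFormatError(
                    f"track {track_index}: running status without prior status byte"
                )
            kind = status & 0xF0
            if status == 0xFF:  # meta
                meta_type = data[pos]
                length, pos2 = _read_varlen(data, pos + 1)
                payload = data[pos2 : pos2 + length]
                pos = pos2 + length
                if meta_type == 0x51 and length == 3:
                    tempo = tempo or int.from_bytes(payload, "big")
                elif meta_type == 0x2F:
                    break
            elif status in (0xF0, 0xF7):  # sysex
                length, pos2 = _read_varlen(data, pos)
                pos = pos2 + length
            elif kind in (0x80, 0x90):
                pitch, velocity = data[pos], data[pos + 1]
                pos += 2
                if kind == 0x90 and velocity > 0:
                    active[pitch] = tick
                else:  # note off (or note-on with velocity 0)
                    if pitch in active:
                        notes.append(RawNote(pitch, active.pop(pitch), tick))
            elif kind in (0xA0, 0xB0, 0xE0):
                pos += 2
            elif kind in (0xC0, 0xD0):
                pos += 1
            else:
                raise MidiFormatError(
                    f"track {track_index}: unknown status byte 0x{status:02x}"
                )
    except IndexError as exc:
        raise MidiFormatError(f"track {track_index}: truncated track data") from exc
    # close dangling notes at the final tick
    for pitch, tick_on in active.items():
        notes.append(RawNote(pitch, tick_on, tick))
    return notes, tempo


def read_smf(path) -> MidiData:
    """Parse an SMF file into raw (pitch, tick) notes plus timing metadata."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 14 or data[:4] != b"MThd":
        raise MidiFormatError(f"{path}: missing MThd header")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise MidiFormatError(f"{path}: SMPTE time division is not supported")
    pos = 8 + header_len
    midi = MidiData(ticks_per_beat=division, tempo_us_per_beat=500000)
    found_tempo = None
    for track_index in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise MidiFormatError(f"{path}: track {track_index} has no MTrk header")
        (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
        chunk = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        notes, tempo = _parse_track(chunk, track_index)
        midi.notes.extend(notes)
        found_tempo = found_tempo or tempo
    if found_tempo:
        midi.tempo_us_per_beat = found_tempo
    if not midi.notes:
        raise MidiFormatError(f"{path}: no notes found in any of {n_tracks} track(s)")
    midi.notes.sort(key=lambda n: (n.tick_on, n.pitch))
    return midi


def write_smf(path, midi: MidiData) -> None:
    """Write raw notes as a single-track format-0 SMF."""
    events: list[tuple[int, int, bytes]] = []  # (tick, order, message)
    for note in midi.notes:
        events.append((note.tick_on, 1, bytes([0x90, note.pitch, 0x60])))
        events.append((note.tick_off, 0, bytes([0x80, note.pitch, 0x00])))
    events.sort(key=lambda e: (e[0], e[1]))
    track = bytearray()
    track += _write_varlen(0) + bytes([0xFF, 0x51, 0x03])
    track += midi.tempo_us_per_beat.to_bytes(3, "big")
    tick = 0
    for ev_tick, _, message in events:
        track += _write_varlen(ev_tick - tick) + message
        tick = ev_tick
    track += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, midi.ticks_per_beat))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
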