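"""Symbolic melody handling: MIDI I/O, tokenization, and fixture melodies.

The learner operates on integer token streams. This module converts between
Standard MIDI Files, an in-memory monophonic note list (:class:`SymbolSequence`),
and :class:`TokenSequence` streams over a small alphabet, and can synthesize
children's-song-like fixture melodies with planted repeated motifs so that
chunkable statistical structure is guaranteed to exist.

Time is measured in beats (quarter note = 1.0); tempo only matters when a
sequence is rendered to audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .midifile import MidiData, MidiFormatError, RawNote, read_smf, write_smf

__all__ = [
    "NoteEvent",
    "SymbolSequence",
    "TokenSequence",
    "read_midi",
    "write_midi",
    "tokenize",
    "detokenize",
    "make_fixture_melody",
    "MidiFormatError",
]

#: duration grid (in beats) used for quantization and fixture melodies
DURATION_GRID = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class NoteEvent:
    """A single monophonic note: MIDI pitch, onset and duration in beats."""

    pitch: int
    onset: float
    duration: float

    def __post_init__(self):
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0-127")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SymbolSequence:
    """An ordered monophonic melody.

    Invariants: onsets non-decreasing, no overlapping notes, durations > 0.
    """

    events: list[NoteEvent]
    ticks_per_beat: int = 480
    tempo_bpm: float = 120.0

    def __post_init__(self):
        if self.ticks_per_beat <= 0:
            raise ValueError("ticks_per_beat must be positive")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.onset < prev.onset:
                raise ValueError("onsets must be non-decreasing")
            if cur.onset < prev.onset + prev.duration - 1e-9:
                raise ValueError("sequence is not monophonic (overlapping notes)")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def pitches(self) -> list[int]:
        return [e.pitch for e in self.events]

    @property
    def total_beats(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration


@dataclass
class TokenSequence:
    """Integer token stream over an explicit alphabet.

    ``scheme="pitch"`` maps each note to its pitch; ``scheme="pitch_duration"``
    maps to the (pitch, quantized duration) pair. The alphabet records the
    distinct symbols in first-appearance order, so every token id is < K.
    """

    tokens: list[int]
    alphabet: list = field(default_factory=list)
    scheme: str = "pitch"

    def __post_init__(self):
        if len(set(map(tuple_key, self.alphabet))) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")
        k = len(self.alphabet)
        if any(not 0 <= t < k for t in self.tokens):
            raise ValueError("token id outside alphabet range")

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.tokens)


def tuple_key(symbol):
    return tuple(symbol) if isinstance(symbol, (list, tuple)) else symbol


def quantize_duration(duration: float, grid=DURATION_GRID) -> float:
    """Snap a duration in beats to the nearest grid value."""
    arr = np.asarray(grid, dtype=float)
    return float(arr[np.argmin(np.abs(arr - duration))])


def read_midi(path) -> SymbolSequence:
    """Read an SMF file as a monophonic melody.

    Polyphony is collapsed by keeping the highest-pitch note among notes
    sounding at the same onset, and truncating any note that would overlap
    its successor. Raises :class:`MidiFormatError` for unreadable or empty
    files.
    """
    midi = read_smf(path)
    tpb = midi.ticks_per_beat
    # group by onset tick, keep highest pitch
    by_onset: dict[int, RawNote] = {}
    for note in midi.notes:
        kept = by_onset.get(note.tick_on)
        if kept is None or note.pitch > kept.pitch:
            by_onset[note.tick_on] = note
    events: list[NoteEvent] = []
    onsets = sorted(by_onset)
    for i, tick in enumerate(onsets):
        note = by_onset[tick]
        tick_off = note.tick_off
        if i + 1 < len(onsets):
            tick_off = min(tick_off, onsets[i + 1])
        duration = max(tick_off - tick, 1) / tpb
        events.append(NoteEvent(note.pitch, tick / tpb, duration))
    tempo_bpm = 60e6 / midi.tempo_us_per_beat
    return SymbolSequence(events, ticks_per_beat=tpb, tempo_bpm=tempo_bpm)


def write_midi(path, seq: SymbolSequence) -> None:
    """Write a melody as a format-0 SMF file."""
    tpb = seq.ticks_per_beat
    notes = [
        RawNote(
            pitch=e.pitch,
            tick_on=round(e.onset * tpb),
            tick_off=round((e.onset + e.duration) * tpb),
        )
        for e in seq.events
    ]
    write_smf(path, MidiData(tpb, round(60e6 / seq.tempo_bpm), notes))


def tokenize(seq: SymbolSequence, scheme: str = "pitch") -> TokenSequence:
    """Map a melody to an integer token stream.

    The alphabet is built from the distinct observed symbols in order of
    first appearance.
    """
    if not seq.events:
        raise ValueError("cannot tokenize an empty sequence")
    if scheme == "pitch":
        symbols = [e.pitch for e in seq.events]
    elif scheme == "pitch_duration":
        symbols = [(e.pitch, quantize_duration(e.duration)) for e in seq.events]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    alphabet: list = []
    index: dict = {}
    tokens: list[int] = []
    for sym in symbols:
        key = tuple_key(sym)
        if key not in index:
            index[key] = len(alphabet)
            alphabet.append(sym)
        tokens.append(index[key])
    return TokenSequence(tokens, alphabet, scheme)


def detokenize(tok: TokenSequence, tempo_bpm: float = 120.0) -> SymbolSequence:
    """Inverse of :func:`tokenize`: rebuild a melody from tokens.

    Pitch-only tokens get unit (one beat) durations; pitch_duration tokens
    restore their quantized durations. Notes are laid out back-to-back.
    """
    events = []
    onset = 0.0
    for t in tok.tokens:
        sym = tok.alphabet[t]
        if tok.scheme == "pitch_duration":
            pitch, duration = int(sym[0]), float(sym[1])
        else:
            pitch, duration = int(sym), 1.0
        events.append(NoteEvent(pitch, onset, duration))
        onset += duration
    return SymbolSequence(events, tempo_bpm=tempo_bpm)


def make_fixture_melody(
    n_notes: int = 40,
    alphabet_size: int = 8,
    motif_length: int = 4,
    motif_repeats: int = 5,
    seed: int = 7,
    base_pitch: int = 60,
) -> SymbolSequence:
    """Generate a children's-song-like melody with a planted repeated motif.

    The melody uses ``alphabet_size`` consecutive scale degrees (major scale
    from ``base_pitch``), durations drawn from {0.5, 1, 2} beats, and embeds
    exactly ``motif_repeats`` non-overlapping copies of one fixed
    ``motif_length``-note motif among uniform filler notes. Deterministic
    for a fixed seed.
    """
    if motif_length < 2:
        raise ValueError("motif_length must be at least 2")
    if motif_length * motif_repeats > n_notes:
        raise ValueError(
            f"cannot place {motif_repeats} motifs of length {motif_length} "
            f"in {n_notes} notes"
        )
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be at least 2")
    seq, _ = make_fixture_melody_with_motif(
        n_notes, alphabet_size, motif_length, motif_repeats, seed, base_pitch
    )
    return seq


def make_fixture_melody_with_motif(
    n_notes: int = 40,
    alphabet_size: int = 8,
    motif_length: int = 4,
    motif_repeats: int = 5,
    seed: int = 7,
    base_pitch: int = 60,
) -> tuple[SymbolSequence, list[int]]:
    """Like :func:`make_fixture_melody` but also return the motif's pitches."""
    if motif_length < 2:
        raise ValueError("motif_length must be at least 2")
    if motif_length * motif_repeats > n_notes:
        raise ValueError(
            f"cannot place {motif_repeats} motifs of length {motif_length} "
            f"in {n_notes} notes"
        )
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be at least 2")
    rng = np.random.default_rng(seed)
    major = [0, 2, 4, 5, 7, 9, 11]
    scale = [base_pitch + 12 * (d // 7) + major[d % 7] for d in range(alphabet_size)]
    durations_grid = np.asarray(DURATION_GRID)

    if alphabet_size < motif_length:
        raise ValueError("alphabet_size must be >= motif_length")
    # one fixed motif: distinct degrees so its internal transitions are
    # unambiguous, each with a fixed duration
    motif_deg = rng.choice(
        min(alphabet_size, motif_length + 2), size=motif_length, replace=False
    )
    motif_dur = rng.choice(durations_grid, size=motif_length)
    motif = [int(d) for d in motif_deg]

    n_filler = n_notes - motif_length * motif_repeats
    for _ in range(1000):  # redraw filler until no accidental motif copy exists
        cuts = np.sort(rng.integers(0, n_filler + 1, size=motif_repeats))
        gaps = np.diff(np.concatenate(([0], cuts, [n_filler])))
        degrees: list[int] = []
        durations: list[float] = []
        for i in range(motif_repeats + 1):
            for _ in range(int(gaps[i])):
                degrees.append(int(rng.integers(alphabet_size)))
                durations.append(float(rng.choice(durations_grid)))
            if i < motif_repeats:
                degrees.extend(motif)
                durations.extend(float(d) for d in motif_dur)
        occurrences = sum(
            1
            for i in range(len(degrees) - motif_length + 1)
            if degrees[i : i + motif_length] == motif
        )
        if occurrences == motif_repeats:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not place motifs without accidental copies")

    events = []
    onset = 0.0
    for deg, dur in zip(degrees, durations):
        events.append(NoteEvent(scale[deg], onset, dur))
        onset += dur
    return SymbolSequence(events), [scale[d] for d in motif]


def count_motif_occurrences(seq: SymbolSequence, motif_pitches: list[int]) -> int:
    """Count (possibly overlapping) occurrences of a pitch pattern."""
    pitches = seq.pitches
    m = len(motif_pitches)
    return sum(
        1 for i in range(len(pitches) - m + 1) if pitches[i : i + m] == motif_pitches
    )
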