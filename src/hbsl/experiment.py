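"""Full perception-to-production simulation grid.

Three sensory-sensitivity regimes (hypo 0.25, normal 1, hyper 4) each learn
the training melody cumulatively for up to five trials. After every trial
the model is snapshotted and, per snapshot: total Bayesian surprise and
chunk count are recorded, a corpus of pieces is generated from the chunk
hierarchy, the corpus-average bigram distribution is compared to the
training piece (Jensen-Shannon divergence), and — optionally — the corpus
is rendered to audio and summarized as AM band powers. The grid is fully
reproducible from a single root seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio import Waveform, render_waveform, write_wav, zscore_normalize
from .chunker import build_hierarchy, extract_chunks
from .generator import (
    average_bigram_distribution,
    bigram_distribution,
    distance_to_reference,
    generate_corpus,
)
from .learner import SENSITIVITY_FACTORS, DirichletMarkovModel, learn_sequence
from .pad import corpus_band_power
from .symbolic import (
    SymbolSequence,
    detokenize,
    make_fixture_melody,
    read_midi,
    tokenize,
    write_midi,
)

__all__ = ["ExperimentConfig", "ResultsTable", "run_experiment", "export_results"]


@dataclass
class ExperimentConfig:
    """Parameters of the simulation grid; defaults give the desk-scale run."""

    # training melody: a MIDI path, or the planted-motif fixture below
    training_midi: str | None = None
    n_notes: int = 40
    alphabet_size: int = 8
    motif_length: int = 4
    motif_repeats: int = 5
    fixture_seed: int = 7

    scheme: str = "pitch_duration"
    sensitivity_factors: dict = field(
        default_factory=lambda: dict(SENSITIVITY_FACTORS)
    )
    sensitivity_mode: str = "prior"
    order: int = 1
    base_concentration: float = 1.0
    max_trials: int = 5
    pieces_per_model: int = 100
    chunk_threshold: float = 5.0
    seed: int = 0

    # audio / rhythm analysis
    include_audio: bool = False
    sample_rate: int = 4000
    tempo_bpm: float = 120.0
    band_rates: tuple = (8.0, 4.0, 2.0, 1.0, 0.5)
    cutoff_hz: float = 10.0
    clip_seconds: float | None = 10.0  # analysis window per piece (None = full)
    audio_pieces: int | None = None  # None = all pieces

    def __post_init__(self):
        if any(f <= 0 for f in self.sensitivity_factors.values()):
            raise ValueError("sensitivity factors must be positive")
        if self.max_trials < 1 or self.pieces_per_model < 1:
            raise ValueError("max_trials and pieces_per_model must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsTable:
    """One row per (regime, trial) with learning and production summaries."""

    frame: pd.DataFrame
    config: ExperimentConfig
    corpora: dict = field(default_factory=dict)  # (regime, trial) -> GeneratedCorpus
    training: SymbolSequence | None = None


def _training_sequence(config: ExperimentConfig) -> SymbolSequence:
    if config.training_midi is not None:
        return read_midi(config.training_midi)
    return make_fixture_melody(
        config.n_notes,
        config.alphabet_size,
        config.motif_length,
        config.motif_repeats,
        config.fixture_seed,
    )


def run_experiment(config: ExperimentConfig) -> ResultsTable:
    """Run the |regimes| x max_trials grid and collect all summaries."""
    training = _training_sequence(config)
    tok = tokenize(training, config.scheme)
    training_bigrams = bigram_distribution(tok)
    root = np.random.SeedSequence(config.seed)

    rows = []
    corpora = {}
    for regime_idx, (regime, factor) in enumerate(
        sorted(config.sensitivity_factors.items())
    ):
        model = DirichletMarkovModel(
            tok.K,
            order=config.order,
            sensitivity_factor=factor,
            base_concentration=config.base_concentration,
            sensitivity_mode=config.sensitivity_mode,
        )
        for trial in range(1, config.max_trials + 1):
            model, trace = learn_sequence(model, tok.tokens, trial_index=trial)
            snapshot = model.copy()
            chunks = extract_chunks(snapshot, tok.tokens, config.chunk_threshold)
            encoded, hmodel = build_hierarchy(
                tok.tokens, chunks, snapshot, training_trials=trial
            )
            gen_seed = int(
                np.random.SeedSequence(
                    (config.seed, regime_idx, trial)
                ).generate_state(1)[0]
                % (2**31)
            )
            corpus = generate_corpus(
                hmodel,
                config.pieces_per_model,
                len(tok.tokens),
                gen_seed,
                model_id=(regime, trial),
                first_token=encoded[0],
                alphabet=tok.alphabet,
                scheme=tok.scheme,
            )
            corpora[(regime, trial)] = corpus
            avg = average_bigram_distribution(corpus)
            row = {
                "regime": regime,
                "trial": trial,
                "sensitivity_factor": factor,
                "total_surprise": trace.total_surprise,
                "n_chunks": len(chunks),
                "js_distance": distance_to_reference(avg, training_bigrams),
            }
            if config.include_audio:
                n_audio = config.audio_pieces or config.pieces_per_model
                waves = []
                for piece in corpus.pieces[:n_audio]:
                    wave = render_waveform(
                        detokenize(piece, config.tempo_bpm),
                        sample_rate=config.sample_rate,
                        tempo_bpm=config.tempo_bpm,
                    )
                    if config.clip_seconds is not None:
                        n_clip = int(config.clip_seconds * config.sample_rate)
                        wave = Waveform(wave.samples[:n_clip], wave.sample_rate)
                    waves.append(zscore_normalize(wave))
                power = corpus_band_power(
                    waves, config.band_rates, cutoff_hz=config.cutoff_hz
                )
                for rate, p in zip(config.band_rates, power):
                    row[f"band_power_{rate:g}hz"] = p
            rows.append(row)
    frame = pd.DataFrame(rows)
    return ResultsTable(frame, config, corpora, training)


def export_results(table: ResultsTable, out_dir) -> dict:
    """Write CSV summaries, MIDI corpora and run metadata; return a manifest.

    The manifest maps each emitted file (relative path) to its SHA-256
    checksum. Re-exporting the same table to the same directory is
    idempotent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = out / "results.csv"
    table.frame.to_csv(summary, index=False)
    written.append(summary)

    if table.training is not None:
        path = out / "training.mid"
        write_midi(path, table.training)
        written.append(path)

    midi_dir = out / "midi"
    midi_dir.mkdir(exist_ok=True)
    for (regime, trial), corpus in table.corpora.items():
        for i, piece in enumerate(corpus.pieces):
            path = midi_dir / f"{regime}_trial{trial}_piece{i:03d}.mid"
            write_midi(path, detokenize(piece, table.config.tempo_bpm))
            written.append(path)

    if table.config.include_audio:
        wav_dir = out / "wav"
        wav_dir.mkdir(exist_ok=True)
        n_audio = table.config.audio_pieces or table.config.pieces_per_model
        for (regime, trial), corpus in table.corpora.items():
            for i, piece in enumerate(corpus.pieces[:n_audio]):
                path = wav_dir / f"{regime}_trial{trial}_piece{i:03d}.wav"
                wave = render_waveform(
                    detokenize(piece, table.config.tempo_bpm),
                    sample_rate=table.config.sample_rate,
                )
                write_wav(path, wave)
                written.append(path)

    metadata = {
        "config": asdict(table.config),
        "config_hash": table.config.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=1, default=str))
    written.append(meta_path)

    manifest = {}
    for path in written:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[str(path.relative_to(out))] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
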