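"""Deterministic synthetic corpus generator for end-to-end testing.

Emulates the shape of a curated anti-CRISPR corpus — two classes, sequence
lengths 50-350, per-protein PSSMs and per-residue embeddings — with a
tunable class-separable signal so every pipeline stage can be exercised
without external downloads.

The signal of strength ``effect`` is injected where all three composite
feature branches can see it:

* sequences: the positive class up-weights a fixed residue subset
  (F, Y, W, M, L), separating composition features;
* PSSMs: five designated columns (the aromatic and M/L reduced groups)
  receive a constant mean shift plus a smooth sinusoidal positional
  component for positives — the shift moves the adjacent-row cross terms of
  the reduced-PSSM descriptor, the positional component adds variance and
  lag autocovariance visible to the (shift-invariant) autocovariance
  encoder;
* embeddings: ten designated dimensions are shifted for positives on top of
  a deterministic sequence projection plus noise.

With ``effect = 0`` the two classes are drawn from identical distributions
(exchangeable); everything is reproducible from ``seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoders import SequenceProjectionEmbedder
from .records import (
    AMINO_ACIDS,
    PSSM_COLUMNS,
    EmbeddingMatrix,
    LabeledDataset,
    ProteinRecord,
    PSSMProfile,
)
from . import io as io_formats

#: Residues biased in positive-class sequences and shifted in their PSSMs
#: (the aromatic {F,Y,W} and {M,L} reduced groups).
SIGNAL_RESIDUES = ("F", "Y", "W", "M", "L")
_SIGNAL_PSSM_COLS = tuple(PSSM_COLUMNS.index(a) for a in SIGNAL_RESIDUES)
_SIGNAL_SEQ_IDX = tuple(AMINO_ACIDS.index(a) for a in SIGNAL_RESIDUES)

#: Embedding dimensions shifted for the positive class.
SIGNAL_EMBED_DIMS = tuple(range(10))

#: Discrete log-odds noise support, mimicking typical PSSM value ranges.
_PSSM_NOISE_VALUES = np.arange(-5, 10)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic corpus.

    ``effect`` scales every injected class difference (0 = exchangeable
    classes); lengths are drawn uniformly from ``length_range``.
    """

    n_pos: int = 412
    n_neg: int = 412
    length_range: tuple[int, int] = (50, 350)
    effect: float = 1.0
    seed: int = 0
    embed_dim: int = 121

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


def _sequence_weights(effect: float) -> np.ndarray:
    logw = np.zeros(20)
    logw[list(_SIGNAL_SEQ_IDX)] = 0.15 * effect
    w = np.exp(logw)
    return w / w.sum()


def _simulate_pssm(rng: np.random.Generator, rec: ProteinRecord,
                   positive: bool, effect: float) -> PSSMProfile:
    L = rec.length
    noise = rng.choice(_PSSM_NOISE_VALUES, size=(L, 20))
    matrix = noise.astype(float)
    if positive and effect > 0:
        shift = int(round(effect))
        amplitude = 1.5 * effect
        positions = np.arange(L)
        wave = np.round(amplitude * np.sin(2 * np.pi * positions / 20.0))
        for j in _SIGNAL_PSSM_COLS:
            matrix[:, j] += shift + wave
    return PSSMProfile(rec.id, matrix, rec.sequence)


def _simulate_embedding(rng: np.random.Generator, rec: ProteinRecord,
                        embedder: SequenceProjectionEmbedder,
                        positive: bool, effect: float) -> EmbeddingMatrix:
    base = embedder.embed(rec).matrix
    noisy = base + 0.1 * rng.standard_normal(base.shape)
    if positive and effect > 0:
        noisy[:, list(SIGNAL_EMBED_DIMS)] += 0.05 * effect
    return EmbeddingMatrix(rec.id, noisy)


def simulate_dataset(cfg: SimulationConfig) -> LabeledDataset:
    """Generate a labelled corpus (sequences + PSSMs + embeddings) from a seed."""
    rng = np.random.default_rng(cfg.seed)
    embedder = SequenceProjectionEmbedder(dim=cfg.embed_dim, seed=0)
    aa = np.array(list(AMINO_ACIDS))
    pos_w = _sequence_weights(cfg.effect)
    neg_w = _sequence_weights(0.0)

    records: list[ProteinRecord] = []
    labels: list[int] = []
    pssms: dict[str, PSSMProfile] = {}
    embeddings: dict[str, EmbeddingMatrix] = {}
    lo, hi = cfg.length_range
    for cls, count, weights in ((1, cfg.n_pos, pos_w), (0, cfg.n_neg, neg_w)):
        prefix = "pos" if cls else "neg"
        for i in range(count):
            rid = f"{prefix}_{i + 1:04d}"
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(aa, size=L, p=weights))
            rec = ProteinRecord(rid, seq)
            records.append(rec)
            labels.append(cls)
            pssms[rid] = _simulate_pssm(rng, rec, cls == 1, cfg.effect)
            embeddings[rid] = _simulate_embedding(
                rng, rec, embedder, cls == 1, cfg.effect
            )
    return LabeledDataset(records, np.array(labels), pssms, embeddings)


def write_corpus(ds: LabeledDataset, directory: str | os.PathLike) -> None:
    """Write a dataset as FASTA + per-protein ASCII PSSMs + embedding TSVs + labels.

    The layout is ``sequences.fasta``, ``labels.tsv``, ``pssm/<id>.pssm`` and
    ``embeddings/<id>.emb.tsv``, all readable by the io module unchanged.
    """
    directory = Path(directory)
    (directory / "pssm").mkdir(parents=True, exist_ok=True)
    (directory / "embeddings").mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(ds.records, directory / "sequences.fasta")
    io_formats.write_labels_tsv(
        dict(zip(ds.ids, (int(v) for v in ds.labels))), directory / "labels.tsv"
    )
    for rid, profile in ds.pssms.items():
        io_formats.write_pssm_ascii(profile, directory / "pssm" / f"{rid}.pssm")
    for rid, emb in ds.embeddings.items():
        io_formats.write_embedding_tsv(
            emb, directory / "embeddings" / f"{rid}.emb.tsv"
        )


def read_corpus(directory: str | os.PathLike) -> LabeledDataset:
    """Load a corpus written by :func:`write_corpus`."""
    directory = Path(directory)
    records = io_formats.read_fasta(directory / "sequences.fasta")
    labels_map = io_formats.read_labels_tsv(directory / "labels.tsv")
    missing = [r.id for r in records if r.id not in labels_map]
    if missing:
        raise ValueError(f"labels missing for ids: {missing}")
    labels = np.array([labels_map[r.id] for r in records])
    pssms = {}
    embeddings = {}
    for rec in records:
        pssm_path = directory / "pssm" / f"{rec.id}.pssm"
        if pssm_path.exists():
            pssms[rec.id] = io_formats.read_pssm_ascii(pssm_path, record_id=rec.id)
        emb_path = directory / "embeddings" / f"{rec.id}.emb.tsv"
        if emb_path.exists():
            embeddings[rec.id] = io_formats.read_embedding_tsv(
                emb_path, record_id=rec.id
            )
    return LabeledDataset(records, labels, pssms, embeddings)
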