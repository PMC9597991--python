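"""Core domain types: protein records, PSSM profiles, embeddings, datasets.

The unit of analysis is a protein sequence over the 20 canonical residues.
Evolutionary information arrives as an L x 20 position-specific scoring matrix
(PSSM, PSI-BLAST column order) and learned per-residue representations as an
L x D embedding matrix (D = 121 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid alphabet in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST PSSM column order (the header order of ``-out_ascii_pssm`` files).
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTVWY"

_CANONICAL = frozenset(AMINO_ACIDS)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class EncodingError(ValueError):
    """Raised when a sequence or profile cannot be encoded."""


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase a sequence and strip non-canonical residues.

    Characters outside the 20 canonical residues (B, J, O, U, X, Z, ``*`` and
    gaps) are removed with a warning: the composition formulas are defined only
    over the canonical alphabet.
    """
    seq = seq.upper()
    kept = [c for c in seq if c in _CANONICAL]
    dropped = len(seq) - len(kept)
    if dropped:
        warnings.warn(
            f"record {record_id!r}: stripped {dropped} non-canonical residue(s)",
            stacklevel=2,
        )
    return "".join(kept)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence; identifiers are unique within a dataset."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sanitized(self) -> "ProteinRecord":
        return ProteinRecord(self.id, sanitize_sequence(self.sequence, self.id))


@dataclass
class PSSMProfile:
    """An L x 20 position-specific scoring matrix aligned to a sequence.

    Columns follow the PSI-BLAST order :data:`PSSM_COLUMNS`; ``matrix[i, j]``
    is the log-odds score of residue ``PSSM_COLUMNS[j]`` at position ``i``.
    """

    record_id: str
    matrix: np.ndarray
    sequence: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.record_id!r} must be L x 20, got {self.matrix.shape}"
            )
        if self.matrix.shape[0] != len(self.sequence):
            raise ValueError(
                f"PSSM for {self.record_id!r}: {self.matrix.shape[0]} rows but "
                f"sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"PSSM for {self.record_id!r} contains non-finite values")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EmbeddingMatrix:
    """An L x D per-residue embedding (one row per position)."""

    record_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError(
                f"embedding for {self.record_id!r} must be L x D with L,D >= 1"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(
                f"embedding for {self.record_id!r} contains non-finite values"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LabeledDataset:
    """Records with binary labels (1 = anti-CRISPR) and optional aligned resources."""

    records: list[ProteinRecord]
    labels: np.ndarray
    pssms: dict[str, PSSMProfile] = field(default_factory=dict)
    embeddings: dict[str, EmbeddingMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.records):
            raise ValueError("one label per record required")
        if self.labels.size and not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique within a dataset")
        known = set(ids)
        for name, res in (("pssms", self.pssms), ("embeddings", self.embeddings)):
            unknown = set(res) - known
            if unknown:
                raise ValueError(f"{name} reference unknown ids: {sorted(unknown)}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FeatureMatrix:
    """An n_samples x n_features table with row ids and encoder provenance."""

    ids: list[str]
    data: np.ndarray
    columns: list[str]
    encoder: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] == 0:
            self.data = self.data.reshape(0, len(self.columns))
        if self.data.shape != (len(self.ids), len(self.columns)):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("feature column names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_columns(self, indices: list[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            ids=list(self.ids),
            data=self.data[:, indices],
            columns=[self.columns[i] for i in indices],
            encoder=self.encoder,
        )
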