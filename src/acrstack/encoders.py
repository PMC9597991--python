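"""Feature encoders for anti-CRISPR prediction.

Five encodings turn a protein into a fixed-length vector:

* **AAC** — amino-acid composition, the residue frequency vector (20 dims).
* **PAAC** — pseudo-amino-acid composition: normalized residue frequencies
  augmented with lambda sequence-order correlation factors theta_j built from
  hydrophobicity, hydrophilicity and side-chain mass (20 + lambda dims).
* **PSSM-AC** — autocovariance of each PSSM column over lags 1..G, capturing
  within-column positional correlation of the evolutionary profile (20*G dims).
* **RPSSM** — the PSSM reduced to 10 physicochemical residue-group columns,
  summarized by per-column variances E_j and adjacent-row pairwise squared
  differences E_{j,t} (10 + 100 = 110 dims).
* **SSA pooling** — the column mean of an L x D per-residue embedding (D dims),
  plus the soft-sequence-alignment similarity between two embeddings.

Each encoder is a stateless scikit-learn transformer over lists of records /
profiles / embeddings; module-level functions wrap them for single inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, TransformerMixin

from .records import (
    AMINO_ACIDS,
    PSSM_COLUMNS,
    EmbeddingMatrix,
    EncodingError,
    FeatureMatrix,
    LabeledDataset,
    ProteinRecord,
    PSSMProfile,
)

# ---------------------------------------------------------------------------
# Per-residue property scales (Chou's pseudo-amino-acid composition convention),
# indexed by AMINO_ACIDS order. Hydrophobicity: Tanford-style consensus scale;
# hydrophilicity: Hopp-Woods; side-chain mass in Daltons.

_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardize(table: dict[str, float]) -> np.ndarray:
    """Zero-mean unit-variance (population) scale over the 20 residues."""
    v = np.array([table[a] for a in AMINO_ACIDS])
    return (v - v.mean()) / v.std()


def standardized_property_tables() -> np.ndarray:
    """3 x 20 array of standardized hydrophobicity, hydrophilicity, mass scales."""
    return np.stack(
        [_standardize(t) for t in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDE_CHAIN_MASS)]
    )


@dataclass
class PAACParams:
    """Pseudo-amino-acid composition parameters.

    lam is the maximum correlation length lambda (sequences must be longer
    than lam); omega weights the sequence-order factors against composition.
    """

    lam: int = 3
    omega: float = 0.05

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lam must be a positive integer")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


# ---------------------------------------------------------------------------
# Residue groups for the reduced PSSM, in output column order.

RPSSM_GROUPS: tuple[tuple[str, ...], ...] = (
    ("F", "Y", "W"),
    ("M", "L"),
    ("I", "V"),
    ("A", "T", "S"),
    ("N", "H"),
    ("Q", "E", "D"),
    ("R", "K"),
    ("C",),
    ("G",),
    ("P",),
)

_GROUP_INDICES = tuple(
    tuple(PSSM_COLUMNS.index(a) for a in group) for group in RPSSM_GROUPS
)


def _aa_index(seq: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=int)
    for i, a in enumerate(AMINO_ACIDS):
        lut[ord(a)] = i
    idx = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(idx < 0):
        raise EncodingError("sequence contains non-canonical residues; sanitize first")
    return idx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Transformers


class _RecordEncoder(BaseEstimator, TransformerMixin):
    """Stateless encoder base: ``fit`` is a no-op, ``transform`` maps a list."""

    name: str = ""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        return np.array([self._encode_one(x) for x in X])

    def _encode_one(self, x) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        raise NotImplementedError


class AACEncoder(_RecordEncoder):
    """Amino-acid composition: residue frequencies over the sanitized sequence."""

    name = "aac"

    def _encode_one(self, rec: ProteinRecord) -> np.ndarray:
        rec = rec.sanitized()
        if not rec.sequence:
            raise EncodingError(f"record {rec.id!r}: empty sequence after sanitization")
        counts = np.bincount(_aa_index(rec.sequence), minlength=20)
        return counts / rec.length

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"aac_{a}" for a in AMINO_ACIDS])


class PAACEncoder(_RecordEncoder):
    """Pseudo-amino-acid composition with lambda sequence-order factors.

    theta_j = (1/(L-j)) * sum_i Theta(S_i, S_{i+j}) where Theta averages the
    squared differences of the three standardized property scales; the 20
    composition terms and lambda omega*theta terms share the denominator
    sum(f) + omega * sum(theta), so the vector sums to 1.
    """

    name = "paac"

    def __init__(self, params: PAACParams | None = None):
        self.params = params

    def _params(self) -> PAACParams:
        return self.params if self.params is not None else PAACParams()

    def _encode_one(self, rec: ProteinRecord) -> np.ndarray:
        params = self._params()
        rec = rec.sanitized()
        L = rec.length
        if L <= params.lam:
            raise EncodingError(
                f"record {rec.id!r}: length {L} must exceed lambda={params.lam}"
            )
        idx = _aa_index(rec.sequence)
        props = standardized_property_tables()[:, idx]  # 3 x L
        f = np.bincount(idx, minlength=20) / L

        thetas = np.empty(params.lam)
        for j in range(1, params.lam + 1):
            diffs = props[:, j:] - props[:, :-j]  # 3 x (L - j)
            thetas[j - 1] = np.mean(diffs**2, axis=0).sum() / (L - j)

        denom = f.sum() + params.omega * thetas.sum()
        return np.concatenate([f / denom, params.omega * thetas / denom])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        lam = self._params().lam
        return np.array(
            [f"paac_{a}" for a in AMINO_ACIDS]
            + [f"paac_theta{j}" for j in range(1, lam + 1)]
        )


class PSSMAutoCovarianceEncoder(_RecordEncoder):
    """Autocovariance of each PSSM column over lags 1..G.

    AC(j, g) = (1/(L-g)) * sum_i (P[i,j] - mean_j) * (P[i+g,j] - mean_j);
    output is ordered column-major over residues (j outer, g inner).
    Invariant to adding a constant to any column.
    """

    name = "pssm_ac"

    def __init__(self, G: int = 10, sigmoid: bool = False):
        self.G = G
        self.sigmoid = sigmoid

    def _encode_one(self, p: PSSMProfile) -> np.ndarray:
        L = p.length
        if L <= self.G:
            raise EncodingError(
                f"record {p.record_id!r}: length {L} must exceed lag bound G={self.G}"
            )
        m = _sigmoid(p.matrix) if self.sigmoid else p.matrix
        centered = m - m.mean(axis=0, keepdims=True)
        out = np.empty((20, self.G))
        for g in range(1, self.G + 1):
            out[:, g - 1] = (centered[:-g] * centered[g:]).sum(axis=0) / (L - g)
        return out.ravel()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [f"pssm_ac_{a}_g{g}" for a in PSSM_COLUMNS for g in range(1, self.G + 1)]
        )


def reduce_pssm(p: PSSMProfile, sigmoid: bool = False) -> np.ndarray:
    """Merge the 20 PSSM columns into 10 physicochemical residue groups (L x 10)."""
    m = _sigmoid(p.matrix) if sigmoid else p.matrix
    return np.stack([m[:, idx].mean(axis=1) for idx in _GROUP_INDICES], axis=1)


class RPSSMEncoder(_RecordEncoder):
    """Variance and adjacent-row descriptors of the 10-column reduced PSSM.

    E_j      = (1/L)     * sum_i (p[i,j] - mean_j)^2
    E_{j,t}  = (1/(L-1)) * sum_i (p[i,j] - p[i+1,t])^2 / 2
    Output order: [E_{1,1} .. E_{10,10}, E_1 .. E_10] (110 dims).
    """

    name = "rpssm"

    def __init__(self, sigmoid: bool = False):
        self.sigmoid = sigmoid

    def _encode_one(self, p: PSSMProfile) -> np.ndarray:
        L = p.length
        if L < 2:
            raise EncodingError(
                f"record {p.record_id!r}: RPSSM needs L >= 2 (adjacent-row terms)"
            )
        r = reduce_pssm(p, sigmoid=self.sigmoid)
        e_col = ((r - r.mean(axis=0, keepdims=True)) ** 2).mean(axis=0)
        # E_{j,t}: column j rows 1..L-1 against column t rows 2..L
        diffs = r[:-1, :, None] - r[1:, None, :]  # (L-1) x 10(j) x 10(t)
        e_pair = (diffs**2 / 2.0).mean(axis=0)
        return np.concatenate([e_pair.ravel(), e_col])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        pair = [f"rpssm_E{j}_{t}" for j in range(1, 11) for t in range(1, 11)]
        return np.array(pair + [f"rpssm_E{j}" for j in range(1, 11)])


class SSAPoolEncoder(_RecordEncoder):
    """Average pooling of an L x D per-residue embedding into a D-vector."""

    name = "ssa"

    def __init__(self, dim: int = 121):
        self.dim = dim

    def _encode_one(self, e: EmbeddingMatrix) -> np.ndarray:
        if e.dim != self.dim:
            raise EncodingError(
                f"record {e.record_id!r}: embedding dim {e.dim} != expected {self.dim}"
            )
        return e.matrix.mean(axis=0)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"ssa_{d}" for d in range(self.dim)])


# ---------------------------------------------------------------------------
# Soft sequence alignment


@dataclass
class SSAAlignment:
    """Soft-alignment attention matrices and similarity score between two embeddings.

    delta is the row softmax of negative L1 distances (each row sums to 1),
    epsilon the column softmax (each column sums to 1); alpha combines them as
    delta + epsilon - delta*epsilon. The score -(1/A) * sum alpha_ij * d_ij is
    a negative weighted mean distance, hence <= 0, and is symmetric in its
    two inputs.
    """

    delta: np.ndarray
    epsilon: np.ndarray
    alpha: np.ndarray
    A: float
    score: float


def ssa_similarity(p1: EmbeddingMatrix, p2: EmbeddingMatrix) -> SSAAlignment:
    """Soft-sequence-alignment similarity between two per-residue embeddings."""
    if p1.dim != p2.dim:
        raise ValueError(
            f"embedding dims differ: {p1.record_id!r} has {p1.dim}, "
            f"{p2.record_id!r} has {p2.dim}"
        )
    # pairwise L1 distances, L1 x L2
    dist = np.abs(p1.matrix[:, None, :] - p2.matrix[None, :, :]).sum(axis=2)
    delta = softmax(-dist, axis=1)
    epsilon = softmax(-dist, axis=0)
    alpha = delta + epsilon - delta * epsilon
    A = float(alpha.sum())
    score = float(-(alpha * dist).sum() / A)
    return SSAAlignment(delta=delta, epsilon=epsilon, alpha=alpha, A=A, score=score)


# ---------------------------------------------------------------------------
# Deterministic fallback embedder

class SequenceProjectionEmbedder:
    """Deterministic per-residue embedder: seeded random projection of one-hot
    residues followed by positional moving-average smoothing.

    Provides an L x D embedding for any sequence so the SSA code path works
    without external pretrained weights; it is not a learned language model.
    """

    def __init__(self, dim: int = 121, seed: int = 0, window: int = 5):
        self.dim = dim
        self.seed = seed
        self.window = window
        rng = np.random.default_rng(seed)
        self._projection = rng.standard_normal((20, dim)) / np.sqrt(dim)

    def embed(self, rec: ProteinRecord) -> EmbeddingMatrix:
        rec = rec.sanitized()
        if not rec.sequence:
            raise EncodingError(f"record {rec.id!r}: empty sequence after sanitization")
        raw = self._projection[_aa_index(rec.sequence)]  # L x D
        w = min(self.window, raw.shape[0])
        kernel = np.ones(w) / w
        smoothed = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, raw
        )
        return EmbeddingMatrix(rec.id, smoothed)


# ---------------------------------------------------------------------------
# Single-record wrappers and dataset-level encoding

@dataclass
class FeatureVector:
    """One encoded record: values with per-element names and encoder provenance."""

    record_id: str
    values: np.ndarray
    names: list[str]
    encoder: str


def _wrap(encoder: _RecordEncoder, record_id: str, x) -> FeatureVector:
    values = encoder.transform([x])[0]
    return FeatureVector(
        record_id=record_id,
        values=values,
        names=list(encoder.get_feature_names_out()),
        encoder=encoder.name,
    )


def encode_aac(rec: ProteinRecord) -> FeatureVector:
    return _wrap(AACEncoder(), rec.id, rec)


def encode_paac(rec: ProteinRecord, params: PAACParams | None = None) -> FeatureVector:
    return _wrap(PAACEncoder(params), rec.id, rec)


def encode_pssm_ac(p: PSSMProfile, G: int = 10, sigmoid: bool = False) -> FeatureVector:
    return _wrap(PSSMAutoCovarianceEncoder(G=G, sigmoid=sigmoid), p.record_id, p)


def encode_rpssm(p: PSSMProfile, sigmoid: bool = False) -> FeatureVector:
    return _wrap(RPSSMEncoder(sigmoid=sigmoid), p.record_id, p)


def ssa_pool(e: EmbeddingMatrix) -> FeatureVector:
    return _wrap(SSAPoolEncoder(dim=e.dim), e.record_id, e)


ENCODER_NAMES = ("aac", "paac", "pssm_ac", "rpssm", "ssa")


def encode_dataset(ds: LabeledDataset, encoder_name: str, **kwargs) -> FeatureMatrix:
    """Encode every record of a dataset with the named encoder.

    PSSM-based encoders require a profile for every record and the SSA encoder
    an embedding for every record; missing resources raise with the offending
    ids listed.
    """
    name = encoder_name.lower().replace("-", "_")
    if name in ("aac", "paac"):
        enc = AACEncoder() if name == "aac" else PAACEncoder(kwargs.get("params"))
        inputs = ds.records
    elif name in ("pssm_ac", "rpssm"):
        missing = [r.id for r in ds.records if r.id not in ds.pssms]
        if missing:
            raise ValueError(f"missing PSSM profiles for ids: {missing}")
        enc = (
            PSSMAutoCovarianceEncoder(**kwargs)
            if name == "pssm_ac"
            else RPSSMEncoder(**kwargs)
        )
        inputs = [ds.pssms[r.id] for r in ds.records]
    elif name == "ssa":
        missing = [r.id for r in ds.records if r.id not in ds.embeddings]
        if missing:
            raise ValueError(f"missing embeddings for ids: {missing}")
        dims = {ds.embeddings[r.id].dim for r in ds.records}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dims: {sorted(dims)}")
        enc = SSAPoolEncoder(dim=dims.pop())
        inputs = [ds.embeddings[r.id] for r in ds.records]
    else:
        raise ValueError(f"unknown encoder {encoder_name!r}; choose from {ENCODER_NAMES}")

    data = enc.transform(inputs)
    return FeatureMatrix(
        ids=ds.ids,
        data=data,
        columns=list(enc.get_feature_names_out()),
        encoder=name,
    )
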