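"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Greedy forward selection under the MID (difference) criterion: the first
feature maximizes mutual information with the label; each subsequent step
maximizes I(f; y) - mean_{s in selected} I(f; s). Continuous features are
discretized into equal-width bins before estimating mutual information;
binary labels are used as-is. Ties break toward the lower column index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.utils.validation import check_is_fitted, validate_data

from .records import FeatureMatrix


@dataclass
class SelectionResult:
    """An mRMR ranking: column indices in selection order with criterion scores."""

    ranked_indices: list[int]
    scores: list[float]
    k: int
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ranked_indices)) != len(self.ranked_indices):
            raise ValueError("ranked indices must be unique")
        if len(self.ranked_indices) != self.k:
            raise ValueError("ranking length must equal k")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, self.k + 1),
                "index": self.ranked_indices,
                "score": self.scores,
            }
        )
        if self.names is not None:
            df.insert(2, "name", self.names)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _discretize(X: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning per column; constant columns collapse to one bin."""
    out = np.zeros(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi > lo:
            edges = np.linspace(lo, hi, bins + 1)
            out[:, j] = np.clip(np.digitize(col, edges[1:-1]), 0, bins - 1)
    return out


class MRMRSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector performing greedy mRMR ranking (MID criterion).

    Parameters
    ----------
    k : int or None
        Number of features to select. None keeps all (full ranking).
    bins : int
        Equal-width bins used to discretize continuous features.
    cap : int or None
        If set, selection is applied only when n_features exceeds ``cap``;
        smaller matrices pass through unreduced (ranking still computed).
    """

    def __init__(self, k: int | None = None, bins: int = 10, cap: int | None = None):
        self.k = k
        self.bins = bins
        self.cap = cap

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if n < 4:
            raise ValueError("mRMR needs at least 4 samples")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        k = p if self.k is None else self.k
        if k > p:
            raise ValueError(f"k={k} exceeds n_features={p}")

        if self.cap is not None and p <= self.cap:
            self.passthrough_ = True
            self.ranking_ = list(range(p))
            self.scores_ = [float("nan")] * p
            return self
        self.passthrough_ = False

        Xd = _discretize(X, self.bins)
        relevance = np.array(
            [mutual_info_score(Xd[:, j], y) for j in range(p)]
        )

        selected: list[int] = []
        scores: list[float] = []
        # pairwise feature MI computed lazily, row per newly selected feature
        redundancy_sum = np.zeros(p)
        remaining = np.ones(p, dtype=bool)
        for step in range(k):
            if step == 0:
                criterion = relevance.copy()
            else:
                criterion = relevance - redundancy_sum / step
            criterion[~remaining] = -np.inf
            best = int(np.argmax(criterion))  # argmax takes the lowest index on ties
            selected.append(best)
            scores.append(float(criterion[best]))
            remaining[best] = False
            if step < k - 1:
                mi_best = np.array(
                    [
                        mutual_info_score(Xd[:, j], Xd[:, best]) if remaining[j] else 0.0
                        for j in range(p)
                    ]
                )
                redundancy_sum += mi_best

        self.ranking_ = selected
        self.scores_ = scores
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_] = True
        return mask


def mrmr_rank(fm: FeatureMatrix, labels, k: int, bins: int = 10) -> SelectionResult:
    """Rank ``k`` columns of a feature matrix by greedy mRMR (MID criterion)."""
    sel = MRMRSelector(k=k, bins=bins).fit(fm.data, np.asarray(labels))
    return SelectionResult(
        ranked_indices=list(sel.ranking_),
        scores=list(sel.scores_),
        k=k,
        names=[fm.columns[i] for i in sel.ranking_],
    )


def apply_selection(fm: FeatureMatrix, sel: SelectionResult) -> FeatureMatrix:
    """Reorder/subset feature columns per an mRMR ranking, names preserved."""
    return fm.subset_columns(sel.ranked_indices)


def select_features(
    fm: FeatureMatrix, labels, cap: int = 200, bins: int = 10
) -> FeatureMatrix:
    """Default policy: apply mRMR only when a matrix exceeds ``cap`` columns.

    Mirrors the study design where encoders at or below 200 dimensions pass
    through unreduced and larger ones are cut to 200.
    """
    if fm.shape[1] <= cap:
        return fm
    return apply_selection(fm, mrmr_rank(fm, labels, k=cap, bins=bins))
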