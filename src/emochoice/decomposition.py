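"""SVD-based PCA of demeaned emotion matrices.

The first two principal components of the within-subject-demeaned emotion
scores carry the classical affective-space interpretation: PC1 separates
unpleasant from pleasant responses (valence) and PC2 calm from energised
responses (arousal).  Because an SVD is only defined up to per-component sign,
components are deterministically oriented -- PC1 so that it correlates
positively with liking, the rest so that the strongest-loading item loads
positively -- before scores enter any downstream model.

Implemented directly on :func:`numpy.linalg.svd` rather than a library PCA:
the contract here is that scores are *exactly* ``X @ rotation`` with no hidden
re-centering, so a rotation learned on the training subjects can be applied
verbatim to a held-out subject's demeaned rows.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .preprocess import CenteredEmotionMatrix

__all__ = ["EmotionPCA", "fit_pca", "orient_signs", "project", "loading_stability"]


class EmotionPCA(BaseEstimator):
    """Full PCA of a column-centered matrix via singular value decomposition.

    Parameters
    ----------
    n_components : int or None
        Number of leading components exposed by :meth:`transform`.  The full
        decomposition is always retained internally.

    Attributes
    ----------
    rotation_ : ndarray of shape (n_items, n_components_full)
        Orthonormal loading matrix (right singular vectors), one column per
        component in decreasing singular-value order.
    scores_ : ndarray of shape (n_rows, n_components_full)
        Training-row scores, exactly ``X @ rotation_``.
    explained_variance_ratio_ : ndarray
        Per-component fraction of total variance; sums to 1, non-increasing.
    orientation_ : ndarray
        The +-1 sign applied to each component by :meth:`orient_signs`
        relative to the raw SVD output.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None) -> "EmotionPCA":
        X = self._coerce(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows for a PCA")
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        self.rotation_ = vt.T
        self.singular_values_ = s
        var = s**2
        total = var.sum()
        self.explained_variance_ratio_ = (var / total if total > 0
                                          else np.zeros_like(var))
        self.scores_ = X @ self.rotation_
        self.orientation_ = np.ones(self.rotation_.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _coerce(X) -> np.ndarray:
        if isinstance(X, CenteredEmotionMatrix):
            X = X.values
        return np.asarray(X, dtype=float)

    def _k(self) -> int:
        full = self.rotation_.shape[1]
        return full if self.n_components is None else min(self.n_components, full)

    def transform(self, X) -> np.ndarray:
        """Project new (already demeaned) rows: ``X @ rotation_[:, :k]``."""
        X = self._coerce(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"row length {X.shape[1]} does not match the {self.n_features_in_} "
                "items this rotation was fitted on")
        return X @ self.rotation_[:, :self._k()]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_[:, :self._k()]

    def orient_signs(self, liking) -> "EmotionPCA":
        """Return a copy with deterministic component signs.

        PC1 is flipped if its training scores correlate negatively with
        liking; every other component is flipped so that its
        largest-|loading| item has a positive loading (first index wins ties).
        """
        liking = np.asarray(liking, dtype=float)
        if liking.shape[0] != self.scores_.shape[0]:
            raise ValueError("liking vector must align with score rows")
        if np.std(liking) == 0.0:
            raise ValueError("liking has zero variance; cannot orient PC1")
        out = copy.deepcopy(self)
        flips = np.ones(out.rotation_.shape[1])
        pc1 = out.scores_[:, 0]
        if np.std(pc1) > 0 and np.corrcoef(pc1, liking)[0, 1] < 0:
            flips[0] = -1.0
        for j in range(1, out.rotation_.shape[1]):
            lead = np.argmax(np.abs(out.rotation_[:, j]))
            if out.rotation_[lead, j] < 0:
                flips[j] = -1.0
        out.rotation_ = out.rotation_ * flips
        out.scores_ = out.scores_ * flips
        out.orientation_ = self.orientation_ * flips
        return out

    def loadings_frame(self, emotion_names: Sequence[str], k: int = 2) -> pd.DataFrame:
        """Biplot-ready loadings table for the first ``k`` components."""
        return pd.DataFrame(self.rotation_[:, :k],
                            index=list(emotion_names),
                            columns=[f"pc{j + 1}" for j in range(k)])


def fit_pca(X, n_components: int | None = None) -> EmotionPCA:
    """Fit a full PCA on a demeaned matrix (thin wrapper over EmotionPCA)."""
    return EmotionPCA(n_components=n_components).fit(X)


def orient_signs(decomp: EmotionPCA, liking) -> EmotionPCA:
    return decomp.orient_signs(liking)


def project(decomp: EmotionPCA, new_rows) -> np.ndarray:
    return decomp.transform(new_rows)


def loading_stability(fold_decomps: Sequence[EmotionPCA],
                      emotion_names: Sequence[str],
                      n_components: int = 2) -> pd.DataFrame:
    """Mean and SD of per-item loadings across cross-validation folds.

    Quantifies how much the learned rotation wobbles when one subject is left
    out; small SDs relative to the mean loadings mean the valence/arousal axes
    are stable properties of the sample, not of individual subjects.  Folds
    must already be sign-oriented, otherwise arbitrary flips inflate the SDs.
    """
    if len(fold_decomps) < 2:
        raise ValueError("need at least 2 folds to compute loading stability")
    stack = np.stack([d.rotation_[:, :n_components] for d in fold_decomps])
    cols: dict[str, np.ndarray] = {}
    for j in range(n_components):
        cols[f"pc{j + 1}_mean"] = stack[:, :, j].mean(axis=0)
        cols[f"pc{j + 1}_sd"] = stack[:, :, j].std(axis=0, ddof=1)
    return pd.DataFrame(cols, index=list(emotion_names))
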