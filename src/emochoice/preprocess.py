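"""Within-subject demeaning and predictor standardization.

Each participant uses the 0-4 intensity scales differently (scale-use or
offset bias).  Removing, per participant, the mean score of every emotion item
across the product set leaves only within-participant variation *between
products*, which is the signal a choice model can use.  Predictors entering
the logit (liking, component scores) are additionally centered and scaled to
unit standard deviation so their slopes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import SUBJECT, PRODUCT, EmotionPanel

__all__ = [
    "CenteredEmotionMatrix",
    "demean_within_subject",
    "PredictorScaler",
    "fit_scaling",
    "apply_scaling",
]


@dataclass
class CenteredEmotionMatrix:
    """Demeaned trials x emotions matrix plus the per-subject means removed.

    ``values`` rows follow panel record order exactly; ``row_keys`` aligns each
    row with its (subject, product) pair; ``subject_means`` (subjects x
    emotions) is retained so held-out data can be treated identically.
    """

    values: np.ndarray
    row_keys: pd.DataFrame
    subject_means: pd.DataFrame
    emotion_names: list[str]

    def rows_for(self, subjects) -> np.ndarray:
        """Boolean row mask selecting the given subjects."""
        return self.row_keys[SUBJECT].isin(set(map(str, subjects))).to_numpy()


def demean_within_subject(panel: EmotionPanel) -> CenteredEmotionMatrix:
    """Remove each subject's own mean from every emotion column.

    After the operation the mean of each emotion over any one subject's rows
    is exactly zero, so any per-subject constant offset in the raw scores
    (scale-use bias) is eliminated.  Each subject is processed independently:
    demeaning a sub-panel equals slicing the demeaned full panel.
    """
    df = panel.data
    counts = df.groupby(SUBJECT, sort=False).size()
    bad = counts[counts != panel.n_alternatives]
    if len(bad):
        raise ValueError(
            f"within-subject demeaning needs {panel.n_alternatives} rows per "
            f"subject; violated by {list(bad.index)[:10]}")
    X = panel.emotion_matrix()
    means = df.groupby(SUBJECT, sort=False)[panel.emotion_names].transform("mean")
    centered = X - means.to_numpy(dtype=float)
    subject_means = (df.groupby(SUBJECT, sort=False)[panel.emotion_names]
                       .mean())
    return CenteredEmotionMatrix(
        values=centered,
        row_keys=df[[SUBJECT, PRODUCT]].reset_index(drop=True),
        subject_means=subject_means,
        emotion_names=list(panel.emotion_names),
    )


class PredictorScaler(BaseEstimator, TransformerMixin):
    """Center to mean 0 and scale to SD 1 with the n-1 denominator.

    A deliberate stand-in for the usual scaler: the sample-SD (ddof=1)
    convention matters when cross-checking slope estimates against R-based
    analyses, and zero-variance columns must fail loudly with the variable
    name rather than silently passing through.
    """

    def __init__(self, with_center: bool = True, with_scale: bool = True):
        self.with_center = with_center
        self.with_scale = with_scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit scaling")
        self.n_features_in_ = X.shape[1]
        self.center_ = X.mean(axis=0) if self.with_center else np.zeros(X.shape[1])
        scale = X.std(axis=0, ddof=1)
        if self.with_scale:
            zero = np.flatnonzero(scale == 0.0)
            if zero.size:
                raise ValueError(f"zero variance in column(s) {zero.tolist()}; "
                                 "cannot scale to unit SD")
            self.scale_ = scale
        else:
            self.scale_ = np.ones(X.shape[1])
        return self

    def transform(self, X):
        one_d = np.ndim(X) == 1
        X = np.asarray(X, dtype=float)
        if one_d:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} columns, got {X.shape[1]}")
        out = (X - self.center_) / self.scale_
        return out[:, 0] if one_d else out

    def inverse_transform(self, X):
        one_d = np.ndim(X) == 1
        X = np.asarray(X, dtype=float)
        if one_d:
            X = X[:, None]
        out = X * self.scale_ + self.center_
        return out[:, 0] if one_d else out


def fit_scaling(values) -> PredictorScaler:
    """Fit centering/scaling stats (mean, SD with n-1) on one or more columns."""
    return PredictorScaler().fit(values)


def apply_scaling(values, stats: PredictorScaler):
    """Apply previously fitted stats; a deterministic affine transform."""
    return stats.transform(values)


def scale_columns(df: pd.DataFrame, columns, stats: dict[str, PredictorScaler] | None = None
                  ) -> tuple[pd.DataFrame, dict[str, PredictorScaler]]:
    """Standardize named columns of a frame, fitting stats unless provided.

    Returns the transformed copy and the per-column stats used, so the same
    transform can be replayed on held-out rows.
    """
    out = df.copy()
    fitted: dict[str, PredictorScaler] = {}
    for col in columns:
        if stats is None:
            sc = PredictorScaler().fit(out[col].to_numpy())
        else:
            sc = stats[col]
        try:
            out[col] = sc.transform(out[col].to_numpy())
        except ValueError as err:
            raise ValueError(f"column {col!r}: {err}") from err
        fitted[col] = sc
    return out, fitted
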