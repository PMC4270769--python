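"""Leave-one-out cross-validated choice prediction with per-fold PCA.

Each fold holds one subject out.  The emotion PCA (and its sign orientation),
the predictor scaling, and the conditional logit are all re-learned on the
remaining ``n - 1`` subjects; the held-out subject contributes only their own
demeaned emotion rows, which are projected through the training rotation to
obtain component scores.  The fitted model then yields one choice probability
per product for the held-out subject, converted to ranks 1 (most likely) .. J
(least likely); the headline statistic is the share of subjects whose actually
chosen product got rank 1.

Within-subject demeaning uses the held-out subject's *own* product means:
the mean is available before any choice is made and demeaning is independent
across subjects, so this leaks nothing from training to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_model import ChoiceDesign, fit_conditional_logit
from .data_io import CHOSEN, LIKING, PRODUCT, SUBJECT, EmotionPanel
from .decomposition import EmotionPCA, fit_pca
from .preprocess import demean_within_subject, scale_columns

__all__ = ["RankPrediction", "RankDistribution", "loocv_predict",
           "predict_left_out", "probs_to_ranks", "rank_distribution"]


@dataclass
class RankPrediction:
    subject_id: str
    probs: np.ndarray
    ranks: np.ndarray
    chosen_rank: int
    chosen_product: str


@dataclass
class RankDistribution:
    """Percent of subjects whose chosen product landed at each predicted rank."""

    percent_at_rank: np.ndarray
    counts: np.ndarray
    n_subjects: int
    chance_level: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": np.arange(1, len(self.counts) + 1),
                             "count": self.counts,
                             "percent": self.percent_at_rank,
                             "chance_percent": self.chance_level})


@dataclass
class LoocvResult:
    predictions: list[RankPrediction]
    failures: list[tuple[str, str]]
    fold_decomps: list[EmotionPCA] = field(default_factory=list, repr=False)

    def distribution(self) -> RankDistribution:
        return rank_distribution(self.predictions)

    def predictions_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            row = {"subject": p.subject_id, "chosen_product": p.chosen_product,
                   "chosen_rank": p.chosen_rank}
            row.update({f"prob_{k}": v for k, v in
                        zip(range(1, len(p.probs) + 1), p.probs)})
            rows.append(row)
        return pd.DataFrame(rows)


def probs_to_ranks(probs) -> np.ndarray:
    """Rank alternatives by descending probability; 1 = most likely.

    Ties are broken by alternative order (A before B ...), which the stable
    sort provides for free.
    """
    probs = np.asarray(probs, dtype=float)
    if not np.isfinite(probs).all():
        raise ValueError("non-finite probabilities")
    order = np.argsort(-probs, kind="stable")
    ranks = np.empty(len(probs), dtype=int)
    ranks[order] = np.arange(1, len(probs) + 1)
    return ranks


def rank_distribution(predictions) -> RankDistribution:
    """Aggregate chosen-product ranks over subjects into percentages."""
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to aggregate")
    J = len(predictions[0].probs)
    counts = np.zeros(J, dtype=int)
    for p in predictions:
        counts[p.chosen_rank - 1] += 1
    pct = 100.0 * counts / counts.sum()
    return RankDistribution(percent_at_rank=pct, counts=counts,
                            n_subjects=len(predictions),
                            chance_level=100.0 / J)


def _predictor_frame(panel_df: pd.DataFrame, scores: np.ndarray,
                     predictors) -> pd.DataFrame:
    table = panel_df[[SUBJECT, PRODUCT]].copy()
    if CHOSEN in panel_df.columns:
        table[CHOSEN] = panel_df[CHOSEN].to_numpy()
    table["liking"] = panel_df[LIKING].to_numpy()
    for k in range(scores.shape[1]):
        table[f"pc{k + 1}"] = scores[:, k]
    return table


def predict_left_out(train_panel: EmotionPanel, test_rows: pd.DataFrame,
                     predictors=("liking", "pc1"), n_components: int = 2,
                     scaling: str = "fold", **fit_kwargs):
    """Fit one fold on ``train_panel`` and predict the held-out subject.

    ``test_rows`` are that subject's raw panel rows (one per alternative).
    Returns ``(probs, fitted_logit, oriented_decomposition)``.  This is the
    single-fold building block of :func:`loocv_predict`; the held-out subject
    appears nowhere in ``train_panel``, which makes the no-leakage contract
    directly testable.
    """
    if scaling not in ("fold", "global"):
        raise ValueError("scaling must be 'fold' or 'global'")
    alts = train_panel.alternatives
    test_rows = test_rows.sort_values(PRODUCT, kind="stable").reset_index(drop=True)
    if list(test_rows[PRODUCT].astype(str)) != list(alts):
        raise ValueError("held-out rows must cover the alternative set exactly once")

    centered_train = demean_within_subject(train_panel)
    decomp = (fit_pca(centered_train)
              .orient_signs(train_panel.data[LIKING].to_numpy()))
    test_emotions = test_rows[train_panel.emotion_names].to_numpy(dtype=float)
    test_centered = test_emotions - test_emotions.mean(axis=0, keepdims=True)
    test_scores = decomp.transform(test_centered)[:, :n_components]

    train_table = _predictor_frame(train_panel.data, decomp.scores_[:, :n_components],
                                   predictors)
    test_table = _predictor_frame(test_rows, test_scores, predictors)
    pred_cols = list(predictors)
    if scaling == "fold":
        # honest prediction: stats from the n-1 training subjects only
        train_table, stats = scale_columns(train_table, pred_cols)
        test_table, _ = scale_columns(test_table, pred_cols, stats=stats)
    else:
        # "global": stats from all n subjects of the fold (training + held-out),
        # mirroring a one-shot standardization of the whole sample
        pooled = pd.concat([train_table[pred_cols], test_table[pred_cols]],
                           ignore_index=True)
        _, stats = scale_columns(pooled, pred_cols)
        train_table, _ = scale_columns(train_table, pred_cols, stats=stats)
        test_table, _ = scale_columns(test_table, pred_cols, stats=stats)

    design = ChoiceDesign.from_frame(train_table, pred_cols, alts)
    fit = fit_conditional_logit(design, **fit_kwargs)
    test_X = test_table[pred_cols].to_numpy(dtype=float)[None, :, :]
    test_design = ChoiceDesign(test_X, np.zeros(1, dtype=int), list(alts), pred_cols)
    probs = fit.predict_proba(test_design)[0]
    return probs, fit, decomp


def loocv_predict(panel: EmotionPanel, predictors=("liking", "pc1"),
                  n_components: int = 2, scaling: str = "fold",
                  keep_decomps: bool = False, **fit_kwargs) -> LoocvResult:
    """Run the full leave-one-out cycle over every subject of ``panel``.

    Deterministic: subjects are processed in panel order and nothing in the
    pipeline is randomised.  A fold whose model fails to fit is recorded in
    ``failures`` and the run continues.
    """
    if not panel.has_choice:
        raise ValueError("LOOCV needs choice flags on the panel")
    chosen_by_subject = panel.chosen_products().astype(str)
    predictions: list[RankPrediction] = []
    failures: list[tuple[str, str]] = []
    decomps: list[EmotionPCA] = []
    for subject in panel.subjects:
        train = panel.drop_subject(subject)
        test_rows = panel.subject_rows(subject)
        try:
            probs, _, decomp = predict_left_out(
                train, test_rows, predictors=predictors,
                n_components=n_components, scaling=scaling, **fit_kwargs)
        except Exception as err:  # noqa: BLE001 - fold failures are data-driven
            failures.append((str(subject), f"{type(err).__name__}: {err}"))
            continue
        ranks = probs_to_ranks(probs)
        chosen_product = chosen_by_subject.loc[subject]
        j = panel.alternatives.index(chosen_product)
        predictions.append(RankPrediction(
            subject_id=str(subject), probs=probs, ranks=ranks,
            chosen_rank=int(ranks[j]), chosen_product=chosen_product))
        if keep_decomps:
            decomps.append(decomp)
    return LoocvResult(predictions=predictions, failures=failures,
                       fold_decomps=decomps)
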