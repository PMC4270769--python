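"""The seven-model comparison ladder and predictor diagnostics.

Seven conditional logit models of increasing complexity are fitted on the
same choosers and compared with likelihood-ratio tests in a stepwise forward
fashion:

====  =========================================
 id   alternative-varying predictors
====  =========================================
 1    liking
 2    valence (instrument A PC1)
 3    valence (instrument B PC1)
 4    liking + A PC1
 5    liking + B PC1
 6    liking + A PC1 + A PC2
 7    liking + B PC1 + B PC2
====  =========================================

Nested additions (2v4, 3v5, 4v6, 5v7) carry chi-square p-values and drive
selection; equal-size "replacement" pairs (1v2, 1v3, 4v5) are reported as raw
``2 dLL`` descriptively.  The selected model is the most complex one whose
addition step is significant at ``alpha``; if both instrument branches
qualify, the branch with the higher log-likelihood wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice_model import (ChoiceDesign, ConditionalLogit, ModelComparison,
                           fit_conditional_logit, fit_null, lr_test,
                           mcfadden_adj_r2)
from .data_io import CHOSEN, LIKING, PRODUCT, SUBJECT, EmotionPanel
from .decomposition import fit_pca
from .preprocess import demean_within_subject, scale_columns

__all__ = ["MODEL_PREDICTORS", "COMPARISON_PAIRS", "LadderResult",
           "build_predictor_table", "run_ladder", "extended_pc_scan",
           "predictor_correlations"]

MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("liking",),
    2: ("premo_pc1",),
    3: ("essense_pc1",),
    4: ("liking", "premo_pc1"),
    5: ("liking", "essense_pc1"),
    6: ("liking", "premo_pc1", "premo_pc2"),
    7: ("liking", "essense_pc1", "essense_pc2"),
}

#: the published comparison sequence (restricted id, full id)
COMPARISON_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (2, 4), (3, 5), (4, 5), (4, 6), (5, 7))

#: extra nested pairs computed for selection only: the combined models must
#: beat *both* single-predictor parents before they can win
_PARENT_PAIRS: tuple[tuple[int, int], ...] = ((1, 4), (1, 5))


def build_predictor_table(premo: EmotionPanel | None = None,
                          essense: EmotionPanel | None = None,
                          n_components: int = 2,
                          standardize: bool = True) -> pd.DataFrame:
    """Assemble the standardized predictor frame feeding the model ladder.

    For each supplied instrument panel: demean within subject, run the PCA,
    orient signs against liking, and attach the first ``n_components`` score
    columns as ``<instrument>_pc<k>``.  Liking is taken from whichever panel
    carries it first.  All predictor columns are centered and scaled to unit
    SD (n-1) over all trials unless ``standardize=False``.
    """
    panels = [(name, p) for name, p in (("premo", premo), ("essense", essense))
              if p is not None]
    if not panels:
        raise ValueError("at least one instrument panel is required")
    base_name, base = panels[0]
    table = base.data[[SUBJECT, PRODUCT, LIKING]].copy()
    if base.has_choice:
        table[CHOSEN] = base.data[CHOSEN].to_numpy()
    table["liking"] = table.pop(LIKING)
    predictors = ["liking"]
    for name, panel in panels:
        if panel.data[[SUBJECT, PRODUCT]].astype(str).to_numpy().tolist() != \
           table[[SUBJECT, PRODUCT]].astype(str).to_numpy().tolist():
            raise ValueError(f"panel {name!r} rows are not aligned with the first panel")
        centered = demean_within_subject(panel)
        decomp = fit_pca(centered).orient_signs(panel.data[LIKING].to_numpy())
        scores = decomp.scores_[:, :n_components]
        for k in range(n_components):
            col = f"{name}_pc{k + 1}"
            table[col] = scores[:, k]
            predictors.append(col)
    if standardize:
        table, _ = scale_columns(table, predictors)
    return table


@dataclass
class LadderResult:
    fits: dict[int, ConditionalLogit]
    null_fit: ConditionalLogit
    comparisons: dict[str, ModelComparison]
    fit_quality: dict[int, float]
    best_model: int
    alpha: float = 0.05
    designs: dict[int, ChoiceDesign] = field(default_factory=dict, repr=False)

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for key, c in self.comparisons.items():
            rows.append({"comparison": key, "chi2": c.chi2, "df": c.df,
                         "p": np.nan if c.p is None else c.p, "nested": c.nested})
        return pd.DataFrame(rows)

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for mid, fit in self.fits.items():
            rows.append({"model": mid,
                         "predictors": "+".join(MODEL_PREDICTORS.get(mid, ())),
                         "loglik": fit.loglik_, "n_params": fit.n_params_,
                         "mcfadden_adj_r2": self.fit_quality[mid]})
        return pd.DataFrame(rows)


def _design(table: pd.DataFrame, predictors: tuple[str, ...],
            alternatives=None) -> ChoiceDesign:
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise ValueError(f"predictor columns {missing} not available; "
                         "supply the corresponding instrument panel")
    return ChoiceDesign.from_frame(table, list(predictors), alternatives)


def run_ladder(table: pd.DataFrame, alpha: float = 0.05,
               mcfadden_penalty: str = "all") -> LadderResult:
    """Fit every available ladder model and run the published comparison sequence.

    ``table`` is the standardized predictor frame from
    :func:`build_predictor_table`; models whose predictors are absent (single
    instrument supplied) are silently dropped along with their comparisons.
    """
    available = {mid: preds for mid, preds in MODEL_PREDICTORS.items()
                 if all(c in table.columns for c in preds)}
    fits: dict[int, ConditionalLogit] = {}
    designs: dict[int, ChoiceDesign] = {}
    for mid, preds in available.items():
        designs[mid] = _design(table, preds)
        fits[mid] = fit_conditional_logit(designs[mid])
    null_fit = fit_null(next(iter(designs.values())))
    quality = {mid: mcfadden_adj_r2(fit, null_fit, penalty=mcfadden_penalty)
               for mid, fit in fits.items()}
    comparisons: dict[str, ModelComparison] = {}
    for a, b in COMPARISON_PAIRS + _PARENT_PAIRS:
        if a in fits and b in fits:
            comparisons[f"{a}v{b}"] = lr_test(fits[a], fits[b], label=f"{a}v{b}")
    best = _select(fits, comparisons, alpha)
    return LadderResult(fits=fits, null_fit=null_fit, comparisons=comparisons,
                        fit_quality=quality, best_model=best, alpha=alpha,
                        designs=designs)


def _select(fits, comparisons, alpha) -> int:
    """Most complex model every one of whose nested addition steps is significant.

    A combined model must improve on both of its single-predictor parents
    (liking-only and valence-only); the PC2 models must additionally improve
    on the combined model.  When both instrument branches qualify the higher
    log-likelihood wins; when neither does, the liking-only baseline stands.
    """
    def sig(a, b):
        c = comparisons.get(f"{a}v{b}")
        return c is not None and c.nested and c.p is not None and c.p < alpha

    candidates = []
    for combined, parents, pc2_step in ((4, ((1, 4), (2, 4)), (4, 6)),
                                        (5, ((1, 5), (3, 5)), (5, 7))):
        if combined in fits and all(sig(*pair) for pair in parents):
            winner = pc2_step[1] if sig(*pc2_step) and pc2_step[1] in fits \
                else combined
            candidates.append(winner)
    if not candidates:
        return 1
    return max(candidates, key=lambda mid: fits[mid].loglik_)


def extended_pc_scan(panel: EmotionPanel, max_components: int,
                     base_predictors: tuple[str, ...] = ("liking", "pc1"),
                     alpha: float = 0.05) -> list[tuple[str, ModelComparison]]:
    """Greedy forward scan over higher-order components of one instrument.

    Starting from the base model, components ``pc2..pc<max_components>`` are
    added one at a time, each step picking the candidate with the largest
    likelihood-ratio improvement; every accepted step's test is reported in
    order.  ``max_components=1`` yields an empty scan.
    """
    centered = demean_within_subject(panel)
    decomp = fit_pca(centered)
    if max_components > decomp.rotation_.shape[1]:
        raise ValueError(f"only {decomp.rotation_.shape[1]} components available")
    decomp = decomp.orient_signs(panel.data[LIKING].to_numpy())
    table = panel.data[[SUBJECT, PRODUCT, CHOSEN]].copy()
    table["liking"] = panel.data[LIKING].to_numpy()
    cols = ["liking"]
    for k in range(max_components):
        col = f"pc{k + 1}"
        table[col] = decomp.scores_[:, k]
        cols.append(col)
    table, _ = scale_columns(table, cols)

    current = [c for c in base_predictors if c in table.columns]
    pool = [f"pc{k + 1}" for k in range(1, max_components) if f"pc{k + 1}" not in current]
    current_fit = fit_conditional_logit(_design(table, tuple(current)))
    results: list[tuple[str, ModelComparison]] = []
    while pool:
        trials = []
        for cand in pool:
            fit = fit_conditional_logit(_design(table, tuple(current + [cand])))
            trials.append((cand, fit, lr_test(current_fit, fit, label=f"+{cand}")))
        cand, fit, comp = max(trials, key=lambda t: t[2].chi2)
        results.append((cand, comp))
        current.append(cand)
        current_fit = fit
        pool.remove(cand)
    return results


def predictor_correlations(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix among the model predictors."""
    if columns is None:
        columns = [c for c in table.columns
                   if c == "liking" or "_pc" in c or c.startswith("pc")]
    sub = table[list(columns)].astype(float)
    sd = sub.std(ddof=1)
    dead = list(sd.index[sd == 0.0])
    if dead:
        raise ValueError(f"zero variance in predictor(s) {dead}")
    return sub.corr(method="pearson")
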