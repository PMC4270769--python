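"""Conditional (multinomial) logit choice models and their fit statistics.

The model: chooser *i* facing alternatives ``j = 1..J`` picks *j* with
probability ``P_ij = exp(V_ij) / sum_k exp(V_ik)`` where the systematic
utility ``V_ij = alpha_j + x_ij' beta`` combines alternative-specific
constants (ASCs, reference alternative fixed at 0) with alternative-varying
covariates such as standardized liking and emotion-component scores.  The
log-likelihood is globally concave in ``(beta, alpha)``, so a cold-started
Newton-Raphson with the analytic gradient and Hessian converges to the unique
maximum.

Alongside the estimator this module implements the inference toolkit used to
compare choice models: likelihood-ratio tests, McFadden's adjusted pseudo-r2
against the ASC-only null, and the Hausman-McFadden specification test of the
independence-of-irrelevant-alternatives (IIA) assumption, which refits the
model with one alternative removed and measures how far the common parameter
estimates move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .data_io import CHOSEN, PRODUCT, SUBJECT

__all__ = [
    "ChoiceDesign",
    "ConditionalLogit",
    "ModelComparison",
    "SeparationError",
    "ConvergenceError",
    "log_likelihood",
    "fit_conditional_logit",
    "predict_probs",
    "lr_test",
    "mcfadden_adj_r2",
    "hausman_mcfadden",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to reach the gradient tolerance."""


class SeparationError(ConvergenceError):
    """Parameters diverge while the likelihood keeps improving: some covariate
    perfectly predicts choice and the MLE does not exist."""


@dataclass
class ChoiceDesign:
    """One chooser x J alternatives with alternative-varying covariates.

    ``X`` has shape (n_choosers, n_alternatives, n_covariates) -- it may have
    zero covariates for the ASC-only null model -- and ``chosen`` holds the
    index of the picked alternative per chooser.
    """

    X: np.ndarray
    chosen: np.ndarray
    alternatives: list[str]
    covariate_names: list[str] = field(default_factory=list)
    chooser_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.chosen = np.asarray(self.chosen, dtype=int)
        if self.X.ndim != 3:
            raise ValueError("X must be (n_choosers, n_alternatives, n_covariates)")
        n, J, p = self.X.shape
        if J != len(self.alternatives):
            raise ValueError("alternative labels do not match X")
        if self.covariate_names and len(self.covariate_names) != p:
            raise ValueError("covariate names do not match X")
        if self.chosen.shape != (n,):
            raise ValueError("chosen must hold one index per chooser")
        if n and ((self.chosen < 0) | (self.chosen >= J)).any():
            raise ValueError("chosen indices out of range")
        if self.chooser_ids is None:
            self.chooser_ids = np.arange(n)
        else:
            self.chooser_ids = np.asarray(self.chooser_ids)
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite covariate values")

    @property
    def n_choosers(self) -> int:
        return self.X.shape[0]

    @property
    def n_alternatives(self) -> int:
        return self.X.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, covariates: Sequence[str],
                   alternatives: Sequence[str] | None = None) -> "ChoiceDesign":
        """Build a design from a long frame with subject/product/chosen columns.

        Rows are pivoted to one chooser per design row; alternatives are
        ordered lexicographically unless given explicitly.
        """
        products = df[PRODUCT].astype(str)
        alts = sorted(products.unique()) if alternatives is None else list(alternatives)
        subjects = list(dict.fromkeys(df[SUBJECT]))
        n, J, p = len(subjects), len(alts), len(covariates)
        sub_codes = pd.Categorical(df[SUBJECT], categories=subjects).codes
        alt_codes = pd.Categorical(products, categories=alts).codes
        if (sub_codes < 0).any() or (alt_codes < 0).any():
            raise ValueError("rows outside the declared alternative set")
        X = np.full((n, J, p), np.nan)
        X[sub_codes, alt_codes, :] = df[list(covariates)].to_numpy(dtype=float)
        chosen = np.full(n, -1, dtype=int)
        if CHOSEN in df.columns:
            hit = df[CHOSEN].to_numpy() == 1
            chosen[sub_codes[hit]] = alt_codes[hit]
        if (chosen < 0).any():
            missing = [subjects[i] for i in np.flatnonzero(chosen < 0)]
            raise ValueError(f"no chosen alternative for subjects {missing[:10]}")
        if np.isnan(X).any():
            raise ValueError("incomplete covariate block (missing subject x product rows)")
        return cls(X, chosen, alts, list(covariates), np.asarray(subjects, dtype=object))

    def subset(self, mask) -> "ChoiceDesign":
        mask = np.asarray(mask, dtype=bool)
        return ChoiceDesign(self.X[mask], self.chosen[mask], list(self.alternatives),
                            list(self.covariate_names), self.chooser_ids[mask])

    def drop_alternative(self, alternative: str) -> "ChoiceDesign":
        """Remove one alternative and the choosers who picked it."""
        j = self.alternatives.index(alternative)
        keep_choosers = self.chosen != j
        if not keep_choosers.any():
            raise ValueError(f"every chooser picked {alternative!r}; nothing left")
        keep_alts = [k for k in range(self.n_alternatives) if k != j]
        new_chosen = self.chosen[keep_choosers].copy()
        new_chosen[new_chosen > j] -= 1
        return ChoiceDesign(self.X[np.ix_(keep_choosers, keep_alts)], new_chosen,
                            [self.alternatives[k] for k in keep_alts],
                            list(self.covariate_names),
                            self.chooser_ids[keep_choosers])


def _augment(design: ChoiceDesign, include_asc: bool, reference: int) -> np.ndarray:
    """Stack ASC one-hot columns after the covariates: Z is (n, J, p + J - 1)."""
    n, J, p = design.X.shape
    if not include_asc:
        return design.X
    asc = np.zeros((J, J - 1))
    cols = [j for j in range(J) if j != reference]
    for c, j in enumerate(cols):
        asc[j, c] = 1.0
    Z = np.concatenate([design.X, np.broadcast_to(asc, (n, J, J - 1))], axis=2)
    return Z


def _ll_grad_hess(theta: np.ndarray, Z: np.ndarray, chosen: np.ndarray):
    """Log-likelihood with analytic gradient and Hessian, overflow-safe."""
    U = Z @ theta                      # (n, J)
    lse = logsumexp(U, axis=1)
    ll = float((U[np.arange(len(chosen)), chosen] - lse).sum())
    P = np.exp(U - lse[:, None])       # (n, J)
    Zc = Z[np.arange(len(chosen)), chosen, :]
    M = np.einsum("nj,njq->nq", P, Z)  # expected covariate per chooser
    grad = (Zc - M).sum(axis=0)
    H = -(np.einsum("nj,njq,njr->qr", P, Z, Z) - M.T @ M)
    return ll, grad, H


def log_likelihood(params, design: ChoiceDesign, include_asc: bool = True,
                   reference: int = 0):
    """Evaluate the conditional-logit log-likelihood at arbitrary parameters.

    ``params`` is the stacked vector ``[beta, alpha_nonref]``.  Returns
    ``(loglik, gradient, hessian)``.
    """
    Z = _augment(design, include_asc, reference)
    theta = np.asarray(params, dtype=float)
    if theta.shape != (Z.shape[2],):
        raise ValueError(f"expected {Z.shape[2]} parameters, got {theta.shape}")
    return _ll_grad_hess(theta, Z, design.chosen)


class ConditionalLogit(BaseEstimator):
    """Maximum-likelihood conditional logit with alternative-specific constants.

    Parameters
    ----------
    include_asc : bool
        Estimate a constant per non-reference alternative.
    reference : int
        Index of the reference alternative whose constant is fixed at zero.
    tol : float
        Convergence tolerance on the infinity norm of the score vector.
    max_iter : int
        Newton-Raphson iteration cap.
    param_bound : float
        Parameter-norm bound beyond which (quasi-)separation is declared.

    Attributes (after :meth:`fit`)
    ------------------------------
    beta_, asc_, params_, loglik_, vcov_, se_, n_params_, converged_, n_iter_
    """

    def __init__(self, include_asc: bool = True, reference: int = 0,
                 tol: float = 1e-8, max_iter: int = 100, param_bound: float = 50.0):
        self.include_asc = include_asc
        self.reference = reference
        self.tol = tol
        self.max_iter = max_iter
        self.param_bound = param_bound

    def fit(self, design: ChoiceDesign, start: np.ndarray | None = None
            ) -> "ConditionalLogit":
        Z_full = _augment(design, self.include_asc, self.reference)
        # a column with no within-chooser variation cannot move any choice
        # probability; its slope is structurally zero and is excluded from the
        # optimization rather than left to blow up the Hessian
        Zc = Z_full - Z_full.mean(axis=1, keepdims=True)
        colnorm = np.sqrt((Zc**2).sum(axis=(0, 1)))
        active = colnorm > 1e-10 * max(1.0, colnorm.max())
        Z = Z_full[:, :, active]
        q = Z.shape[2]
        if start is None:
            theta = np.zeros(q)
        else:
            start = np.asarray(start, dtype=float)
            theta = start[active] if start.shape[0] == Z_full.shape[2] else start
        ll, grad, H = _ll_grad_hess(theta, Z, design.chosen)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                it -= 1
                break
            try:
                step = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(
                    "singular Hessian -- covariates are likely collinear "
                    "(or an alternative is never chosen)") from err
            # damped Newton: concavity makes full steps safe almost always,
            # but halve on the rare overshoot
            scale = 1.0
            for _ in range(40):
                cand = theta + scale * step
                ll_new, grad_new, H_new = _ll_grad_hess(cand, Z, design.chosen)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            theta, ll, grad, H = cand, ll_new, grad_new, H_new
            if np.linalg.norm(theta) > self.param_bound:
                raise SeparationError(
                    "parameter norm exceeds bound while the likelihood still "
                    "improves; a covariate separates the choices perfectly")
        else:
            if np.max(np.abs(grad)) < self.tol:
                converged = True
        if not converged and np.max(np.abs(grad)) >= self.tol:
            raise ConvergenceError(
                f"no convergence in {self.max_iter} iterations "
                f"(|grad|_inf = {np.max(np.abs(grad)):.3g})")
        # the MLE does not exist when the supremum of the LL is 0 (every
        # observed choice predicted with probability 1); Newton then stalls on
        # a flat plateau and "converges" at huge parameter values
        if ll > -1e-6 * max(design.n_choosers, 1):
            raise SeparationError(
                "all observed choices are predicted with probability ~1; "
                "a covariate separates the choices perfectly")

        p = design.n_covariates
        J = design.n_alternatives
        self.design_info_ = {
            "alternatives": list(design.alternatives),
            "covariate_names": list(design.covariate_names),
            "chooser_ids": np.asarray(design.chooser_ids),
        }
        full_theta = np.zeros(Z_full.shape[2])
        full_theta[active] = theta
        self.params_ = full_theta
        self.active_params_ = active
        self.beta_ = full_theta[:p]
        asc = np.zeros(J)
        if self.include_asc:
            k = 0
            for j in range(J):
                if j != self.reference:
                    asc[j] = full_theta[p + k]
                    k += 1
        self.asc_ = asc
        self.loglik_ = ll
        self.n_params_ = int(active.sum())
        self.n_choosers_ = design.n_choosers
        self.converged_ = converged
        self.n_iter_ = it
        try:
            vcov_active = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov_active = np.linalg.pinv(-H)
        vcov = np.full((len(full_theta), len(full_theta)), 0.0)
        vcov[np.ix_(active, active)] = vcov_active
        inactive = ~active
        vcov[np.diag_indices_from(vcov)] = np.where(inactive, np.inf, np.diag(vcov))
        self.vcov_ = vcov
        self.se_ = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        return self

    # -- inference helpers ----------------------------------------------
    def wald_pvalues(self) -> np.ndarray:
        """Two-sided normal-approximation p-values for all parameters."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params_ / self.se_
        return 2.0 * stats.norm.sf(np.abs(z))

    def predict_proba(self, design: ChoiceDesign) -> np.ndarray:
        """Per-chooser choice-probability vectors; rows sum to one."""
        if design.n_covariates != len(self.beta_):
            raise ValueError("covariate count differs from the fitted model")
        Z = _augment(design, self.include_asc, self.reference)
        U = Z @ self.params_
        return np.exp(U - logsumexp(U, axis=1)[:, None])

    def summary_frame(self) -> pd.DataFrame:
        names = list(self.design_info_["covariate_names"])
        names += [f"asc_{a}" for j, a in enumerate(self.design_info_["alternatives"])
                  if self.include_asc and j != self.reference]
        return pd.DataFrame({"estimate": self.params_, "se": self.se_,
                             "p": self.wald_pvalues()}, index=names)


def fit_conditional_logit(design: ChoiceDesign, include_asc: bool = True,
                          **kwargs) -> ConditionalLogit:
    return ConditionalLogit(include_asc=include_asc, **kwargs).fit(design)


def predict_probs(fit: ConditionalLogit, design: ChoiceDesign) -> np.ndarray:
    return fit.predict_proba(design)


def fit_null(design: ChoiceDesign, **kwargs) -> ConditionalLogit:
    """ASC-only null model on the same choosers (market-share model)."""
    empty = ChoiceDesign(design.X[:, :, :0], design.chosen, list(design.alternatives),
                         [], design.chooser_ids)
    return ConditionalLogit(include_asc=True, **kwargs).fit(empty)


@dataclass
class ModelComparison:
    """A likelihood-based comparison between two fitted models.

    For nested pairs ``chi2 = 2 (LL_full - LL_restricted)`` follows a
    chi-square with ``df`` equal to the parameter-count difference.  For
    same-size "replacement" pairs the statistic is reported descriptively
    with ``nested=False`` and no p-value.
    """

    chi2: float
    df: int
    p: float | None
    nested: bool
    label: str = ""


def lr_test(fit_restricted: ConditionalLogit, fit_full: ConditionalLogit,
            force_p: bool = False, label: str = "") -> ModelComparison:
    """Likelihood-ratio comparison of two fits on the same choosers.

    ``force_p`` assigns a chi-square(df=1) p-value even when the models are
    not nested (df = 0), reproducing the treatment of replacement comparisons
    in some published analyses; off by default.
    """
    a = np.asarray(fit_restricted.design_info_["chooser_ids"])
    b = np.asarray(fit_full.design_info_["chooser_ids"])
    if a.shape != b.shape or (a != b).any():
        raise ValueError("fits were not estimated on the same choosers")
    chi2 = 2.0 * (fit_full.loglik_ - fit_restricted.loglik_)
    df = fit_full.n_params_ - fit_restricted.n_params_
    nested = df > 0
    if nested:
        p = float(stats.chi2.sf(chi2, df))
    elif force_p:
        p = float(stats.chi2.sf(abs(chi2), max(df, 1)))
    else:
        p = None
    return ModelComparison(chi2=float(chi2), df=df, p=p, nested=nested, label=label)


def mcfadden_adj_r2(fit: ConditionalLogit, null_fit: ConditionalLogit,
                    penalty: str = "all") -> float:
    """McFadden's adjusted pseudo-r2: ``1 - (LL - K) / LL_null``.

    ``penalty`` chooses what K counts: ``"all"`` (default) every estimated
    parameter including ASCs, ``"slopes"`` only the covariate slopes --
    software conventions differ and published values rarely say which was
    used.
    """
    if null_fit.loglik_ == 0.0:
        raise ValueError("null log-likelihood is zero")
    if penalty == "all":
        k = fit.n_params_
    elif penalty == "slopes":
        k = len(fit.beta_)
    else:
        raise ValueError(f"unknown penalty convention {penalty!r}")
    return 1.0 - (fit.loglik_ - k) / null_fit.loglik_


@dataclass
class HausmanResult(ModelComparison):
    removed_alternative: str = ""
    positive_definite: bool = True


def hausman_mcfadden(design: ChoiceDesign, removed_alternative: str,
                     include_asc: bool = True, **fit_kwargs) -> HausmanResult:
    """Hausman-McFadden IIA specification test.

    Under IIA, dropping one alternative (and the choosers who picked it)
    should leave the remaining parameters consistent, so
    ``q = d' (V_r - V_f)^{-1} d`` with ``d`` the difference of the common
    parameter estimates is asymptotically chi-square with df = number of
    common parameters.  When the variance difference is not positive definite
    (common in finite samples) the Moore-Penrose pseudo-inverse is used and a
    warning is emitted.
    """
    # reference must survive the removal so both fits share a parameterization
    ref = next(k for k, a in enumerate(design.alternatives) if a != removed_alternative)
    full = ConditionalLogit(include_asc=include_asc, reference=ref, **fit_kwargs).fit(design)
    restricted_design = design.drop_alternative(removed_alternative)
    r_ref = restricted_design.alternatives.index(design.alternatives[ref])
    restricted = ConditionalLogit(include_asc=include_asc, reference=r_ref,
                                  **fit_kwargs).fit(restricted_design)

    p = design.n_covariates
    common_full = list(range(p))
    common_restr = list(range(p))
    if include_asc:
        full_asc_alts = [a for k, a in enumerate(design.alternatives) if k != ref]
        restr_asc_alts = [a for k, a in enumerate(restricted_design.alternatives)
                          if k != r_ref]
        for a in restr_asc_alts:
            common_full.append(p + full_asc_alts.index(a))
            common_restr.append(p + restr_asc_alts.index(a))
    d = restricted.params_[common_restr] - full.params_[common_full]
    V = (restricted.vcov_[np.ix_(common_restr, common_restr)]
         - full.vcov_[np.ix_(common_full, common_full)])
    eigvals = np.linalg.eigvalsh((V + V.T) / 2.0)
    pd_ok = bool(eigvals.min() > 0)
    if pd_ok:
        q = float(d @ np.linalg.solve(V, d))
    else:
        warnings.warn("Hausman variance difference is not positive definite; "
                      "using a pseudo-inverse", RuntimeWarning, stacklevel=2)
        q = float(d @ np.linalg.pinv(V) @ d)
    q = max(q, 0.0)
    df = len(d)
    return HausmanResult(chi2=q, df=df, p=float(stats.chi2.sf(q, df)), nested=True,
                         label=f"IIA remove {removed_alternative}",
                         removed_alternative=removed_alternative,
                         positive_definite=pd_ok)
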