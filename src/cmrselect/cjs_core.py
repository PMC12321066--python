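"""Cormack-Jolly-Seber survival models with individual trait covariates.

The model conditions on each individual's first capture and describes the
subsequent detections.  Detection probability ``p`` is constant over time and
individuals; apparent survival is constant over time but may depend on a
per-individual covariate through a logit link::

    logit(phi_i) = beta0 + beta1 * x_i

An individual first caught at occasion ``f`` and last seen at occasion ``l``
contributes

    sum_{t=f+1..l} [ log phi_i + h_t log p + (1 - h_t) log(1 - p) ]
        + log chi_l

where ``h_t`` is the detection indicator and ``chi_t`` — the probability of
never being seen after ``t`` — satisfies the backward recursion
``chi_T = 1``, ``chi_t = (1 - phi) + phi (1 - p) chi_{t+1}``.

Fitting maximizes the joint log-likelihood over the unconstrained
``(beta, logit p)`` scale with analytic gradients and a small multi-start;
standard errors come from the inverse observed information.  Trait models are
compared against an intercept-only null by AIC, with the null refit on
exactly the individuals entering the trait model (likelihoods on different
data are not comparable).  Time intervals are treated as equal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from . import trait_prep
from .capture_io import Dataset, EncounterHistory, build_histories

logger = logging.getLogger(__name__)

SELECTORS = ("first", "median", "last")

_TINY = 1e-300


class CJSError(ValueError):
    """Raised for invalid model inputs."""


@dataclass
class CJSParams:
    """Parameters on the unconstrained scale: survival betas and logit-p."""

    beta: np.ndarray
    p_logit: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)) or not np.isfinite(self.p_logit):
            raise CJSError("parameters must be finite")

    def phi(self, x: float | np.ndarray = 0.0) -> float | np.ndarray:
        """Survival probability at covariate value(s) ``x``."""
        eta = self.beta[0] + (self.beta[1] * np.asarray(x) if self.beta.size > 1 else 0.0)
        out = expit(eta)
        return float(out) if np.ndim(out) == 0 else out

    @property
    def p(self) -> float:
        return float(expit(self.p_logit))


@dataclass
class CJSFit:
    """Maximum-likelihood fit: parameters, log-likelihood, AIC, uncertainty."""

    params: CJSParams
    logL: float
    k: int
    AIC: float
    se: np.ndarray | None  # on the (beta, logit p) scale; None if information singular
    converged: bool
    n_histories: int
    identifiable: bool  # False when the data contain no recaptures at all

    @property
    def phi_hat(self) -> float:
        """Fitted survival at covariate 0 (the mean, for standardized covariates)."""
        return self.params.phi(0.0)

    @property
    def p_hat(self) -> float:
        return self.params.p

    @property
    def phi_se(self) -> float | None:
        """Delta-method SE of phi at covariate 0 (intercept-only models)."""
        if self.se is None or self.params.beta.size != 1:
            return None
        return float(self.se[0] * self.phi_hat * (1.0 - self.phi_hat))

    @property
    def p_se(self) -> float | None:
        if self.se is None:
            return None
        return float(self.se[-1] * self.p_hat * (1.0 - self.p_hat))


def chi_vector(phi: float, p: float, first: int, T: int) -> np.ndarray:
    """Probabilities of never being seen after occasions ``first..T``.

    Returns an array ``chi`` with ``chi[i]`` the probability for occasion
    ``first + i``; ``chi[-1]`` (occasion T) is 1 by definition.
    """
    if not (0.0 <= phi <= 1.0 and 0.0 <= p <= 1.0):
        raise CJSError("phi and p must lie in [0, 1]")
    if not 1 <= first <= T:
        raise CJSError("first must lie in 1..T")
    chi = np.ones(T - first + 1)
    for i in range(len(chi) - 2, -1, -1):
        chi[i] = (1.0 - phi) + phi * (1.0 - p) * chi[i + 1]
    return chi


def history_loglik(h: EncounterHistory, phi_i: float, p: float) -> float:
    """Log-probability of one history's post-release detections.

    Scalar reference implementation of the conditional CJS likelihood; the
    vectorized :func:`dataset_loglik` must agree with it.
    """
    if not (0.0 < phi_i < 1.0 and 0.0 < p < 1.0):
        raise CJSError("phi and p must lie strictly inside (0, 1)")
    T = len(h.detections)
    f, l = h.first, h.last
    ll = 0.0
    for t in range(f + 1, l + 1):
        ll += math.log(phi_i)
        ll += math.log(p) if h.detections[t - 1] else math.log(1.0 - p)
    ll += math.log(chi_vector(phi_i, p, l, T)[0])
    return ll


def _suff_stats(histories: Sequence[EncounterHistory]):
    """Per-history sufficient statistics for the conditional likelihood."""
    if not histories:
        raise CJSError("no histories supplied")
    T = len(histories[0].detections)
    if any(len(h.detections) != T for h in histories):
        raise CJSError("histories differ in length")
    f = np.array([h.first for h in histories])
    l = np.array([h.last for h in histories])
    d = np.array([sum(h.detections[h.first:h.last]) for h in histories])  # detections after first
    s = l - f  # survival intervals up to last detection
    m = s - d  # misses between first and last
    return f, l, s, d, m, T


def _nll_grad(theta: np.ndarray, X: np.ndarray, s, d, m, l_idx, T: int):
    """Negative log-likelihood and analytic gradient, vectorized over histories."""
    kb = X.shape[1]
    beta = theta[:kb]
    zeta = theta[kb]
    eta = X @ beta
    phi = expit(eta)
    p = float(expit(zeta))
    n = X.shape[0]

    chi = np.ones((n, T))
    A = np.zeros((n, T))  # d chi / d phi
    B = np.zeros((n, T))  # d chi / d p
    q = 1.0 - p
    for t in range(T - 2, -1, -1):
        A[:, t] = -1.0 + q * chi[:, t + 1] + phi * q * A[:, t + 1]
        B[:, t] = -phi * chi[:, t + 1] + phi * q * B[:, t + 1]
        chi[:, t] = (1.0 - phi) + phi * q * chi[:, t + 1]

    rows = np.arange(n)
    chi_l = np.maximum(chi[rows, l_idx], _TINY)
    ll = (
        s * log_expit(eta)
        + d * log_expit(zeta)
        + m * log_expit(-zeta)
        + np.log(chi_l)
    )
    dphi = s / np.maximum(phi, _TINY) + A[rows, l_idx] / chi_l
    dp_i = d / max(p, _TINY) - m / max(q, _TINY) + B[rows, l_idx] / chi_l
    grad_beta = X.T @ (dphi * phi * (1.0 - phi))
    grad_zeta = float(np.sum(dp_i) * p * q)
    grad = -np.concatenate([grad_beta, [grad_zeta]])
    return -float(np.sum(ll)), grad


def _design_matrix(
    histories: Sequence[EncounterHistory],
    covariates: Mapping[str, float] | pd.Series | None,
) -> np.ndarray:
    n = len(histories)
    if covariates is None:
        return np.ones((n, 1))
    try:
        x = np.array([float(covariates[h.individual_id]) for h in histories])
    except KeyError as exc:
        raise CJSError(f"covariate missing for individual {exc.args[0]!r}") from exc
    if not np.all(np.isfinite(x)):
        raise CJSError("covariates must be finite")
    return np.column_stack([np.ones(n), x])


def dataset_loglik(
    histories: Sequence[EncounterHistory],
    covariates: Mapping[str, float] | pd.Series | None,
    params: CJSParams,
) -> float:
    """Joint conditional log-likelihood of all histories.

    Histories whose first detection is the terminal occasion contribute 0.
    """
    f, l, s, d, m, T = _suff_stats(histories)
    X = _design_matrix(histories, covariates)
    if X.shape[1] != params.beta.size:
        raise CJSError(
            f"params have {params.beta.size} beta(s) but design has {X.shape[1]} column(s)"
        )
    theta = np.concatenate([params.beta, [params.p_logit]])
    nll, _ = _nll_grad(theta, X, s, d, m, l - 1, T)
    return -nll


def _observed_information(theta, X, s, d, m, l_idx, T) -> np.ndarray:
    """Hessian of the negative log-likelihood by central differences of the gradient."""
    k = theta.size
    H = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        up, dn = theta.copy(), theta.copy()
        up[i] += h[i]
        dn[i] -= h[i]
        _, gu = _nll_grad(up, X, s, d, m, l_idx, T)
        _, gd = _nll_grad(dn, X, s, d, m, l_idx, T)
        H[i] = (gu - gd) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def fit_cjs(
    histories: Sequence[EncounterHistory],
    covariates: Mapping[str, float] | pd.Series | None = None,
    *,
    n_starts: int = 3,
    gtol: float = 1e-8,
) -> CJSFit:
    """Maximum-likelihood CJS fit, intercept-only or with one covariate.

    Optimizes on the unconstrained ``(beta, logit p)`` scale with BFGS and
    analytic gradients from ``n_starts`` starting points (0, +1, -1 on every
    coordinate) to guard against flat regions.  A dataset with no recaptures
    at all is flagged non-identifiable (intercept and ``logit p`` lie on a
    ridge).  SEs come from the inverse observed information when it is
    positive-definite, else are reported absent.
    """
    f, l, s, d, m, T = _suff_stats(histories)
    X = _design_matrix(histories, covariates)
    l_idx = l - 1
    k = X.shape[1] + 1
    identifiable = int(d.sum()) > 0

    dim = X.shape[1] + 1
    starts = [np.zeros(dim), np.ones(dim), -np.ones(dim)][: max(1, n_starts)]
    best = None
    for x0 in starts:
        res = minimize(
            _nll_grad, x0, args=(X, s, d, m, l_idx, T), jac=True,
            method="BFGS", options={"gtol": gtol, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    logL = -float(best.fun)
    converged = bool(best.success) or float(np.linalg.norm(best.jac)) < 1e-5

    se = None
    H = _observed_information(theta, X, s, d, m, l_idx, T)
    try:
        ev = np.linalg.eigvalsh(H)
        # positive-definite and well-conditioned, else the information is singular
        if ev[0] > 0 and ev[0] / ev[-1] > 1e-10:
            diag = np.diag(np.linalg.inv(H))
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        se = None

    params = CJSParams(theta[:-1], float(theta[-1]))
    return CJSFit(
        params=params,
        logL=logL,
        k=k,
        AIC=-2.0 * logL + 2.0 * k,
        se=se,
        converged=converged,
        n_histories=len(histories),
        identifiable=identifiable,
    )


@dataclass
class SelectorResult:
    """Trait-vs-null comparison for one instance selector."""

    selector: str
    n: int = 0
    logL_null: float = np.nan
    logL_trait: float = np.nan
    AIC_null: float = np.nan
    AIC_trait: float = np.nan
    dAIC: float = np.nan
    beta1: float = np.nan
    se_beta1: float = np.nan
    converged: bool = False
    error: str | None = None


@dataclass
class ModelComparison:
    """Per-trait AIC comparison against the null across instance selectors."""

    species: str
    trait_name: str
    results: dict[str, SelectorResult] = field(default_factory=dict)

    def dAIC(self, selectors: Sequence[str] = SELECTORS) -> tuple[float, ...]:
        return tuple(self.results[s].dAIC for s in selectors if s in self.results)

    def beta1(self, selectors: Sequence[str] = SELECTORS) -> tuple[float, ...]:
        return tuple(self.results[s].beta1 for s in selectors if s in self.results)

    @property
    def complete(self) -> bool:
        return all(
            s in self.results and self.results[s].error is None for s in SELECTORS
        )


def scan_traits(
    ds: Dataset,
    traits: Sequence[str],
    selectors: Sequence[str] = SELECTORS,
    *,
    standardize: bool = True,
    n_starts: int = 3,
) -> list[ModelComparison]:
    """AIC scan of univariate survival-by-trait models, per species.

    For every species x trait x selector the covariate table is built, the
    null refit on exactly that covariate's individual subset, and the trait
    model fitted; per-trait failures (missing data, constant covariates,
    non-identifiable fits) are recorded on the result and the scan continues.
    """
    comparisons: list[ModelComparison] = []
    for sp in ds.species:
        sub = ds.for_species(sp)
        hist_by_id = {h.individual_id: h for h in build_histories(sub)}
        null_cache: dict[tuple[str, ...], CJSFit] = {}
        for trait in traits:
            mc = ModelComparison(sp, trait)
            for sel in selectors:
                result = SelectorResult(selector=sel)
                try:
                    cov = trait_prep.build_covariate_table(
                        sub, trait, sel, standardize=standardize
                    )
                    if cov.values.nunique() < 2:
                        raise CJSError(f"{trait}: covariate constant; beta1 unidentifiable")
                    ids = tuple(cov.values.index)
                    hsub = [hist_by_id[i] for i in ids]
                    null = null_cache.get(ids)
                    if null is None:
                        null = fit_cjs(hsub, None, n_starts=n_starts)
                        null_cache[ids] = null
                    fit = fit_cjs(hsub, cov.values, n_starts=n_starts)
                    if not fit.identifiable:
                        raise CJSError("no recaptures: parameters not identifiable")
                    result = SelectorResult(
                        selector=sel,
                        n=len(hsub),
                        logL_null=null.logL,
                        logL_trait=fit.logL,
                        AIC_null=null.AIC,
                        AIC_trait=fit.AIC,
                        dAIC=fit.AIC - null.AIC,
                        beta1=float(fit.params.beta[1]),
                        se_beta1=float(fit.se[1]) if fit.se is not None else np.nan,
                        converged=fit.converged and null.converged,
                    )
                except (CJSError, trait_prep.TraitPrepError) as exc:
                    result.error = str(exc)
                    logger.warning("scan %s/%s/%s failed: %s", sp, trait, sel, exc)
                mc.results[sel] = result
            comparisons.append(mc)
    return comparisons


def consistency(mc: ModelComparison, strict_margin: float = 0.0) -> bool:
    """Whether the first/median/last models agree in favoring the trait.

    True iff all three selectors fitted successfully and every dAIC is below
    ``-strict_margin`` (0 by default; 2 for the stricter variant).
    """
    if not mc.complete:
        return False
    return all(r.dAIC < -strict_margin for r in mc.results.values())


def scan_frame(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    """CSV-ready long view of a model scan."""
    rows = []
    for mc in comparisons:
        for sel, r in mc.results.items():
            rows.append(
                {"species": mc.species, "trait": mc.trait_name, "selector": sel,
                 "n": r.n, "logL_null": r.logL_null, "logL_trait": r.logL_trait,
                 "AIC_null": r.AIC_null, "AIC_trait": r.AIC_trait, "dAIC": r.dAIC,
                 "beta1": r.beta1, "se_beta1": r.se_beta1,
                 "converged": r.converged, "error": r.error}
            )
    return pd.DataFrame(rows)
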