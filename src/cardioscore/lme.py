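"""Linear mixed models with bootstrap inference and diagnostics.

The response (normalized RR in score time) is regressed on the music
predictors with a per-performance random intercept:

    y = X beta + Z u + eps,   u ~ N(0, sigma_u^2 I),  eps ~ N(0, sigma^2 I).

Three nested fixed-effect sets are defined: Set 1 (loudness, tempo),
Set 2 (+ note density and the Interpretation Map terms), Set 3
(+ starting factor).  Estimation is maximum likelihood — AIC comparisons
across fixed-effect structures require ML, not REML — via the profiled
likelihood: for a single random intercept, beta and both variances have
closed forms given the variance ratio lambda = sigma_u^2 / sigma^2, so
fitting reduces to a 1-D optimization.  This makes the thousands of
refits needed for bootstrap inference and calibration studies cheap.

Inference is by stratified row bootstrap: rows are resampled with
replacement within each performance, the model refit, and percentile
CIs taken; p-values come from re-centering the bootstrap coefficient
distribution at zero (the null that the term has no effect) and
measuring the two-tailed exceedance of the observed estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

INTERCEPT = "intercept"

#: Fixed-effect terms of the three nested model sets.
TERMS_SET1 = ("loudness", "tempo")
TERMS_SET2 = TERMS_SET1 + (
    "note_density",
    "melody",
    "dialogue",
    "significant_accompaniment",
    "accompaniment",
    "climax",
    "moment_of_concern",
)
TERMS_SET3 = TERMS_SET2 + ("starting_factor",)
MODEL_SET_TERMS: dict[int, tuple[str, ...]] = {1: TERMS_SET1, 2: TERMS_SET2, 3: TERMS_SET3}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one model set (random intercept implied)."""

    set_id: int
    fixed_terms: tuple[str, ...]
    random_effect: str = "performance"

    @classmethod
    def for_set(cls, set_id: int) -> "ModelSpec":
        if set_id not in MODEL_SET_TERMS:
            raise ValueError(f"unknown model set {set_id}; expected 1, 2 or 3")
        return cls(set_id, MODEL_SET_TERMS[set_id])

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in model set {self.set_id}")
        return replace(self, fixed_terms=tuple(t for t in self.fixed_terms if t != term))


@dataclass
class StackedDesign:
    """Long-format design: one row per (performance, half-beat sample).

    ``frame`` holds the group column, the response and all predictor
    columns; the same container serves all three model sets.
    """

    frame: pd.DataFrame
    terms: tuple[str, ...]
    response: str = "rr_norm"
    group_col: str = "performance"

    def __post_init__(self) -> None:
        missing = [c for c in (self.group_col, *self.terms) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design frame missing columns: {missing}")
        if self.frame[list(self.terms)].isna().any().any():
            raise ValueError("design contains missing predictor values")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def groups(self) -> np.ndarray:
        return self.frame[self.group_col].to_numpy()

    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def X(self, terms: Sequence[str] | None = None) -> np.ndarray:
        """Fixed-effect matrix with a leading intercept column."""
        terms = self.terms if terms is None else tuple(terms)
        cols = [np.ones(self.n_rows)]
        cols += [self.frame[t].to_numpy(dtype=float) for t in terms]
        return np.column_stack(cols)


@dataclass
class TermInference:
    """Bootstrap inference for one coefficient."""

    beta: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class FitResult:
    """Point fit (and optional inference/diagnostics) of one model set."""

    spec: ModelSpec
    beta: dict[str, float]
    sigma_u2: float
    sigma2: float
    llf: float
    aic: float
    n_rows: int
    n_groups: int
    r2_marginal: float
    r2_conditional: float
    cov_beta: np.ndarray
    dropped_terms: tuple[str, ...] = ()
    inference: dict[str, TermInference] = field(default_factory=dict)
    vif: dict[str, float] = field(default_factory=dict)
    f2: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


class _GroupedData:
    """Per-group sufficient statistics for the profiled likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        Xs, ys, gs = X[order], y[order], groups[order]
        change = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
        self.starts = change
        self.n_g = np.diff(np.r_[change, gs.size]).astype(float)
        self.n = float(gs.size)
        self.k = X.shape[1]
        self.XtX = Xs.T @ Xs
        self.Xty = Xs.T @ ys
        self.yty = float(ys @ ys)
        self.S = np.add.reduceat(Xs, change, axis=0)  # group sums of X
        self.T = np.add.reduceat(ys, change)  # group sums of y
        self.group_labels = gs[change]

    def profile(self, lam: float) -> tuple[float, np.ndarray, float]:
        """Profile log-likelihood, GLS beta and sigma^2 at variance ratio lam."""
        c = lam / (1.0 + lam * self.n_g)
        A = self.XtX - np.einsum("g,gi,gj->ij", c, self.S, self.S)
        b = self.Xty - (c * self.T) @ self.S
        beta = np.linalg.solve(A, b)
        Q = self.yty - float(np.sum(c * self.T**2)) - float(beta @ b)
        if Q <= 0:
            return -np.inf, beta, 0.0
        sigma2 = Q / self.n
        ll = -0.5 * (
            self.n * np.log(2.0 * np.pi * sigma2)
            + float(np.sum(np.log1p(lam * self.n_g)))
            + self.n
        )
        return ll, beta, sigma2

    def solve_A(self, lam: float) -> np.ndarray:
        c = lam / (1.0 + lam * self.n_g)
        A = self.XtX - np.einsum("g,gi,gj->ij", c, self.S, self.S)
        return np.linalg.inv(A)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.flatnonzero(diag < max(tol, 1e-10))]
    if bad:
        raise ValueError(f"rank-deficient fixed-effect matrix; collinear columns: {bad}")


def _profile_ml(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, lambda_fixed: float | None = None
) -> dict:
    gd = _GroupedData(X, y, groups)
    if lambda_fixed is not None:
        ll, beta, sigma2 = gd.profile(lambda_fixed)
        lam = lambda_fixed
    else:
        neg = lambda theta: -gd.profile(float(np.exp(theta)))[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize_scalar(neg, bounds=(-16.0, 16.0), method="bounded",
                                  options={"xatol": 1e-10})
        ll0, _, _ = gd.profile(0.0)
        ll_opt = -res.fun
        lam = float(np.exp(res.x)) if ll_opt > ll0 else 0.0
        ll, beta, sigma2 = gd.profile(lam)
    return {
        "beta": beta,
        "lambda": lam,
        "sigma2": sigma2,
        "sigma_u2": lam * sigma2,
        "llf": ll,
        "cov_beta": sigma2 * gd.solve_A(lam),
        "grouped": gd,
    }


def _blup_intercepts(gd: _GroupedData, beta: np.ndarray, lam: float) -> dict:
    """Empirical-Bayes random-intercept predictions per group."""
    resid_sum = gd.T - gd.S @ beta
    shrink = lam * gd.n_g / (1.0 + lam * gd.n_g)
    u = shrink * resid_sum / gd.n_g
    return dict(zip(gd.group_labels, u))


def fit_lmm(
    design: StackedDesign,
    spec: ModelSpec,
    lambda_fixed: float | None = None,
) -> FitResult:
    """ML fit of one model set with a per-performance random intercept.

    ``lambda_fixed`` pins the variance ratio sigma_u^2/sigma^2 (0 gives
    the OLS limit); by default it is profiled out by 1-D optimization.
    """
    groups = design.groups()
    if np.unique(groups).size < 2:
        raise ValueError("need at least two performances (groups)")
    X = design.X(spec.fixed_terms)
    names = (INTERCEPT, *spec.fixed_terms)
    # constant predictor columns are indistinguishable from the intercept
    const = [spec.fixed_terms[j] for j in range(len(spec.fixed_terms))
             if np.ptp(X[:, j + 1]) == 0]
    if const:
        raise ValueError(f"rank-deficient fixed-effect matrix; collinear columns: {const}")
    _check_full_rank(X, names)
    y = design.y()
    fit = _profile_ml(X, y, groups, lambda_fixed)
    beta = dict(zip(names, fit["beta"]))
    k = X.shape[1]
    # parameters: fixed effects + random-intercept variance + residual variance
    aic = -2.0 * fit["llf"] + 2.0 * (k + 2)
    yhat_fixed = X @ fit["beta"]
    u = _blup_intercepts(fit["grouped"], fit["beta"], fit["lambda"])
    yhat_cond = yhat_fixed + np.vectorize(u.get)(groups)
    return FitResult(
        spec=spec,
        beta=beta,
        sigma_u2=fit["sigma_u2"],
        sigma2=fit["sigma2"],
        llf=fit["llf"],
        aic=aic,
        n_rows=design.n_rows,
        n_groups=int(np.unique(groups).size),
        r2_marginal=_squared_corr(y, yhat_fixed),
        r2_conditional=_squared_corr(y, yhat_cond),
        cov_beta=fit["cov_beta"],
        meta={"lambda": fit["lambda"], "random_intercepts": u},
    )


def _squared_corr(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    if np.ptp(yhat) == 0:
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


def compute_r2(fit: FitResult, design: StackedDesign) -> dict[str, float]:
    """Marginal (fixed-effects-only) and conditional (fixed + BLUP) R^2.

    Both are squared Pearson correlations between the observed response
    and the corresponding prediction; the mixed-model R^2 is not unique,
    so both flavours are always reported.
    """
    X = design.X(fit.spec.fixed_terms)
    y = design.y()
    beta_vec = np.array([fit.beta[INTERCEPT]] + [fit.beta[t] for t in fit.spec.fixed_terms])
    yhat = X @ beta_vec
    u = fit.meta["random_intercepts"]
    yhat_cond = yhat + np.vectorize(u.get)(design.groups())
    return {"marginal": _squared_corr(y, yhat), "conditional": _squared_corr(y, yhat_cond)}


def compute_vif(design: StackedDesign, terms: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from OLS of predictor j on the remaining predictors
    (plus intercept).  Perfect collinearity yields inf with a warning.
    """
    terms = tuple(terms) if terms is not None else design.terms
    if len(terms) < 2:
        raise ValueError("need at least two fixed terms for VIF")
    out: dict[str, float] = {}
    cols = {t: design.frame[t].to_numpy(dtype=float) for t in terms}
    n = design.n_rows
    for t in terms:
        others = [o for o in terms if o != t]
        X = np.column_stack([np.ones(n)] + [cols[o] for o in others])
        yj = cols[t]
        coef, _, _, _ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            warnings.warn(f"constant predictor {t!r}; VIF undefined")
            out[t] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity involving {t!r}; VIF infinite")
            out[t] = np.inf
        else:
            out[t] = 1.0 / (1.0 - r2)
    return out


def cohens_f2(
    design: StackedDesign,
    spec: ModelSpec,
    term: str,
    fit_full: FitResult | None = None,
    kind: str = "marginal",
) -> float:
    """Local effect size f^2 = (R2_full - R2_without_term) / (1 - R2_full)."""
    if term not in spec.fixed_terms:
        raise ValueError(f"term {term!r} not in model set {spec.set_id}")
    if fit_full is None:
        fit_full = fit_lmm(design, spec)
    r2_full = fit_full.r2_marginal if kind == "marginal" else fit_full.r2_conditional
    if r2_full >= 1.0 - 1e-12:
        raise ValueError("degenerate model: R^2 = 1")
    fit_red = fit_lmm(design, spec.without(term))
    r2_red = fit_red.r2_marginal if kind == "marginal" else fit_red.r2_conditional
    return float((r2_full - r2_red) / (1.0 - r2_full))


def backward_stepwise_aic(
    design: StackedDesign, spec: ModelSpec
) -> tuple[ModelSpec, FitResult, tuple[str, ...]]:
    """Backward elimination: drop the term whose removal most lowers AIC.

    Stops when no single removal lowers AIC.  Near-ties (within 1e-9)
    are broken by dropping the term with the larger VIF, keeping the
    procedure deterministic.  Removed terms are reported so downstream
    tables can mark them "non-sign.".
    """
    current = spec
    fit = fit_lmm(design, current)
    dropped: list[str] = []
    while len(current.fixed_terms) > 0:
        candidates: list[tuple[float, str, FitResult]] = []
        for term in current.fixed_terms:
            reduced = current.without(term)
            try:
                f = fit_lmm(design, reduced)
            except ValueError:
                continue
            candidates.append((f.aic, term, f))
        if not candidates:
            break
        best_aic = min(c[0] for c in candidates)
        if best_aic >= fit.aic:
            break
        near = [c for c in candidates if c[0] <= best_aic + 1e-9]
        if len(near) > 1 and len(current.fixed_terms) >= 2:
            vifs = compute_vif(design, current.fixed_terms)
            near.sort(key=lambda c: -vifs.get(c[1], 0.0))
        _, term, fit = near[0]
        current = current.without(term)
        dropped.append(term)
    fit.dropped_terms = tuple(dropped)
    return current, fit, tuple(dropped)


def _stratified_resample(rng: np.random.Generator, group_idx: list[np.ndarray]) -> np.ndarray:
    picks = [idx[rng.integers(0, idx.size, idx.size)] for idx in group_idx]
    return np.concatenate(picks)


def bootstrap_inference(
    design: StackedDesign,
    spec: ModelSpec,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    max_retries: int = 50,
) -> tuple[dict[str, TermInference], dict]:
    """Percentile-bootstrap CIs and re-centered-null p-values per term.

    Rows are resampled with replacement *within* each performance
    (preserving group sizes) and the model refit; the 2.5/97.5
    percentiles of the refitted coefficients give the CI.  For the
    p-value the bootstrap distribution is shifted to mean zero (the
    no-effect null) and the two-tailed exceedance of the observed
    coefficient is measured, as p = 2*min(tails) with the (k+1)/(B+1)
    correction.  Failed refits (e.g. a resample losing all variation in
    a column) are retried with a fresh resample and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = fit_lmm(design, spec)
    names = (INTERCEPT, *spec.fixed_terms)
    groups = design.groups()
    labels = np.unique(groups)
    group_idx = [np.flatnonzero(groups == g) for g in labels]
    X = design.X(spec.fixed_terms)
    y = design.y()
    draws = np.empty((n_boot, len(names)))
    retries = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            rows = _stratified_resample(rng, group_idx)
            try:
                fit = _profile_ml(X[rows], y[rows], groups[rows])
                draws[b] = fit["beta"]
                break
            except np.linalg.LinAlgError:
                retries += 1
                if attempt == max_retries:
                    raise RuntimeError("bootstrap refit failed repeatedly")
    inference: dict[str, TermInference] = {}
    for j, name in enumerate(names):
        beta_obs = point.beta[name]
        col = draws[:, j]
        lo, hi = np.percentile(col, [2.5, 97.5])
        centered = col - col.mean()
        p_hi = (1 + np.sum(centered >= beta_obs)) / (n_boot + 1)
        p_lo = (1 + np.sum(centered <= beta_obs)) / (n_boot + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
        inference[name] = TermInference(beta_obs, float(lo), float(hi), float(p))
    info = {"n_boot": n_boot, "retries": retries, "point_fit": point}
    return inference, info


def correlation_matrix(
    design: StackedDesign,
    terms: Sequence[str] | None = None,
    flag_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson r and two-tailed p for the predictors.

    Pairs with |r| >= ``flag_threshold`` are returned separately as the
    strong-correlation watchlist.  Constant columns get NaN correlations
    with a warning.
    """
    terms = tuple(terms) if terms is not None else design.terms
    if len(terms) < 2:
        raise ValueError("need at least two predictors")
    r = pd.DataFrame(np.eye(len(terms)), index=terms, columns=terms)
    p = pd.DataFrame(np.zeros((len(terms), len(terms))), index=terms, columns=terms)
    flagged: list[tuple[str, str, float]] = []
    for i, a in enumerate(terms):
        xa = design.frame[a].to_numpy(dtype=float)
        for j in range(i + 1, len(terms)):
            b = terms[j]
            xb = design.frame[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(f"constant column in pair ({a}, {b}); correlation undefined")
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
            if np.isfinite(rij) and abs(rij) >= flag_threshold:
                flagged.append((a, b, float(rij)))
    return r, p, flagged
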