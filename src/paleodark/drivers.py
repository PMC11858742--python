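"""Drivers of diversity: GLS regression with AR(1) errors, exhaustive
subset enumeration over candidate covariates, and AICc ranking.

The response is a per-bin diversity series; candidate covariates are
bin-aligned time series (sea level, carbonate/siliciclastic rock area,
Mg/Ca proxies, sampling-effort proxies ...), log-normalised before
fitting.  Models are fitted by exact maximum likelihood: for a given AR(1)
parameter ρ the model is whitened (first observation scaled by
√(1−ρ²), then successive quasi-differences y_t − ρ·y_{t−1}), the
coefficients and innovation variance are profiled in closed form, and ρ is
maximised numerically on (−1, 1).  Ranking uses
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the fixed effects
(incl. intercept) plus ρ and σ — so the intercept-only model has k = 3.

ML (not REML) is used throughout so that AICc comparisons across models
with different fixed effects are valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

MAX_DREDGE_COVARIATES = 12


class ModelError(ValueError):
    """Model cannot be fitted on the data provided."""


# ---------------------------------------------------------------------------
# covariate preparation

def prepare_covariates(raw: pd.DataFrame, transform: str = "log",
                       standardize: bool = False
                       ) -> tuple[pd.DataFrame, dict]:
    """Log-normalise candidate covariate series.

    Strictly positive series get the natural log; series containing zeros
    get log1p (recorded per series in the report).  Negative values are an
    error naming the series.  Bins with any missing covariate are dropped
    listwise and counted.  ``standardize=True`` additionally centres and
    scales each transformed series.
    """
    out = {}
    report = {"transforms": {}, "n_dropped_bins": 0}
    for name in raw.columns:
        x = pd.to_numeric(raw[name], errors="coerce")
        if transform == "log":
            if (x < 0).any():
                raise ModelError(f"covariate {name!r} has negative values; "
                                 "cannot log-transform")
            if (x == 0).any():
                out[name] = np.log1p(x)
                report["transforms"][name] = "log1p"
            else:
                out[name] = np.log(x)
                report["transforms"][name] = "log"
        elif transform is None:
            out[name] = x
            report["transforms"][name] = "none"
        else:
            raise ValueError(f"unknown transform {transform!r}")
    df = pd.DataFrame(out, index=raw.index)
    complete = df.dropna()
    report["n_dropped_bins"] = len(df) - len(complete)
    report["dropped_bins"] = list(df.index[df.isna().any(axis=1)])
    if standardize:
        complete = (complete - complete.mean()) / complete.std(ddof=1)
    return complete, report


# ---------------------------------------------------------------------------
# GLS-AR(1) by exact maximum likelihood

@dataclass(frozen=True)
class GLSFit:
    """One fitted GLS-AR(1) model."""

    covariates: tuple[str, ...]
    beta: np.ndarray               # fixed effects, intercept first
    rho: float
    sigma: float                   # innovation standard deviation
    n: int
    df: int                        # fixed effects (incl. intercept) + rho + sigma
    loglik: float
    aicc: float

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    def label(self) -> str:
        return "+".join(("(intercept)",) + self.covariates)


def _whiten(z: np.ndarray, rho: float) -> np.ndarray:
    w = np.empty_like(z, dtype=float)
    w[0] = z[0] * np.sqrt(1.0 - rho * rho)
    w[1:] = z[1:] - rho * z[:-1]
    return w


def _profile_loglik(rho: float, y: np.ndarray, X: np.ndarray
                    ) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood at fixed rho: beta and sigma concentrated out.

    The AR(1) error covariance is sigma²/(1−rho²)·rho^|i−j|; whitening makes
    the errors iid with innovation variance sigma², and the Jacobian
    contributes ½·log(1−rho²).
    """
    n = len(y)
    ys = _whiten(y, rho)
    Xs = np.column_stack([_whiten(X[:, j], rho) for j in range(X.shape[1])])
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    rss = float(resid @ resid)
    if rss <= 0.0:
        rss = 1e-300        # exact fit: likelihood unbounded, clamp
    sigma2 = rss / n
    ll = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
          + 0.5 * np.log(1.0 - rho * rho))
    return ll, beta, np.sqrt(sigma2)


def gls_ar1(y, X: pd.DataFrame | np.ndarray | None = None,
            names: tuple[str, ...] = (), rho: float | None = None) -> GLSFit:
    """Fit a GLS regression with AR(1) errors by exact maximum likelihood.

    ``X`` holds the covariate columns (no intercept column; one is always
    added).  ``names`` labels the columns when ``X`` is a bare array.
    Passing ``rho`` fixes the autoregressive parameter instead of profiling
    it (``rho=0`` reduces the estimator to ordinary least squares).
    """
    fixed_rho = rho
    y = np.asarray(y, float)
    n = len(y)
    if X is None:
        Xm = np.empty((n, 0))
        names = ()
    elif isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        Xm = X.to_numpy(float)
    else:
        Xm = np.asarray(X, float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = tuple(names) if names else tuple(
            f"x{j}" for j in range(Xm.shape[1]))
    if not np.isfinite(y).all() or not np.isfinite(Xm).all():
        raise ModelError("non-finite values in response or covariates")
    p = Xm.shape[1]
    k = (p + 1) + 2                      # fixed effects + rho + sigma
    if n <= k + 1:
        raise ModelError(f"n = {n} too small for {p} covariate(s) "
                         f"(need n > df + 1 = {k + 1})")
    design = np.column_stack([np.ones(n), Xm])

    def neg_ll(rho: float) -> float:
        return -_profile_loglik(rho, y, design)[0]

    if fixed_rho is not None:
        if not -1.0 < fixed_rho < 1.0:
            raise ModelError("rho must lie in (-1, 1)")
        rho = float(fixed_rho)
    else:
        # coarse grid guards against local optima before the bounded refine
        grid = np.linspace(-0.98, 0.98, 41)
        r0 = grid[int(np.argmin([neg_ll(r) for r in grid]))]
        lo, hi = max(r0 - 0.06, -0.999), min(r0 + 0.06, 0.999)
        res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        rho = float(res.x)
    ll, beta, sigma = _profile_loglik(rho, y, design)
    if not np.isfinite(ll):
        raise ModelError("non-finite likelihood")
    aicc = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return GLSFit(covariates=names, beta=beta, rho=rho, sigma=sigma,
                  n=n, df=k, loglik=float(ll), aicc=float(aicc))


# ---------------------------------------------------------------------------
# exhaustive model selection

def dredge(y, X: pd.DataFrame) -> pd.DataFrame:
    """Fit every covariate subset (including intercept-only) and rank by
    AICc ascending; ties break toward fewer parameters, then lexically.

    Returns the model-selection table with one row per subset:
    ``model``, ``covariates``, ``df``, ``loglik``, ``AICc``, ``delta_AICc``.
    """
    cols = sorted(X.columns)
    if len(cols) > MAX_DREDGE_COVARIATES:
        raise ModelError(f"{len(cols)} covariates would need 2^{len(cols)} "
                         "fits; prune the candidate set")
    rows = []
    for r in range(len(cols) + 1):
        for subset in combinations(cols, r):
            fit = gls_ar1(y, X[list(subset)] if subset else None)
            rows.append({"model": fit.label(), "covariates": subset,
                         "df": fit.df, "loglik": fit.loglik,
                         "AICc": fit.aicc, "rho": fit.rho})
    tab = pd.DataFrame(rows)
    tab = tab.sort_values(["AICc", "df", "model"],
                          kind="mergesort").reset_index(drop=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return tab


def best_model(table: pd.DataFrame) -> pd.Series:
    """Top-ranked row of a dredge table."""
    return table.iloc[0]
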