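"""Richness estimation from incidence data: raw per-bin diversity,
coverage-based rarefaction/extrapolation at fixed quorum levels, Good's u,
and between-dataset correlation testing.

The sampling unit is the *collection*; a taxon's incidence frequency
``Y_i`` is the number of collections it occurs in.  Sample coverage — the
probability that the next sampled collection contains no new taxon — is
estimated from singleton/doubleton counts (Q1, Q2) and used as the
standardisation base ("quorum"): richness is compared between datasets at
equal coverage rather than equal effort.  Interpolation follows the
classical incidence rarefaction expectation; extrapolation beyond the
observed number of collections uses the Chao2 estimate of undetected
richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .occurrence import DatasetPartition


@dataclass(frozen=True)
class IncidenceSummary:
    """Incidence frequencies of one bin/dataset: T sampling units and one
    count per observed taxon."""

    T: int
    y: np.ndarray
    bin: str | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "y", y[y > 0])
        if self.T < 1:
            raise ValueError("need at least one sampling unit")
        if (self.y > self.T).any():
            raise ValueError("incidence frequency exceeds number of units")

    @property
    def S_obs(self) -> int:
        return int(len(self.y))

    @property
    def U(self) -> int:
        return int(self.y.sum())

    @property
    def Q1(self) -> int:
        return int((self.y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.y == 2).sum())


def incidence_from_occurrences(df: pd.DataFrame, taxon_col: str = "genus",
                               bin_label: str | None = None) -> IncidenceSummary:
    """Build incidence frequencies from occurrence rows (one bin's worth):
    T = distinct collections, Y_i = collections containing taxon i."""
    named = df[df[taxon_col] != ""]
    T = int(df["collection_id"].nunique())
    y = named.groupby(taxon_col)["collection_id"].nunique().to_numpy()
    return IncidenceSummary(T=max(T, 1), y=y, bin=bin_label)


# ---------------------------------------------------------------------------
# coverage and richness, continuous in t

def _lchoose(n: float, k: float) -> float:
    if k < 0 or k > n:
        return -np.inf
    return lgamma(n + 1.0) - lgamma(k + 1.0) - lgamma(n - k + 1.0)


def coverage_estimate(inc: IncidenceSummary) -> float:
    """Estimated sample coverage of the full reference sample,
    Ĉ(T) = 1 − (Q1/U)·[(T−1)Q1 / ((T−1)Q1 + 2Q2)]."""
    if inc.U == 0:
        raise ValueError("coverage undefined for U = 0")
    T, q1, q2, u = inc.T, inc.Q1, inc.Q2, inc.U
    denom = (T - 1) * q1 + 2 * q2
    a = ((T - 1) * q1 / denom) if denom > 0 else 0.0
    return 1.0 - (q1 / u) * a


def _chao2_q0(inc: IncidenceSummary) -> float:
    """Chao2 estimate of undetected richness (with the Q2 = 0 fallback)."""
    T, q1, q2 = inc.T, inc.Q1, inc.Q2
    pre = (T - 1) / T
    if q2 > 0:
        return pre * q1 * q1 / (2.0 * q2)
    return pre * q1 * (q1 - 1) / (2.0 * (q2 + 1.0))


def _coverage_at(inc: IncidenceSummary, t: float) -> float:
    """Coverage of a rarefied (t < T) or extrapolated (t > T) sample,
    continuous and nondecreasing in t."""
    T, u, q1, q2 = inc.T, inc.U, inc.Q1, inc.Q2
    c_T = coverage_estimate(inc)
    if t >= T:
        denom = (T - 1) * q1 + 2 * q2
        a = ((T - 1) * q1 / denom) if denom > 0 else 0.0
        return 1.0 - (q1 / u) * a ** (t - T + 1.0)
    if t > T - 1:
        # bridge the last unit linearly in coverage: the rarefied formula is
        # only defined up to t = T - 1, where it equals 1 - Q1/U
        c_lo = 1.0 - q1 / u
        return c_lo + (c_T - c_lo) * (t - (T - 1))
    s = 0.0
    ld = _lchoose(T - 1, t)
    for yi in inc.y:
        if t <= T - yi:
            s += yi / u * np.exp(_lchoose(T - yi, t) - ld)
    return 1.0 - s


def rarefy_richness(inc: IncidenceSummary, t: float) -> float:
    """Expected richness at ``t`` sampling units.

    For t ≤ T the interpolation expectation
    S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t); for t > T the Chao2-based
    extrapolation S(T+m) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^m].
    ``t`` may be non-integer (gamma-function binomials).
    """
    if t < 1:
        raise ValueError("need t >= 1")
    T = inc.T
    if t <= T:
        ld = _lchoose(T, t)
        s = 0.0
        for yi in inc.y:
            if t <= T - yi:
                s += np.exp(_lchoose(T - yi, t) - ld)
        return inc.S_obs - s
    q0 = _chao2_q0(inc)
    if q0 <= 0 or inc.Q1 == 0:
        return float(inc.S_obs)
    m = t - T
    return inc.S_obs + q0 * (1.0 - (1.0 - inc.Q1 / (inc.Q1 + T * q0)) ** m)


@dataclass(frozen=True)
class RarefactionEstimate:
    """Coverage-standardised richness at one quorum level."""

    bin: str | None
    quorum: float
    richness: float
    t_star: float
    kind: str            # "interpolated" | "extrapolated" | "below_minimum"
    ok: bool
    reason: str | None = None


def estimate_at_quorum(inc: IncidenceSummary, q: float,
                       max_extrap_factor: float = 2.0,
                       tol: float = 1e-8) -> RarefactionEstimate:
    """Richness standardised to coverage quorum ``q`` by inverting the
    coverage curve (monotone bisection on effective units t*).

    Bins with too little signal (T < 3, or all taxa singletons) and quorums
    beyond the coverage reachable at ``max_extrap_factor``·T are reported
    as missing (``ok=False``) rather than estimated.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("quorum must be in (0, 1)")
    if inc.T < 3 or inc.U == 0 or inc.Q1 == inc.U:
        return RarefactionEstimate(inc.bin, q, np.nan, np.nan, "missing",
                                   False, "insufficient data (T < 3 or all "
                                   "taxa singletons)")
    t_max = max_extrap_factor * inc.T
    c_max = _coverage_at(inc, t_max)
    if q > c_max + tol:
        return RarefactionEstimate(inc.bin, q, np.nan, np.nan, "missing",
                                   False, f"quorum {q} unreachable within "
                                   f"{max_extrap_factor}x extrapolation")
    lo, hi = 1.0, t_max
    if q <= _coverage_at(inc, lo):
        t_star = 1.0
        kind = "below_minimum"
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _coverage_at(inc, mid) < q:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        t_star = 0.5 * (lo + hi)
        kind = "interpolated" if t_star <= inc.T else "extrapolated"
    return RarefactionEstimate(inc.bin, q, float(rarefy_richness(inc, t_star)),
                               float(t_star), kind, True)


# ---------------------------------------------------------------------------
# per-bin summaries

def goods_u(df: pd.DataFrame, taxon_col: str = "genus") -> float:
    """Good's u coverage proxy: 1 − (taxa occurring once)/(occurrences)."""
    named = df[df[taxon_col] != ""]
    n = len(named)
    if n == 0:
        raise ValueError("need at least one named occurrence")
    singles = int((named[taxon_col].value_counts() == 1).sum())
    return 1.0 - singles / n


def raw_diversity(part: DatasetPartition, taxon_col: str = "genus",
                  bin_col: str = "bin") -> pd.DataFrame:
    """Sampled-in-bin distinct taxon and collection counts per dataset."""
    rows = []
    bins = sorted(part.D[bin_col].dropna().unique())
    for label, df in part.labelled():
        for b in bins:
            sub = df[df[bin_col] == b]
            named = sub[sub[taxon_col] != ""]
            rows.append({
                "dataset": label, "bin": b,
                "n_taxa": int(named[taxon_col].nunique()),
                "n_collections": int(sub["collection_id"].nunique()),
                "n_occurrences": len(sub),
                "goods_u": goods_u(sub, taxon_col) if len(named) else np.nan,
            })
    return pd.DataFrame(rows)


def quorum_diversity(part: DatasetPartition, quorums=(0.4, 0.5, 0.6),
                     taxon_col: str = "genus", bin_col: str = "bin",
                     max_extrap_factor: float = 2.0) -> pd.DataFrame:
    """Coverage-based rarefaction curves: one richness estimate per
    dataset × bin × quorum (missing points flagged, not fabricated)."""
    rows = []
    bins = sorted(part.D[bin_col].dropna().unique())
    for label, df in part.labelled():
        for b in bins:
            sub = df[df[bin_col] == b]
            if sub.empty:
                continue
            inc = incidence_from_occurrences(sub, taxon_col, bin_label=str(b))
            for q in quorums:
                if inc.U == 0:
                    est = RarefactionEstimate(str(b), q, np.nan, np.nan,
                                              "missing", False, "no incidences")
                else:
                    est = estimate_at_quorum(inc, q, max_extrap_factor)
                rows.append({"dataset": label, "bin": b, "quorum": q,
                             "richness": est.richness, "t_star": est.t_star,
                             "kind": est.kind, "ok": est.ok,
                             "reason": est.reason,
                             "coverage_at_T": coverage_estimate(inc)
                             if inc.U else np.nan,
                             "S_obs": inc.S_obs, "T": inc.T})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations

@dataclass(frozen=True)
class CorrelationResult:
    name: str
    r_s: float
    p_value: float
    n: int
    ok: bool
    reason: str | None = None


def _log_transform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if np.nanmin(x) < 0:
        raise ValueError("log transform of negative values")
    return np.log1p(x) if np.nanmin(x) == 0 else np.log(x)


def correlate_series(x, y, transform: str | None = "log",
                     name: str = "") -> CorrelationResult:
    """Spearman rank correlation between two bin-aligned series
    (pairwise-complete, optionally log-transformed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        return CorrelationResult(name, np.nan, np.nan, len(x), False,
                                 "fewer than 4 shared bins")
    if transform == "log":
        x, y = _log_transform(x), _log_transform(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(name, np.nan, np.nan, len(x), False,
                                 "constant series")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(name, float(r), float(p), len(x), True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, order-preserving)."""
    return stats.false_discovery_control(np.asarray(p, float), method="bh")


def correlate_batch(pairs: list[tuple[str, np.ndarray, np.ndarray]],
                    transform: str | None = "log") -> pd.DataFrame:
    """Run a family of Spearman tests with Benjamini–Hochberg adjustment
    applied across the batch."""
    results = [correlate_series(x, y, transform, name) for name, x, y in pairs]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["p_adjusted"] = np.nan
    ok = df["ok"] & df["p_value"].notna()
    if ok.any():
        df.loc[ok, "p_adjusted"] = benjamini_hochberg(
            df.loc[ok, "p_value"].to_numpy())
    return df
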