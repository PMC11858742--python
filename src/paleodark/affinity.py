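"""Standardised relative affinity (SRA) for carbonate vs siliciclastic
substrates.

For a family with ``n`` lithology-known occurrences of which ``k`` are
carbonate-hosted, against a background carbonate proportion ``π`` (the
lithology mix of a reference pool, by default all occurrences of the
combined dataset in the same interval), the raw affinity is
``RA = k/n − π``.  The SRA standardises RA against a binomial null: draw
``k* ~ Binomial(n, π)`` B times and report the Monte-Carlo z-score
``(RA − mean(RA*)) / sd(RA*)``.  Positive SRA ⇒ carbonate affinity,
negative ⇒ siliciclastic affinity, ~0 ⇒ mixed or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrence import DatasetPartition


@dataclass(frozen=True)
class AffinityResult:
    family: str
    interval: str
    dataset: str
    n: int
    k: int
    pi: float
    ra: float
    sra: float
    b: int
    ok: bool
    reason: str | None = None


def background_proportion(reference: pd.DataFrame) -> tuple[float, bool]:
    """Carbonate fraction of the lithology-known rows of a reference pool.

    Returns ``(π, usable)``; π of exactly 0 or 1 leaves no room for a
    binomial null and flags the interval unanalysable.
    """
    known = reference[reference["lithology"].isin(["carbonate",
                                                   "siliciclastic"])]
    if known.empty:
        return np.nan, False
    pi = float((known["lithology"] == "carbonate").mean())
    return pi, 0.0 < pi < 1.0


def sra_score(k: int, n: int, pi: float, B: int = 5000,
              rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo SRA z-score (and the raw affinity RA) for one family."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be strictly inside (0, 1)")
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    rng = rng or np.random.default_rng()
    ra = k / n - pi
    null = rng.binomial(n, pi, size=B) / n - pi
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        return np.nan, ra
    return float((ra - null.mean()) / sd), ra


def sra_null_calibration(n: int, pi: float, n_families: int, B: int = 5000,
                         seed: int = 0, chunk: int = 250
                         ) -> tuple[float, float, np.ndarray]:
    """SRA of ``n_families`` datasets drawn *from the null itself*
    (k ~ Binomial(n, π)); a well-calibrated score has mean ≈ 0, sd ≈ 1.

    Vectorised and chunked so large calibrations stay in memory budget.
    Returns (mean, sd, scores).
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_families)
    done = 0
    while done < n_families:
        m = min(chunk, n_families - done)
        k = rng.binomial(n, pi, size=m)
        null = rng.binomial(n, pi, size=(m, B)) / n - pi
        ra = k / n - pi
        scores[done:done + m] = ((ra - null.mean(axis=1))
                                 / null.std(axis=1, ddof=1))
        done += m
    return float(scores.mean()), float(scores.std(ddof=1)), scores


def affinity_table(part: DatasetPartition, interval_col: str = "bin",
                   families: list[str] | None = None, B: int = 5000,
                   seed: int = 0, n_min: int = 5,
                   reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """SRA per family × interval × dataset.

    The reference pool for π defaults to the combined dataset's occurrences
    in the same interval (pass ``reference`` to plug in an external pool).
    Families with fewer than ``n_min`` lithology-known occurrences in an
    interval are withheld (``ok=False``), mirroring the practice of
    restricting affinity analysis to well-sampled families.
    """
    rng = np.random.default_rng(seed)
    ref_pool = reference if reference is not None else part.D
    intervals = sorted(part.D[interval_col].dropna().unique())
    if families is None:
        families = sorted(f for f in part.D["family"].unique() if f)
    rows = []
    for interval in intervals:
        ref = ref_pool[ref_pool[interval_col] == interval]
        pi, usable = background_proportion(ref)
        for label, df in part.labelled():
            sub = df[(df[interval_col] == interval)
                     & df["lithology"].isin(["carbonate", "siliciclastic"])]
            for fam in families:
                fsub = sub[sub["family"] == fam]
                n = len(fsub)
                k = int((fsub["lithology"] == "carbonate").sum())
                if n == 0:
                    continue
                if not usable:
                    rows.append(AffinityResult(fam, str(interval), label, n, k,
                                               pi, np.nan, np.nan, B, False,
                                               "background proportion 0 or 1"))
                    continue
                if n < n_min:
                    rows.append(AffinityResult(fam, str(interval), label, n, k,
                                               pi, k / n - pi, np.nan, B,
                                               False, f"n < {n_min}"))
                    continue
                sra, ra = sra_score(k, n, pi, B, rng)
                rows.append(AffinityResult(fam, str(interval), label, n, k,
                                           pi, ra, sra, B, True))
    return pd.DataFrame([r.__dict__ for r in rows])
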