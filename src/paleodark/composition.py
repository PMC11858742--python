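"""Compositional comparisons between datasets.

Contingency-table tests (chi-squared), rank-based tests (Kruskal–Wallis
with epsilon-squared effect size, Wilcoxon rank-sum) on metadata such as
lithology, grain size, taxonomic rank and taphonomic grade, plus the
domestic/foreign repository split used to assess "parachute science".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .occurrence import DatasetPartition

#: Qualitative epsilon-squared effect-size thresholds.
EFFECT_SIZE_LABELS = ((0.26, "large"), (0.08, "medium"), (0.01, "small"))


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of one comparison test."""

    test: str                      # "chi_squared" | "kruskal_wallis" | "rank_sum"
    statistic: float
    df: int | None
    p_value: float
    effect_size: float | None = None
    effect_label: str | None = None
    observed: pd.DataFrame | None = None


def _effect_label(eps2: float) -> str:
    for cut, label in EFFECT_SIZE_LABELS:
        if eps2 >= cut:
            return label
    return "negligible"


def composition_table(part: DatasetPartition, variable: str,
                      unit: str = "occurrence",
                      specimens: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-dataset category proportions for one metadata variable.

    ``unit="specimen"`` weights occurrence rows by ``n_specimens``
    (for ``taph_grade`` it uses the specimen table directly).  Proportions
    are over known categories and sum to 1; the unknown fraction is reported
    in its own column.
    """
    if unit not in ("occurrence", "specimen"):
        raise ValueError(f"unknown unit {unit!r}")
    rows = []
    for label, df in part.labelled():
        if variable == "taph_grade":
            if specimens is None:
                raise ValueError("taph_grade needs the specimen table")
            sub = specimens[specimens["occurrence_id"].isin(df["occurrence_id"])]
            counts = sub["taph_grade"].value_counts()
            unknown = 0.0
        else:
            if variable not in df.columns:
                raise ValueError(f"variable {variable!r} not in table")
            w = df["n_specimens"] if unit == "specimen" else \
                pd.Series(1, index=df.index)
            grp = w.groupby(df[variable]).sum()
            unknown = float(grp.get("unknown", 0))
            counts = grp.drop(index="unknown", errors="ignore")
        total_known = float(counts.sum())
        rec = {"dataset": label, "n_known": total_known,
               "prop_unknown": (unknown / (unknown + total_known))
               if unknown + total_known > 0 else np.nan,
               "empty": total_known + unknown == 0}
        for cat, cnt in counts.items():
            rec[str(cat)] = cnt / total_known if total_known else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("dataset").fillna(0.0)


def composition_counts(part: DatasetPartition, variable: str,
                       datasets: tuple[str, ...] = ("A", "B"),
                       unit: str = "occurrence",
                       specimens: pd.DataFrame | None = None) -> pd.DataFrame:
    """Category-by-dataset count matrix feeding :func:`chi_squared`."""
    cols = {}
    for label, df in part.labelled():
        if label not in datasets:
            continue
        if variable == "taph_grade":
            if specimens is None:
                raise ValueError("taph_grade needs the specimen table")
            sub = specimens[specimens["occurrence_id"].isin(df["occurrence_id"])]
            cols[label] = sub["taph_grade"].value_counts()
        else:
            w = df["n_specimens"] if unit == "specimen" else \
                pd.Series(1, index=df.index)
            cols[label] = w.groupby(df[variable]).sum().drop(
                index="unknown", errors="ignore")
    out = pd.DataFrame(cols).fillna(0).astype(int)
    return out.sort_index()


def chi_squared(counts) -> ContingencyResult:
    """Pearson chi-squared test of independence on a count matrix."""
    obs = pd.DataFrame(counts)
    arr = obs.to_numpy(float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 count matrix")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row or column")
    res = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(test="chi_squared", statistic=float(res.statistic),
                             df=int(res.dof), p_value=float(res.pvalue),
                             observed=obs)


def kruskal_wallis(groups: dict[str, np.ndarray] | list) -> ContingencyResult:
    """Kruskal–Wallis H (tie-corrected) with epsilon² = H/(n−1)."""
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(vals) < 2 or any(len(v) == 0 for v in vals):
        raise ValueError("need >= 2 non-empty groups")
    h, p = stats.kruskal(*vals)
    n = sum(len(v) for v in vals)
    eps2 = float(h) / (n - 1)
    return ContingencyResult(test="kruskal_wallis", statistic=float(h),
                             df=len(vals) - 1, p_value=float(p),
                             effect_size=eps2, effect_label=_effect_label(eps2))


def wilcoxon_rank_sum(x, y, method: str = "auto") -> ContingencyResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    ``method="exact"`` enumerates the rank-sum null (small samples, no
    ties); the default lets the backend choose.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need two non-empty groups")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ContingencyResult(test="rank_sum", statistic=float(res.statistic),
                             df=None, p_value=float(res.pvalue))


def domestic_foreign(part: DatasetPartition, top_k: int = 15) -> pd.DataFrame:
    """Per-country repository contributions, split domestic vs foreign.

    A row is *domestic* when the fossil was found and accessioned in the
    same country, *foreign* otherwise; contributions are credited to the
    housing country as percentages of each dataset's occurrences with known
    countries.  The ``top_k`` housing countries per dataset are returned;
    excluded missing-country rows are counted in
    ``df.attrs["n_missing_country"]``.
    """
    frames = []
    missing = {}
    for label, df in part.labelled():
        known = df[(df["country_found"] != "") & (df["country_housed"] != "")]
        missing[label] = len(df) - len(known)
        if known.empty:
            continue
        dom = known["country_found"] == known["country_housed"]
        tab = (pd.DataFrame({"country_housed": known["country_housed"],
                             "domestic": dom})
               .groupby(["country_housed", "domestic"]).size()
               .unstack(fill_value=0)
               .reindex(columns=[True, False], fill_value=0))
        pct = 100.0 * tab / len(known)
        out = pd.DataFrame({
            "dataset": label,
            "country_housed": pct.index,
            "pct_domestic": pct[True].to_numpy(),
            "pct_foreign": pct[False].to_numpy(),
        })
        out["pct_total"] = out["pct_domestic"] + out["pct_foreign"]
        out = out.sort_values(["pct_total", "country_housed"],
                              ascending=[False, True]).head(top_k)
        frames.append(out)
    res = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["dataset", "country_housed",
                                      "pct_domestic", "pct_foreign", "pct_total"]))
    res.attrs["n_missing_country"] = missing
    return res
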