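"""Coverage-based rarefaction, Good's u, raw diversity and correlations."""

import numpy as np
import pandas as pd
import pytest

from paleodark.diversity import (IncidenceSummary, benjamini_hochberg,
                                 correlate_batch, correlate_series,
                                 coverage_estimate, estimate_at_quorum,
                                 goods_u, incidence_from_occurrences,
                                 quorum_diversity, raw_diversity,
                                 rarefy_richness)
from paleodark.occurrence import partition


def random_incidence(rng, T=50, s_max=40) -> IncidenceSummary:
    """A random incidence-frequency vector over T sampling units."""
    s = rng.integers(5, s_max + 1)
    p = rng.beta(0.6, 3.0, size=s)           # mostly rare taxa
    mat = rng.uniform(size=(s, T)) < p[:, None]
    y = mat.sum(axis=1)
    return IncidenceSummary(T=T, y=y[y > 0]), mat[y > 0]


def subsample_oracle(mat: np.ndarray, t: int, reps: int, rng):
    """Mean richness over `reps` uniform random t-subsets of the units —
    the brute-force expectation rarefaction must match."""
    s, T = mat.shape
    pick = np.argsort(rng.uniform(size=(reps, T)), axis=1)[:, :t]
    sel = np.zeros((T, reps))
    for r in range(reps):
        sel[pick[r], r] = 1.0
    hits = (mat.astype(float) @ sel) > 0
    rich = hits.sum(axis=0)
    return rich.mean(), rich.std(ddof=1) / np.sqrt(reps)


# ---------------------------------------------------------------------------
# coverage

def test_coverage_no_singletons_is_one():
    inc = IncidenceSummary(T=10, y=np.array([2, 3, 5]))
    assert coverage_estimate(inc) == 1.0


def test_coverage_all_singletons_is_zero():
    inc = IncidenceSummary(T=10, y=np.ones(6, dtype=int))
    assert coverage_estimate(inc) == pytest.approx(0.0)


def test_coverage_matches_independent_recomputation():
    rng = np.random.default_rng(12)
    for _ in range(10):
        inc, _ = random_incidence(rng)
        T, y = inc.T, inc.y
        q1 = int((y == 1).sum())
        q2 = int((y == 2).sum())
        u = int(y.sum())
        expected = 1 - (q1 / u) * (((T - 1) * q1) / ((T - 1) * q1 + 2 * q2)) \
            if (T - 1) * q1 + 2 * q2 > 0 else 1.0
        assert coverage_estimate(inc) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# rarefaction / extrapolation

def test_richness_at_full_effort_is_observed():
    rng = np.random.default_rng(3)
    inc, _ = random_incidence(rng)
    assert rarefy_richness(inc, inc.T) == pytest.approx(inc.S_obs)


def test_richness_at_one_unit_is_mean_per_unit():
    """S(1) = E[taxa in one unit] = sum_i Y_i / T (brute-force average)."""
    rng = np.random.default_rng(4)
    inc, mat = random_incidence(rng)
    per_unit = mat.sum(axis=0)                 # richness of each single unit
    assert rarefy_richness(inc, 1) == pytest.approx(per_unit.mean())
    assert rarefy_richness(inc, 1) == pytest.approx(inc.U / inc.T)


def test_interpolation_matches_subsampling_oracle():
    rng = np.random.default_rng(5)
    inc, mat = random_incidence(rng, T=50)
    est = rarefy_richness(inc, 25)
    mean, se = subsample_oracle(mat, 25, 4000, rng)
    assert abs(est - mean) < 3 * se + 1e-9


def test_interpolated_curve_monotone_concave():
    rng = np.random.default_rng(6)
    inc, _ = random_incidence(rng)
    ts = np.arange(1, inc.T + 1, dtype=float)
    s = np.array([rarefy_richness(inc, t) for t in ts])
    diffs = np.diff(s)
    assert (diffs >= -1e-9).all()              # nondecreasing
    assert (np.diff(diffs) <= 1e-9).all()      # concave


def test_extrapolation_continuous_and_bounded():
    rng = np.random.default_rng(7)
    inc, _ = random_incidence(rng)
    s_T = rarefy_richness(inc, inc.T)
    s_T_eps = rarefy_richness(inc, inc.T + 1e-9)
    assert s_T_eps == pytest.approx(s_T, abs=1e-6)
    s_2T = rarefy_richness(inc, 2 * inc.T)
    assert s_2T >= s_T


def test_rarefy_rejects_t_below_one():
    inc = IncidenceSummary(T=10, y=np.array([1, 2]))
    with pytest.raises(ValueError):
        rarefy_richness(inc, 0.5)


# ---------------------------------------------------------------------------
# quorum standardisation

def test_quorum_at_sample_coverage_returns_observed():
    rng = np.random.default_rng(8)
    inc, _ = random_incidence(rng)
    q = coverage_estimate(inc)
    est = estimate_at_quorum(inc, q)
    assert est.ok
    assert est.richness == pytest.approx(inc.S_obs, rel=1e-4)
    assert est.t_star == pytest.approx(inc.T, rel=1e-4)


def test_quorum_monotone():
    rng = np.random.default_rng(9)
    inc, _ = random_incidence(rng)
    e1 = estimate_at_quorum(inc, 0.4)
    e2 = estimate_at_quorum(inc, 0.6)
    if e1.ok and e2.ok:
        assert e1.richness <= e2.richness + 1e-9


def test_quorum_roundtrip_within_1e6():
    from paleodark.diversity import _coverage_at
    rng = np.random.default_rng(10)
    for _ in range(10):
        inc, _ = random_incidence(rng)
        for q in (0.3, 0.5, 0.7, 0.9):
            est = estimate_at_quorum(inc, q)
            if est.ok and est.kind in ("interpolated", "extrapolated"):
                assert _coverage_at(inc, est.t_star) == pytest.approx(
                    q, abs=1e-6)


def test_unreachable_quorum_flagged_missing():
    inc = IncidenceSummary(T=5, y=np.array([1, 1, 1, 2]))
    est = estimate_at_quorum(inc, 0.999)
    assert not est.ok
    assert "unreachable" in est.reason


def test_minimum_data_rules():
    assert not estimate_at_quorum(
        IncidenceSummary(T=2, y=np.array([1, 2])), 0.5).ok
    assert not estimate_at_quorum(
        IncidenceSummary(T=10, y=np.array([1, 1, 1])), 0.5).ok


# ---------------------------------------------------------------------------
# per-bin summaries

def test_raw_diversity_counts(make_occ):
    part = partition(make_occ([
        {"genus": "Ga", "collection_id": "c1"},
        {"genus": "Gb", "collection_id": "c1"},
        {"genus": "Gb", "collection_id": "c2"},
        {"genus": "Gc", "collection_id": "c2"},
    ]))
    tab = raw_diversity(part)
    b = tab[tab["dataset"] == "B"].iloc[0]
    assert b["n_taxa"] == 3
    assert b["n_collections"] == 2


@pytest.mark.parametrize("counts,expected", [
    ([1, 1, 1], 0.0),                     # every taxon once
    ([3, 2, 5], 1.0),                     # no singletons
    ([1, 1, 4, 4], 0.8),                  # 2 singletons of 10 occurrences
])
def test_goods_u(make_occ, counts, expected):
    rows = []
    for i, c in enumerate(counts):
        rows += [{"genus": f"G{i}", "collection_id": f"c{i}-{j}"}
                 for j in range(c)]
    assert goods_u(make_occ(rows)) == pytest.approx(expected)


def test_quorum_diversity_invariant_to_row_order(small_partition):
    a = quorum_diversity(small_partition, quorums=(0.5,))
    shuffled = partition(small_partition.D.sample(frac=1.0, random_state=1))
    b = quorum_diversity(shuffled, quorums=(0.5,))
    key = ["dataset", "bin", "quorum"]
    pd.testing.assert_frame_equal(
        a.sort_values(key).reset_index(drop=True),
        b.sort_values(key).reset_index(drop=True))


# ---------------------------------------------------------------------------
# correlations

def test_spearman_perfect_monotone():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = correlate_series(x, 2 * x)
    assert res.r_s == pytest.approx(1.0)


def test_single_test_batch_unchanged_by_bh():
    x = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
    out = correlate_batch([("only", x, x[::-1])])
    assert out["p_adjusted"].iloc[0] == pytest.approx(out["p_value"].iloc[0])


def test_bh_preserves_ordering():
    p = np.array([0.001, 0.04, 0.03, 0.2, 0.9])
    adj = benjamini_hochberg(p)
    assert (np.argsort(adj) == np.argsort(p)).all() or \
        np.allclose(np.sort(adj), adj[np.argsort(p)])
    assert (adj >= p - 1e-15).all()


def test_constant_series_flagged():
    res = correlate_series(np.ones(6), np.arange(6.0))
    assert not res.ok and res.reason == "constant series"
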