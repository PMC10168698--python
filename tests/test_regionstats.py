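"""Regional averaging, OLS, group models, and nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkmap.preprocess import FlyMeta
from walkmap.regionstats import (RegionActivity, average_regions,
                                 benjamini_hochberg, fit_group_model,
                                 fit_single_regression, map_similarity,
                                 normalize_per_fly, pairwise_mannwhitney)
from walkmap.synth import RegionAtlas

from conftest import movie_from_array


# ---------------------------------------------------------------------------
# oracles

def ols_oracle(y, x):
    """Closed-form slope/intercept/R² from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 1.0
    return slope, intercept, r2


def bh_oracle(p):
    """Direct step-up formula: p(i)*m/i with a cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def mannwhitney_exact_oracle(a, b):
    """Two-sided exact p by enumerating all rank arrangements."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    u_obs = sum((x > y) for x in a for y in b)
    u_obs = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for positions in itertools.combinations(range(n1 + n2), n1):
        ranks = np.asarray(positions)
        u = ranks.sum() - n1 * (n1 - 1) / 2
        u = min(u, n1 * n2 - u)
        count += u <= u_obs
        total += 1
    return count / total


def signed_rank_oracle(values):
    """One-sided (greater) exact p over all 2^n sign assignments."""
    v = np.abs(np.asarray(values, float))
    ranks = np.argsort(np.argsort(v)) + 1.0
    w_obs = ranks[np.asarray(values) > 0].sum()
    n = len(v)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += w >= w_obs
    return count / 2 ** n


# ---------------------------------------------------------------------------
# averaging / normalization

def _atlas_two_regions():
    labels = np.zeros((1, 1, 4), dtype=np.int32)
    labels[0, 0, :2] = 1
    labels[0, 0, 2] = 2
    return RegionAtlas(labels, {1: "A", 2: "B"})


def test_average_regions_arithmetic_mean():
    data = np.zeros((2, 1, 1, 4))
    data[:, 0, 0, 0] = [0, 2]
    data[:, 0, 0, 1] = [2, 0]
    data[:, 0, 0, 2] = [5, 7]
    act = average_regions(movie_from_array(data, space="dff"), _atlas_two_regions())
    np.testing.assert_allclose(act.values[0], [1, 1])      # two-voxel mean
    np.testing.assert_allclose(act.values[1], [5, 7])      # single voxel: identity
    assert act.region_names == ["A", "B"]


def test_average_regions_zero_movie():
    data = np.zeros((3, 1, 1, 4))
    act = average_regions(movie_from_array(data, space="dff"), _atlas_two_regions())
    np.testing.assert_array_equal(act.values, 0.0)


def test_normalize_per_fly_uses_own_maximum():
    a = RegionActivity(np.array([[-2.0, 4.0]]), ["A"], 10.0, FlyMeta("f1"))
    b = RegionActivity(np.array([[1.0, 5.0]]), ["A"], 10.0, FlyMeta("f2"))
    na, nb = normalize_per_fly(a), normalize_per_fly(b)
    np.testing.assert_allclose(na.values, [[-0.5, 1.0]])
    np.testing.assert_allclose(nb.values, [[0.2, 1.0]])    # per-fly, not global
    # idempotence
    np.testing.assert_allclose(normalize_per_fly(na).values, na.values)


def test_normalize_all_zero_raises():
    act = RegionActivity(np.zeros((1, 4)), ["A"], 10.0)
    with pytest.raises(ValueError):
        normalize_per_fly(act)


# ---------------------------------------------------------------------------
# single regression

def test_identity_fit():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    res = fit_single_regression(x, x)
    assert res.coefficient == pytest.approx(1.0)
    assert res.r2 == pytest.approx(1.0)


def test_worked_example():
    res = fit_single_regression(np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 1, 2]))
    assert res.coefficient == pytest.approx(1.5)
    assert res.r2 == pytest.approx(0.9)


def test_sign_symmetry_carries_inhibition():
    x = np.linspace(0, 1, 20)
    res = fit_single_regression(-x, x)
    assert res.coefficient == pytest.approx(-1.0)
    assert res.r2 == pytest.approx(1.0)
    assert res.ci_low <= res.coefficient <= res.ci_high


def test_degenerate_regressor_raises():
    with pytest.raises(ValueError, match="degenerate"):
        fit_single_regression(np.arange(4.0), np.ones(4))


def test_ols_matches_normal_equation_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(5, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = fit_single_regression(y, x)
        slope, _, r2 = ols_oracle(y, x)
        assert res.coefficient == pytest.approx(slope, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       ay=st.floats(0.1, 10), by=st.floats(-5, 5), ax=st.floats(0.1, 10))
def test_r2_affine_invariance(seed, ay, by, ax):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r_base = fit_single_regression(y, x).r2
    r_scaled = fit_single_regression(ay * y + by, ax * x).r2
    assert r_scaled == pytest.approx(r_base, abs=1e-9)


# ---------------------------------------------------------------------------
# group model

def test_group_model_two_balanced_groups_reports_cell_means():
    df = pd.DataFrame({"r2": [1.0, 1.2, 2.0, 2.2],
                       "behavior": ["walk", "walk", "groom", "groom"]})
    out = fit_group_model(df, "r2", ["behavior"])
    est = dict(zip(out["level"], out["estimate"]))
    assert est["walk"] == pytest.approx(1.1)
    assert est["groom"] == pytest.approx(2.1)


def test_group_model_degenerate_response_gives_zero_widths():
    df = pd.DataFrame({"r2": [0.5] * 6,
                       "behavior": ["a", "a", "b", "b", "c", "c"]})
    out = fit_group_model(df, "r2", ["behavior"])
    np.testing.assert_allclose(out["estimate"], 0.5, atol=1e-12)
    np.testing.assert_allclose(out["ci_high"] - out["ci_low"], 0.0, atol=1e-8)


def test_group_model_recovers_planted_additive_effects(rng):
    regions = ["GNG", "AVLP", "MB", "CX"]
    gal4 = ["nsyb", "Cha"]
    region_fx = dict(zip(regions, [0.0, 0.1, -0.1, 0.3]))
    gal4_fx = dict(zip(gal4, [0.0, 0.2]))
    hits = 0
    trials = 0
    for _ in range(20):
        rows = []
        for r in regions:
            for g in gal4:
                for _rep in range(6):
                    rows.append({"region": r, "gal4": g,
                                 "y": 1.0 + region_fx[r] + gal4_fx[g]
                                 + rng.normal(0, 0.05)})
        out = fit_group_model(pd.DataFrame(rows), "y", ["region", "gal4"])
        sub = out[out["factor"] == "region"].set_index("level")
        # reported level value = intercept + level coefficient, i.e. the
        # cell mean at the reference gal4 level
        ref_gal4 = sorted(gal4)[0]
        for lev in regions:
            if lev == sorted(regions)[0]:
                continue
            truth = 1.0 + region_fx[lev] + gal4_fx[ref_gal4]
            trials += 1
            hits += bool(sub.loc[lev, "ci_low"] <= truth <= sub.loc[lev, "ci_high"])
    assert hits / trials >= 0.95


def test_group_model_rank_deficiency_reports_aliased_levels():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                       "a": ["p", "p", "q", "q"],
                       "b": ["u", "u", "v", "v"]})  # b aliases a
    with pytest.raises(ValueError, match="aliased"):
        fit_group_model(df, "y", ["a", "b"])


# ---------------------------------------------------------------------------
# nonparametric tests and FDR

def test_mannwhitney_worked_example():
    out = pairwise_mannwhitney({"lo": np.array([1.0, 2, 3]),
                                "hi": np.array([4.0, 5, 6])})
    row = out.iloc[0]
    assert row["U"] == 0.0
    assert row["p"] == pytest.approx(0.1)


def test_mannwhitney_identical_groups_not_significant():
    out = pairwise_mannwhitney({"a": np.array([1.0, 2, 3, 4]),
                                "b": np.array([1.0, 2, 3, 4])})
    assert out.iloc[0]["p"] > 0.5


def test_bonferroni_caps_at_one():
    groups = {k: np.array([1.0, 2, 3]) + i * 0.1 for i, k in enumerate("abc")}
    out = pairwise_mannwhitney(groups)
    assert len(out) == 3
    assert np.all(out["p_bonf"] <= 1.0)
    assert np.all(out["p_bonf"] >= out["p"])


def test_mannwhitney_exact_matches_enumeration(rng):
    for n1 in range(1, 7):
        for n2 in range(n1, 7):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2) + rng.normal()
            got = pairwise_mannwhitney({"a": a, "b": b}).iloc[0]["p"]
            assert got == pytest.approx(mannwhitney_exact_oracle(a, b), abs=1e-12)


def test_bh_worked_example():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.04]),
                               [0.03, 0.03, 0.04])


def test_bh_single_and_equal_pvalues_unchanged():
    np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])
    np.testing.assert_allclose(benjamini_hochberg([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 100_000), m=st.integers(1, 40))
def test_bh_matches_oracle_and_is_bounded(seed, m):
    p = np.random.default_rng(seed).uniform(size=m)
    adj = benjamini_hochberg(p)
    np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= np.minimum(p * m, 1.0) + 1e-15)  # never beyond Bonferroni


# ---------------------------------------------------------------------------
# cosine similarity

def test_map_similarity_examples():
    assert map_similarity([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(1.0)
    assert map_similarity([1.0, 0], [0.0, 1]) == pytest.approx(0.0)
    assert map_similarity([1.0, 0], [1.0, 1]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(ValueError):
        map_similarity([0.0, 0], [1.0, 1])
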