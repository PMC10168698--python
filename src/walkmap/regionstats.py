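"""Region-wise statistics: averaging, normalization, regression, tests.

Mirrors the analysis applied to the fly recordings: average ΔF/F per
atlas region, normalize by the per-fly absolute maximum, regress each
unit (region or extracted component) on one behavior regressor with OLS,
summarize across flies with a treatment-coded linear model, and compare
groups with Mann–Whitney (Bonferroni) or one-sample t-tests
(Benjamini–Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .preprocess import FlyMeta, VolumeSeries
from .regressors import Regressor
from .synth import RegionAtlas

__all__ = [
    "RegionActivity",
    "RegressionResult",
    "average_regions",
    "normalize_per_fly",
    "fit_single_regression",
    "fit_group_model",
    "pairwise_mannwhitney",
    "benjamini_hochberg",
    "map_similarity",
]


@dataclass
class RegionActivity:
    """Mean ΔF/F per region: ``values`` is (n_regions, T)."""

    values: np.ndarray
    region_names: list[str]
    frame_rate_hz: float
    meta: FlyMeta = field(default_factory=FlyMeta)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_regions, T)")
        if self.values.shape[0] != len(self.region_names):
            raise ValueError("one row per region name required")


@dataclass
class RegressionResult:
    """Single-regressor OLS summary for one unit.

    ``coefficient`` is the slope (its sign is the direction of
    modulation: negative = inhibited during the behavior), ``r2`` the
    fraction of variance explained.
    """

    unit: str
    channel: str
    coefficient: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    p_adj: float | None = None
    meta: FlyMeta = field(default_factory=FlyMeta)

    def as_dict(self) -> dict:
        return {
            "unit": self.unit, "channel": self.channel,
            "coefficient": self.coefficient, "r2": self.r2, "p": self.p,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p_adj": self.p_adj,
            "fly_id": self.meta.fly_id, "gal4": self.meta.gal4,
            "gcamp": self.meta.gcamp, "substrate": self.meta.substrate,
            "condition": self.meta.condition,
        }


def average_regions(movie: VolumeSeries, atlas: RegionAtlas) -> RegionActivity:
    """Unweighted mean over each region's voxels, per frame."""
    if movie.space != "dff":
        raise ValueError("average_regions expects a dff movie")
    if movie.spatial_shape != atlas.labels.shape:
        raise ValueError(
            f"movie spatial shape {movie.spatial_shape} != atlas shape {atlas.labels.shape}"
        )
    labs = atlas.labels.ravel()
    sorted_labels = sorted(atlas.names)
    counts = np.bincount(labs, minlength=max(sorted_labels) + 1)
    for lab in sorted_labels:
        if counts[lab] == 0:
            raise ValueError(f"region {atlas.names[lab]!r} has no voxels")
    T = movie.n_frames
    flat = movie.data.reshape(T, -1)
    sums = np.vstack([np.bincount(labs, weights=flat[t], minlength=len(counts))
                      for t in range(T)])  # (T, n_labels+1)
    rows = np.array([sums[:, lab] / counts[lab] for lab in sorted_labels])
    return RegionActivity(rows, [atlas.names[lab] for lab in sorted_labels],
                          movie.frame_rate_hz, meta=movie.meta)


def normalize_per_fly(activity: RegionActivity) -> RegionActivity:
    """Divide all of a fly's regional traces by the fly-wide max |value|."""
    m = float(np.max(np.abs(activity.values)))
    if m == 0:
        raise ValueError("all-zero activity; cannot normalize")
    return replace(activity, values=activity.values / m, normalized=True)


def fit_single_regression(
    y: np.ndarray,
    x: Regressor | np.ndarray,
    unit: str = "unit",
    meta: FlyMeta | None = None,
    channel: str | None = None,
) -> RegressionResult:
    """OLS of one unit's trace on one behavior regressor.

    Returns slope, R², the slope's two-sided p and 95% CI from its t
    distribution.
    """
    if isinstance(x, Regressor):
        channel = channel or x.channel
        xv = x.values
    else:
        xv = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != xv.shape:
        raise ValueError("y and x must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.var(xv) == 0:
        raise ValueError("degenerate regressor (zero variance)")
    fit = sm.OLS(y, sm.add_constant(xv)).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        unit=unit, channel=channel or "x",
        coefficient=float(fit.params[1]), r2=float(fit.rsquared),
        p=float(fit.pvalues[1]), ci_low=float(ci[1, 0]), ci_high=float(ci[1, 1]),
        meta=meta or FlyMeta(),
    )


def _design_matrix(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Treatment-coded design with intercept; returns (X, column keys)."""
    cols = [np.ones(len(df))]
    keys: list[tuple[str, str]] = [("Intercept", "")]
    for f in factors:
        levels = sorted(pd.unique(df[f].astype(str)))
        for lev in levels[1:]:  # first level is the reference
            cols.append((df[f].astype(str) == lev).to_numpy(dtype=float))
            keys.append((f, lev))
    return np.column_stack(cols), keys


def fit_group_model(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    ci_method: str = "summed",
) -> pd.DataFrame:
    """Linear model of per-fit summaries on categorical factors.

    Fits ``response ~ factor_1 + factor_2 + ...`` with treatment coding
    and reports, per factor level, intercept + level coefficient, a 95%
    interval, a t-test of that combination against zero, and BH-adjusted
    p-values.  ``ci_method="summed"`` adds the half-widths of the
    intercept CI and the level-coefficient CI (the construction used for
    the original per-region bar plots); ``"covariance"`` uses the exact
    variance of the linear combination.
    """
    if ci_method not in ("summed", "covariance"):
        raise ValueError("ci_method must be 'summed' or 'covariance'")
    missing = [f for f in factors if f not in table.columns]
    if missing:
        raise ValueError(f"factors not in table: {missing}")
    X, keys = _design_matrix(table, factors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, R, piv = scipy.linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [keys[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        bad += [keys[j] for j in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; aliased levels: {bad}")
    y = table[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    hw = (ci[:, 1] - ci[:, 0]) / 2.0
    cov = fit.cov_params()

    rows = []
    for j, (factor, level) in enumerate(keys):
        if factor == "Intercept":
            continue
        est = fit.params[0] + fit.params[j]
        if ci_method == "summed":
            half = hw[0] + hw[j]
        else:
            var = cov[0, 0] + cov[j, j] + 2 * cov[0, j]
            half = scipy.stats.t.ppf(0.975, fit.df_resid) * np.sqrt(max(var, 0.0))
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
        contrast[j] = 1.0
        tt = fit.t_test(contrast)
        rows.append({"factor": factor, "level": level, "estimate": est,
                     "ci_low": est - half, "ci_high": est + half,
                     "p": float(np.squeeze(tt.pvalue))})
        # reference level of this factor: intercept alone (other factors at reference)
    # reference levels, reported once per factor
    for f in factors:
        ref = sorted(pd.unique(table[f].astype(str)))[0]
        est = fit.params[0]
        half = hw[0] if ci_method == "summed" else hw[0]
        tt = fit.t_test(np.eye(X.shape[1])[0])
        rows.append({"factor": f, "level": ref, "estimate": est,
                     "ci_low": est - half, "ci_high": est + half,
                     "p": float(np.squeeze(tt.pvalue))})
    out = pd.DataFrame(rows).sort_values(["factor", "level"]).reset_index(drop=True)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def pairwise_mannwhitney(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise two-sided Mann–Whitney U tests, Bonferroni-adjusted.

    Uses the exact U null distribution when both samples have n <= 8 and
    no ties across groups; otherwise the normal approximation with tie
    correction.  Group samples are typically fly-wise averages.
    """
    names = list(groups)
    for name in names:
        if len(np.asarray(groups[name])) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        pooled = np.concatenate([xa, xb])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(xa) <= 8 and len(xb) <= 8 and not has_ties) else "asymptotic"
        res = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        p = float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "U": float(res.statistic),
                     "p": p, "p_bonf": min(1.0, p * n_pairs)})
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted p-values, original order, capped at 1."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def map_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two per-region (or per-component) vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))
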