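"""Walk-onset analysis and condition comparisons.

Onsets are rest→walk transitions with enough preceding rest and
following walk.  Around each onset a component's trace is cut into a
trial, normalized (baseline-subtracted and scaled by its max |value|),
and averaged.  Early, behavior-preceding activity is quantified by
integrating the trace over the half second before onset (referenced to
its value at −0.5 s) and testing the per-trial integrals against zero
with a one-sided Wilcoxon signed-rank test, Benjamini–Hochberg adjusted
across components.  Turning lateralization and spontaneous-vs-forced
comparisons complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .regionstats import benjamini_hochberg, map_similarity
from .synth import BehaviorTrace

logger = logging.getLogger(__name__)

__all__ = [
    "OnsetParams",
    "TriggeredResult",
    "detect_onsets",
    "triggered_average",
    "pre_onset_statistic",
    "test_pre_onset",
    "walk_onset_analysis",
    "lateralization_index",
    "compare_conditions",
]


@dataclass(frozen=True)
class OnsetParams:
    """Windows (seconds) around walk onset.

    t_pre is the pre-onset integration window (default 0.5 s);
    display_before/display_after bound the trial window; min_rest and
    min_walk are the qualifying run lengths around a transition.
    """

    t_pre: float = 0.5
    display_before: float = 2.0
    display_after: float = 2.0
    min_rest: float = 1.0
    min_walk: float = 1.0
    norm_epsilon: float = 1e-12
    normalize_trials: bool = True

    def __post_init__(self) -> None:
        for name in ("t_pre", "display_before", "display_after", "min_rest", "min_walk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_pre > self.display_before:
            raise ValueError("t_pre cannot exceed display_before")


@dataclass
class TriggeredResult:
    """Trial-resolved onset-triggered average for one component."""

    times: np.ndarray          # seconds relative to onset
    mean: np.ndarray
    sem: np.ndarray | None     # None when a single trial was retained
    trials: np.ndarray         # (n_trials, len(times))
    n_trials: int
    n_dropped: int
    pre_onset_stats: np.ndarray | None = None  # per trial, ΔF/F·s
    p: float | None = None
    p_adj: float | None = None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_onsets(behavior: BehaviorTrace, params: OnsetParams) -> np.ndarray:
    """Indices of the first walk frame of each qualifying bout.

    A transition qualifies when the immediately preceding frames are an
    unbroken rest run of at least min_rest seconds and the walk run
    lasts at least min_walk seconds.
    """
    labels = np.asarray(behavior.label, dtype=object)
    fs = behavior.frame_rate_hz
    need_rest = max(1, int(round(params.min_rest * fs)))
    need_walk = max(1, int(round(params.min_walk * fs)))
    walk = labels == "walk"
    rest = labels == "rest"
    onsets = []
    for start, stop in _runs(walk):
        if stop - start < need_walk or start < need_rest:
            continue
        if np.all(rest[start - need_rest:start]):
            onsets.append(start)
    return np.asarray(onsets, dtype=np.int64)


def triggered_average(
    tc: np.ndarray,
    onsets: np.ndarray,
    params: OnsetParams,
    frame_rate_hz: float,
) -> TriggeredResult:
    """Cut, normalize, and average trials around the given onsets.

    Each trial covers [-display_before, +display_after]; the baseline
    mean over [-display_before, -t_pre] is subtracted, and (by default)
    the trial is scaled by its max |value| — skipped when that max is
    below norm_epsilon.  Onsets whose window leaves the recording are
    dropped with a logged count.
    """
    tc = np.asarray(tc, dtype=np.float64)
    fs = frame_rate_hz
    n_before = int(round(params.display_before * fs))
    n_after = int(round(params.display_after * fs))
    n_pre = int(round(params.t_pre * fs))
    T = len(tc)
    trials = []
    dropped = 0
    for o in np.asarray(onsets, dtype=np.int64):
        if o - n_before < 0 or o + n_after >= T:
            dropped += 1
            continue
        w = tc[o - n_before: o + n_after + 1].copy()
        w -= w[: n_before - n_pre + 1].mean()
        if params.normalize_trials:
            m = np.max(np.abs(w))
            if m >= params.norm_epsilon:
                w = w / m
        trials.append(w)
    if dropped:
        logger.info("dropped %d onset(s) with incomplete windows", dropped)
    if not trials:
        raise ValueError("no trials with a complete window around any onset")
    trials = np.vstack(trials)
    nt = trials.shape[0]
    times = (np.arange(-n_before, n_after + 1)) / fs
    mean = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(nt) if nt >= 2 else None
    return TriggeredResult(times, mean, sem, trials, nt, dropped)


def pre_onset_statistic(trace: np.ndarray, params: OnsetParams, frame_rate_hz: float) -> float:
    """Integral of (a(t) - a(-t_pre)) over [-t_pre, 0], trapezoidal.

    ``trace`` must end at the onset sample (t = 0) and cover at least
    t_pre seconds before it.  Units: (trace units)·s.
    """
    trace = np.asarray(trace, dtype=np.float64)
    n_pre = int(round(params.t_pre * frame_rate_hz))
    if len(trace) < n_pre + 1:
        raise ValueError(
            f"trace has {len(trace)} samples; needs {n_pre + 1} to cover t_pre"
        )
    seg = trace[-(n_pre + 1):]
    return float(np.trapezoid(seg - seg[0], dx=1.0 / frame_rate_hz))


def _wilcoxon_greater(values: np.ndarray, exact_max_n: int = 15) -> float:
    """One-sided (greater) signed-rank p; exact for small tie-free samples."""
    v = np.asarray(values, dtype=np.float64)
    v = v[v != 0.0]
    if v.size == 0:
        raise ValueError("all-zero sample: signed-rank test undefined")
    ties = len(np.unique(np.abs(v))) < len(v)
    if len(v) <= exact_max_n and not ties:
        res = scipy.stats.wilcoxon(v, alternative="greater", method="exact")
    else:
        res = scipy.stats.wilcoxon(v, alternative="greater", method="approx",
                                   correction=True)
    return float(res.pvalue)


def test_pre_onset(
    stats_per_component: list[np.ndarray],
    flies_per_component: list[np.ndarray] | None = None,
    aggregate: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Wilcoxon one-sided test of pre-onset integrals against zero.

    ``aggregate`` chooses the unit of replication: "trial" tests the
    per-trial integrals, "fly" first averages trials within each fly,
    and "auto" picks fly-wise when at least 5 flies contributed.
    Returns (p, BH-adjusted p) across components.
    """
    if aggregate not in ("trial", "fly", "auto"):
        raise ValueError("aggregate must be 'trial', 'fly', or 'auto'")
    ps = []
    for i, stats in enumerate(stats_per_component):
        stats = np.asarray(stats, dtype=np.float64)
        mode = aggregate
        flies = None if flies_per_component is None else np.asarray(flies_per_component[i])
        if mode == "auto":
            n_flies = len(np.unique(flies)) if flies is not None else 1
            mode = "fly" if n_flies >= 5 else "trial"
        if mode == "fly":
            if flies is None:
                raise ValueError("fly-wise aggregation requires fly ids")
            vals = np.array([stats[flies == f].mean() for f in np.unique(flies)])
        else:
            vals = stats
        ps.append(_wilcoxon_greater(vals))
    p = np.asarray(ps)
    return p, benjamini_hochberg(p)


def walk_onset_analysis(
    tcs: np.ndarray,
    behavior: BehaviorTrace,
    params: OnsetParams | None = None,
    aggregate: str = "trial",
) -> list[TriggeredResult]:
    """Full onset pipeline for a stack of component time courses (K, T).

    Detects onsets, builds triggered averages, computes per-trial
    pre-onset integrals, and attaches Wilcoxon + BH p-values per
    component.
    """
    params = params or OnsetParams()
    tcs = np.atleast_2d(np.asarray(tcs, dtype=np.float64))
    onsets = detect_onsets(behavior, params)
    fs = behavior.frame_rate_hz
    n_after = int(round(params.display_after * fs))
    results = []
    for k in range(tcs.shape[0]):
        res = triggered_average(tcs[k], onsets, params, fs)
        end = len(res.times) - n_after - 1  # index of t = 0
        res.pre_onset_stats = np.array([
            pre_onset_statistic(trial[: end + 1], params, fs) for trial in res.trials
        ])
        results.append(res)
    p, p_adj = test_pre_onset([r.pre_onset_stats for r in results], aggregate=aggregate)
    for r, pi, ai in zip(results, p, p_adj):
        r.p, r.p_adj = float(pi), float(ai)
    return results


def lateralization_index(
    coef_ipsi: dict[str, np.ndarray],
    coef_contra: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Ipsi-minus-contra turning coefficient per mirrored component pair.

    Inputs map pair name -> per-fly coefficients for turning toward the
    component's own side (ipsi) and the opposite side (contra).  The
    index is the mean per-fly difference; positive means the component
    is more active during ipsilateral turns.  95% CI and a t-test
    against zero propagate per-fly variability; p-values are BH-adjusted
    across pairs.
    """
    if set(coef_ipsi) != set(coef_contra):
        raise ValueError(
            f"unmatched pairs: {sorted(set(coef_ipsi) ^ set(coef_contra))}"
        )
    rows = []
    for name in coef_ipsi:
        a = np.asarray(coef_ipsi[name], dtype=np.float64)
        b = np.asarray(coef_contra[name], dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError(f"pair {name!r}: ipsi/contra fly counts differ")
        d = a - b
        n = len(d)
        m = d.mean()
        if n >= 2 and np.std(d, ddof=1) > 0:
            se = np.std(d, ddof=1) / np.sqrt(n)
            half = scipy.stats.t.ppf(0.975, n - 1) * se
            p = float(scipy.stats.ttest_1samp(d, 0.0).pvalue)
        else:
            half, p = 0.0, 1.0
        rows.append({"pair": name, "index": m, "ci_low": m - half,
                     "ci_high": m + half, "p": p, "n_flies": n})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def compare_conditions(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    turn_samples_a: dict[str, np.ndarray] | None = None,
    turn_samples_b: dict[str, np.ndarray] | None = None,
) -> dict:
    """Compare per-unit regression summaries between two conditions.

    Each table needs columns unit, r2, coefficient and (optionally)
    ci_low/ci_high.  Returns cosine similarities of the R² and
    coefficient vectors over the shared unit ordering, the units whose
    coefficient CIs do not overlap, and — when per-fly turn-difference
    samples are supplied — a Mann–Whitney test per unit with BH
    adjustment (the forced-vs-spontaneous turning contrast).
    """
    a = results_a.set_index("unit")
    b = results_b.set_index("unit")
    shared = [u for u in a.index if u in b.index]
    if not shared:
        raise ValueError("conditions share no units")
    a, b = a.loc[shared], b.loc[shared]
    out = {
        "units": shared,
        "cosine_r2": map_similarity(a["r2"].to_numpy(), b["r2"].to_numpy()),
        "cosine_coefficient": map_similarity(a["coefficient"].to_numpy(),
                                             b["coefficient"].to_numpy()),
    }
    if {"ci_low", "ci_high"} <= set(a.columns) and {"ci_low", "ci_high"} <= set(b.columns):
        disjoint = (a["ci_low"] > b["ci_high"]) | (b["ci_low"] > a["ci_high"])
        out["non_overlapping_ci"] = [u for u, bad in disjoint.items() if bad]
    if turn_samples_a is not None and turn_samples_b is not None:
        units = sorted(set(turn_samples_a) & set(turn_samples_b))
        ps = []
        for u in units:
            res = scipy.stats.mannwhitneyu(turn_samples_a[u], turn_samples_b[u],
                                           alternative="two-sided")
            ps.append(float(res.pvalue))
        out["turn_tests"] = pd.DataFrame({
            "unit": units, "p": ps, "p_adj": benjamini_hochberg(np.asarray(ps)),
        })
    return out
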