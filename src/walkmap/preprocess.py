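"""Raw fluorescence to denoised ΔF/F.

The pipeline is: per-voxel ΔF/F against a long moving-average baseline,
then a fixed-gain recursive (Kalman-style) temporal filter.  Motion
correction is deliberately a no-op hook: registration is assumed to have
happened upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FlyMeta",
    "VolumeSeries",
    "PreprocessParams",
    "moving_baseline",
    "dff_series",
    "compute_dff",
    "kalman_denoise",
    "motion_correct",
]


@dataclass(frozen=True)
class FlyMeta:
    """Per-recording metadata carried through every stage."""

    fly_id: str = "fly1"
    gal4: str = "nsyb"
    gcamp: str = "6m"
    substrate: str = "styrofoam_ball"
    condition: str = "spontaneous"  # or "forced"


@dataclass
class VolumeSeries:
    """A 4-D movie: ``data`` is (T, Z, Y, X).

    ``space`` records processing history: ``"raw"`` for fluorescence in
    arbitrary units, ``"dff"`` after ΔF/F normalization.
    """

    data: np.ndarray
    frame_rate_hz: float
    space: str = "raw"
    meta: FlyMeta = field(default_factory=FlyMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (T,Z,Y,X), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.isfinite(self.frame_rate_hz) or self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if self.space not in ("raw", "dff"):
            raise ValueError(f"unknown space {self.space!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the ΔF/F + denoising stage.

    baseline_window
        Number of frames averaged for the baseline F0 (default 4000).
        When the recording is shorter than the window the baseline
        degenerates to the global mean of each voxel.
    gain
        Gain G of the recursive filter, in [0, 1].  G = 0 is the
        identity; larger G trusts the running estimate more.
    epsilon
        Guard for the baseline division; baselines below it are clamped
        (or, for the subtract-only fallback used on regressors, trigger
        subtraction without division).
    baseline_mode
        "moving" (centered moving average, edge-truncated) or "global"
        (one mean per voxel).  Moving is the default and reduces to
        global when T <= baseline_window.
    """

    baseline_window: int = 4000
    gain: float = 0.5
    epsilon: float = 1e-6
    baseline_mode: str = "moving"

    def __post_init__(self) -> None:
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError("gain must be in [0, 1]")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.baseline_mode not in ("moving", "global"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")


def moving_baseline(x: np.ndarray, window: int, mode: str = "moving") -> np.ndarray:
    """Centered moving average along axis 0, truncated at the edges.

    The effective window is min(window, T); with mode="global" (or when
    the window covers the whole series) every frame gets the global
    per-voxel mean, matching the behavior of a single long average on
    short recordings.
    """
    x = np.asarray(x, dtype=np.float64)
    T = x.shape[0]
    w = min(int(window), T)
    if mode == "global" or w >= T:
        return np.broadcast_to(x.mean(axis=0, keepdims=True), x.shape).copy()
    half = w // 2
    # cumulative-sum trick; windows truncated to [0, T)
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)], axis=0)
    t = np.arange(T)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t - half + w, T)
    counts = (hi - lo).astype(np.float64)
    out = (cs[hi] - cs[lo]) / counts.reshape((-1,) + (1,) * (x.ndim - 1))
    return out


def dff_series(
    x: np.ndarray,
    params: PreprocessParams,
    subtract_only_fallback: bool = False,
) -> np.ndarray:
    """ΔF/F transform of an array of time series (time on axis 0).

    ΔF/F(t) = (x(t) - B(t)) / max(B(t), epsilon).  With
    ``subtract_only_fallback`` (used for behavior regressors), series
    whose baseline magnitude never exceeds epsilon are only
    baseline-subtracted, so an all-zero series maps to zero instead of
    0/0.
    """
    x = np.asarray(x, dtype=np.float64)
    B = moving_baseline(x, params.baseline_window, params.baseline_mode)
    num = x - B
    if subtract_only_fallback:
        degenerate = np.max(np.abs(B), axis=0, keepdims=True) < max(params.epsilon, 1e-12)
        denom = np.where(degenerate, 1.0, np.maximum(B, params.epsilon))
        return num / denom
    if params.epsilon == 0:
        n_bad = int(np.count_nonzero(np.any(B <= 0, axis=0)))
        if n_bad:
            raise ValueError(
                f"baseline <= 0 for {n_bad} voxel(s) with epsilon=0; "
                "set epsilon > 0 to guard the division"
            )
        denom = B
    else:
        denom = np.maximum(B, params.epsilon)
    return num / denom


def compute_dff(movie: VolumeSeries, params: PreprocessParams | None = None) -> VolumeSeries:
    """Per-voxel ΔF/F against the moving-window baseline.

    The raw movie is required; the result is flagged ``space="dff"`` so
    downstream stages can enforce ordering.
    """
    if movie.space != "raw":
        raise ValueError(f"compute_dff expects a raw movie, got space={movie.space!r}")
    params = params or PreprocessParams()
    out = dff_series(movie.data, params)
    return VolumeSeries(out, movie.frame_rate_hz, space="dff", meta=movie.meta)


def kalman_denoise(movie: VolumeSeries, params: PreprocessParams | None = None) -> VolumeSeries:
    """Fixed-gain recursive predictor–corrector along time.

    E_1 = x_1;  E_t = G*E_{t-1} + (1-G)*x_t.  A stationary simplification
    of the adaptive-variance movie filter it is modeled on; G = 0 is the
    identity.  Every output sample is a convex combination of past
    inputs, so it stays inside the running input range.
    """
    params = params or PreprocessParams()
    G = params.gain
    x = np.asarray(movie.data, dtype=np.float64)
    if G == 0.0:
        out = x.copy()
    else:
        out = np.empty_like(x)
        out[0] = x[0]
        for t in range(1, x.shape[0]):
            out[t] = G * out[t - 1] + (1.0 - G) * x[t]
    return VolumeSeries(out, movie.frame_rate_hz, space=movie.space, meta=movie.meta)


def motion_correct(movie: VolumeSeries) -> VolumeSeries:
    """Registration hook; identity here (handled by external tools upstream)."""
    return replace(movie)
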