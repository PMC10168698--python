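"""Behavior regressors.

A behavior channel becomes a regressor in three steps: (1) binarize
discrete behaviors (walk/groom/flail) from the frame labels, or keep the
rotational optic-flow channels continuous; (2) convolve causally with
the calcium indicator's single-spike response; (3) apply the same ΔF/F
transform used for the fluorescence, so regressor and signal live on the
same scale.  Onset/offset channels start from unit Dirac trains at label
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import PreprocessParams, dff_series
from .synth import BehaviorTrace

__all__ = [
    "KernelSpec",
    "Regressor",
    "GCAMP_KERNELS",
    "kernel_for_variant",
    "score_labels",
    "gcamp_kernel",
    "build_regressor",
    "CHANNELS",
]

CHANNELS = ("walk", "turn_left", "turn_right", "groom", "flail", "walk_onset", "walk_offset")

#: Default rise/decay time constants (seconds) per GCaMP variant, taken
#: from published single-spike sensor characterizations; overridable via
#: an explicit KernelSpec.
GCAMP_KERNELS: dict[str, tuple[float, float]] = {
    "6f": (0.05, 0.40),
    "6m": (0.08, 1.00),
    "6s": (0.18, 1.80),
    "7f": (0.03, 0.45),
    "7s": (0.15, 1.70),
}


@dataclass(frozen=True)
class KernelSpec:
    """Difference-of-exponentials calcium impulse response.

    k(t) = exp(-t/tau_decay) - exp(-t/tau_rise) for t >= 0, peak
    normalized to 1 when sampled.
    """

    variant: str = "6m"
    tau_rise: float = 0.08
    tau_decay: float = 1.00

    def __post_init__(self) -> None:
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValueError("need 0 < tau_rise < tau_decay")


def kernel_for_variant(variant: str) -> KernelSpec:
    try:
        tr, td = GCAMP_KERNELS[variant]
    except KeyError:
        raise KeyError(
            f"unknown GCaMP variant {variant!r}; known: {sorted(GCAMP_KERNELS)}"
        ) from None
    return KernelSpec(variant=variant, tau_rise=tr, tau_decay=td)


@dataclass
class Regressor:
    """A per-frame regressor on the ΔF/F scale."""

    values: np.ndarray
    channel: str
    frame_rate_hz: float
    binary_source: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor contains non-finite values")


def score_labels(
    behavior: BehaviorTrace,
    walk_threshold: float = 0.25,
    min_bout: int = 6,
) -> BehaviorTrace:
    """Score walk frames from forward speed.

    Frames with forward_speed > walk_threshold (mm/s) are labeled walk;
    walk runs shorter than ``min_bout`` frames are merged back into the
    flanking (non-walk) state.  Groom/flail labels on non-walk frames
    pass through untouched.
    """
    if walk_threshold < 0:
        raise ValueError("walk_threshold must be >= 0")
    T = len(behavior.forward_speed)
    if T == 0:
        return replace(behavior, label=np.asarray([], dtype=object))
    walk = behavior.forward_speed > walk_threshold
    # drop walk runs shorter than min_bout
    if min_bout > 1:
        padded = np.concatenate([[False], walk, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start < min_bout:
                walk[start:stop] = False
    old = np.asarray(behavior.label, dtype=object)
    new = np.where(walk, "walk", np.where(np.isin(old, ("groom", "flail")) & ~walk, old, "rest"))
    return replace(behavior, label=new.astype(object))


def gcamp_kernel(spec: KernelSpec, frame_rate_hz: float) -> np.ndarray:
    """Sample the causal indicator kernel at the frame rate, peak = 1.

    Support covers 5 decay time constants; k(0) = 0 by construction.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if spec.tau_rise >= spec.tau_decay:
        raise ValueError("need tau_rise < tau_decay")
    n = int(np.floor(5.0 * spec.tau_decay * frame_rate_hz)) + 1
    t = np.arange(n) / frame_rate_hz
    k = np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise)
    peak = k.max()
    if peak <= 0:  # frame rate too low to sample the rise; single-sample kernel
        return np.ones(1)
    return k / peak


def _base_channel(behavior: BehaviorTrace, channel: str) -> tuple[np.ndarray, bool]:
    labels = np.asarray(behavior.label, dtype=object)
    if channel in ("walk", "groom", "flail"):
        return (labels == channel).astype(np.float64), True
    if channel == "turn_left":
        return np.asarray(behavior.rot_left, dtype=np.float64), False
    if channel == "turn_right":
        return np.asarray(behavior.rot_right, dtype=np.float64), False
    walk = labels == "walk"
    prev = np.concatenate([[False], walk[:-1]])
    if channel == "walk_onset":
        return (walk & ~prev).astype(np.float64), True
    if channel == "walk_offset":
        return (~walk & prev).astype(np.float64), True
    raise ValueError(f"unknown channel {channel!r}")


def build_regressor(
    behavior: BehaviorTrace,
    channel: str,
    kernel: np.ndarray | None = None,
    dff_params: PreprocessParams | None = None,
    kernel_spec: KernelSpec | None = None,
) -> Regressor:
    """Binarize/convolve/normalize one behavior channel into a regressor.

    ``kernel`` is the sampled indicator response (from
    :func:`gcamp_kernel`); if omitted it is built from ``kernel_spec``
    (default variant "6m") at the trace's frame rate.  ``dff_params``
    enables the final ΔF/F stage; regressors with an effectively zero
    baseline are only baseline-subtracted (an all-rest walk regressor
    stays exactly zero).
    """
    base, binary = _base_channel(behavior, channel)
    if kernel is None:
        spec = kernel_spec or kernel_for_variant("6m")
        kernel = gcamp_kernel(spec, behavior.frame_rate_hz)
    kernel = np.asarray(kernel, dtype=np.float64)
    T = base.shape[0]
    conv = np.convolve(base, kernel)[:T]  # causal: zero-padded past, truncated future
    if dff_params is not None:
        conv = dff_series(conv, dff_params, subtract_only_fallback=True)
    return Regressor(conv, channel, behavior.frame_rate_hz, binary_source=binary)
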