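"""Synthetic recordings with known ground truth.

Emulates the structure of whole-brain volumetric calcium recordings of a
walking fly: a two-state walk/rest bout process with geometric dwell
times, localized Gaussian-blob spatial components whose time courses
couple to kernel-convolved behavior channels (with optional temporal
leads and negative, i.e. inhibitory, gains), a positive per-voxel
baseline, signal-dependent shot noise and additive read noise.  Every
stage is driven by a single seed so the rendered data are bit-
reproducible and each downstream analysis has a recoverable target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .preprocess import FlyMeta, VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorTrace",
    "ComponentSpec",
    "SyntheticSpec",
    "RegionAtlas",
    "GroundTruth",
    "simulate_behavior",
    "make_atlas",
    "render_movie",
    "mirrored_pair",
    "default_components",
    "noiseless_movie",
]

LABELS = ("walk", "rest", "groom", "flail")


@dataclass
class BehaviorTrace:
    """Per-frame behavior aligned to the movie.

    forward_speed in mm/s, rotations in rad/s (both non-negative; the
    left/right split of the rotational optic flow is stored separately),
    and a discrete label per frame.
    """

    forward_speed: np.ndarray
    rot_left: np.ndarray
    rot_right: np.ndarray
    label: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.forward_speed = np.asarray(self.forward_speed, dtype=np.float64)
        self.rot_left = np.asarray(self.rot_left, dtype=np.float64)
        self.rot_right = np.asarray(self.rot_right, dtype=np.float64)
        self.label = np.asarray(self.label, dtype=object)
        T = len(self.forward_speed)
        for name in ("rot_left", "rot_right", "label"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} length != forward_speed length")
        for name in ("forward_speed", "rot_left", "rot_right"):
            arr = getattr(self, name)
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
                raise ValueError(f"{name} must be finite and >= 0")
        bad = set(self.label) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.forward_speed)


@dataclass(frozen=True)
class ComponentSpec:
    """One planted source: an anisotropic Gaussian blob with a coupled
    time course.

    coupling maps behavior channel -> dimensionless gain (negative =
    inhibited during that behavior).  lead_s shifts the time course:
    negative values make the component's activity precede the behavior.
    """

    name: str
    center: tuple[float, float, float]  # (z, y, x) voxel coordinates
    scale: tuple[float, float, float] = (2.0, 2.0, 2.0)
    coupling: dict = field(default_factory=lambda: {"walk": 0.3})
    lead_s: float = 0.0
    noise_sd: float = 0.05
    noise_ar: float = 0.8  # AR(1) coefficient of the intrinsic noise


def mirrored_pair(
    name: str,
    center: tuple[float, float, float],
    x_size: int,
    scale: tuple[float, float, float] = (2.0, 2.0, 2.0),
    coupling_ipsi: float = 0.3,
    coupling_contra: float = 0.0,
    noise_sd: float = 0.05,
) -> tuple[ComponentSpec, ComponentSpec]:
    """A bilaterally mirrored component pair coupled to turning.

    The left member sits at ``center`` and couples to turn_left with
    gain ``coupling_ipsi`` (turn_right with ``coupling_contra``); the
    right member is its reflection across the x midline with the
    couplings swapped.
    """
    z, y, x = center
    left = ComponentSpec(
        name=f"{name}_L", center=(z, y, x), scale=scale,
        coupling={"turn_left": coupling_ipsi, "turn_right": coupling_contra},
        noise_sd=noise_sd,
    )
    right = ComponentSpec(
        name=f"{name}_R", center=(z, y, x_size - 1 - x), scale=scale,
        coupling={"turn_left": coupling_contra, "turn_right": coupling_ipsi},
        noise_sd=noise_sd,
    )
    return left, right


def default_components(shape: tuple[int, int, int] = (10, 20, 30)) -> list[ComponentSpec]:
    """Default planted sources for the standard synthetic study.

    Four walk-coupled blobs — one inhibited (negative gain, the
    serotonergic-AVLP-like case) and one leading walk onset by 300 ms —
    plus a mirrored turning pair, spread through the volume.
    """
    Z, Y, X = shape
    comps = [
        ComponentSpec("walk_global", (Z * 0.5, Y * 0.3, X * 0.5),
                      scale=(Z * 0.25, Y * 0.2, X * 0.2), coupling={"walk": 0.30}),
        ComponentSpec("walk_dorsal", (Z * 0.75, Y * 0.7, X * 0.35),
                      coupling={"walk": 0.25}),
        ComponentSpec("walk_inhibited", (Z * 0.3, Y * 0.75, X * 0.7),
                      coupling={"walk": -0.20}),
        ComponentSpec("walk_leading", (Z * 0.25, Y * 0.25, X * 0.2),
                      coupling={"walk": 0.30}, lead_s=-0.3),
    ]
    comps += list(mirrored_pair("turn", (Z * 0.55, Y * 0.55, X * 0.22), X,
                                coupling_ipsi=0.30))
    return comps


@dataclass
class SyntheticSpec:
    """Full description of one synthetic recording.

    The bout process is first-order Markov over {rest, walk} with
    per-frame transition probabilities ``p_rest_to_walk`` (alpha) and
    ``p_walk_to_rest`` (beta); dwell times are geometric.  Mean forward
    speed defaults to 5.6 mm/s and mean rotational speed to 0.4 rad/s.
    Fractions of rest bouts may be relabeled groom or flail to exercise
    behavior contrasts.
    """

    shape: tuple[int, int, int] = (10, 20, 30)
    n_frames: int = 3000
    frame_rate_hz: float = 30.0
    p_rest_to_walk: float = 0.01
    p_walk_to_rest: float = 0.02
    mean_forward_speed: float = 5.6
    mean_rot_speed: float = 0.4
    groom_bout_frac: float = 0.0
    flail_bout_frac: float = 0.0
    baseline: float = 100.0
    baseline_variation: float = 0.2
    shot_noise_scale: float = 0.01
    read_noise_sd: float = 0.1
    components: list[ComponentSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.components is None:
            self.components = default_components(self.shape)
        _require(self.n_frames >= 2, "n_frames", "must be >= 2")
        _require(np.isfinite(self.frame_rate_hz) and self.frame_rate_hz > 0,
                 "frame_rate_hz", "must be positive")
        for name in ("p_rest_to_walk", "p_walk_to_rest"):
            p = getattr(self, name)
            _require(np.isfinite(p) and 0.0 <= p <= 1.0, name, "must be in [0, 1]")
        for name in ("mean_forward_speed", "mean_rot_speed"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(self.baseline > 0, "baseline", "must be > 0")
        _require(0 <= self.baseline_variation < 1, "baseline_variation", "must be in [0, 1)")
        _require(self.shot_noise_scale >= 0, "shot_noise_scale", "must be >= 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        for c in self.components:
            _require(all(s > 0 for s in c.scale), f"components[{c.name}].scale", "must be > 0")
            _require(c.noise_sd >= 0, f"components[{c.name}].noise_sd", "must be >= 0")


def _require(ok: bool, fieldname: str, msg: str) -> None:
    if not ok:
        raise ValueError(f"{fieldname} {msg}")


@dataclass
class RegionAtlas:
    """Integer label volume (0 = background) plus a label -> name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D volume")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("region names must be unique")
        for lab in self.names:
            if lab not in present:
                raise ValueError(f"named region {self.names[lab]!r} has no voxels")

    @property
    def region_names(self) -> list[str]:
        return [self.names[lab] for lab in sorted(self.names)]


@dataclass
class GroundTruth:
    """Planted sources of a rendered movie.

    ``maps`` (K, Z, Y, X) and ``time_courses`` (K, T) reconstruct the
    noiseless movie exactly via ``noiseless_movie``; ``couplings`` and
    ``leads_s`` record the generative parameters per component.
    """

    maps: np.ndarray
    time_courses: np.ndarray
    names: list[str]
    couplings: list[dict]
    leads_s: list[float]
    baseline: np.ndarray  # F0 per voxel, (Z, Y, X)
    n_clipped: int = 0


# ---------------------------------------------------------------------------
# behavior


def _bout_states(T: int, alpha: float, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Walk indicator from alternating geometric dwell times (start rest)."""
    walk = np.zeros(T, dtype=bool)
    t, state = 0, 0  # 0 = rest, 1 = walk
    while t < T:
        p = alpha if state == 0 else beta
        if p == 0.0:
            run = T - t  # absorbing
        elif p == 1.0:
            run = 1
        else:
            run = int(rng.geometric(p))
        if state == 1:
            walk[t:t + run] = True
        t += run
        state = 1 - state
    return walk


def _ar1(T: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with the given marginal sd."""
    if sd == 0 or T == 0:
        return np.zeros(T)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=T)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


def simulate_behavior(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> BehaviorTrace:
    """Simulate the walk/rest bout process and ball kinematics.

    During walk, forward speed is gamma-distributed around the
    configured mean (strictly positive) and the rotational flow is a
    smoothed signed process split into non-negative left/right traces.
    All speeds are exactly zero at rest; a configurable fraction of rest
    bouts is relabeled groom or flail (speeds stay zero).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    T = spec.n_frames
    walk = _bout_states(T, spec.p_rest_to_walk, spec.p_walk_to_rest, rng)

    fwd = np.zeros(T)
    rot_l = np.zeros(T)
    rot_r = np.zeros(T)
    n_walk = int(walk.sum())
    if n_walk and spec.mean_forward_speed > 0:
        # shape 9 gives cv = 1/3 around the mean, always > 0
        fwd[walk] = rng.gamma(9.0, spec.mean_forward_speed / 9.0, size=n_walk)
    if n_walk and spec.mean_rot_speed > 0:
        signed = _ar1(T, 0.9, spec.mean_rot_speed / np.sqrt(2.0 / np.pi), rng)
        signed[~walk] = 0.0
        rot_l = np.maximum(signed, 0.0)
        rot_r = np.maximum(-signed, 0.0)

    label = np.where(walk, "walk", "rest").astype(object)
    if spec.groom_bout_frac or spec.flail_bout_frac:
        padded = np.concatenate([[True], walk, [True]])
        edges = np.flatnonzero(np.diff((~padded).astype(np.int8)))
        rest_bouts = list(zip(edges[::2], edges[1::2]))
        for start, stop in rest_bouts:
            u = rng.uniform()
            if u < spec.groom_bout_frac:
                label[start:stop] = "groom"
            elif u < spec.groom_bout_frac + spec.flail_bout_frac:
                label[start:stop] = "flail"
    return BehaviorTrace(fwd, rot_l, rot_r, label, spec.frame_rate_hz)


# ---------------------------------------------------------------------------
# atlas


_REGION_NAMES = [
    "GNG", "AVLP_L", "AVLP_R", "MB_L", "MB_R", "CX", "SLP_L", "SLP_R",
    "AL_L", "AL_R", "LAL_L", "LAL_R", "PENP", "WED_L", "WED_R", "EB",
]


def make_atlas(shape: tuple[int, int, int], n_regions: int, seed: int = 0) -> RegionAtlas:
    """Partition an ellipsoidal "brain" mask into contiguous regions.

    Voxels inside the ellipsoid are assigned to the nearest of
    ``n_regions`` seed points (a Voronoi partition of a convex mask, so
    each region is contiguous); the shell outside is background 0.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    Z, Y, X = shape
    zz, yy, xx = np.meshgrid(np.arange(Z), np.arange(Y), np.arange(X), indexing="ij")
    cz, cy, cx = (Z - 1) / 2, (Y - 1) / 2, (X - 1) / 2
    mask = ((zz - cz) / max(cz, 0.5)) ** 2 + ((yy - cy) / max(cy, 0.5)) ** 2 \
        + ((xx - cx) / max(cx, 0.5)) ** 2 <= 1.0
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError(f"n_regions={n_regions} exceeds {len(coords)} mask voxels")
    centers = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.T)] = assign + 1
    names = {
        i + 1: (_REGION_NAMES[i] if i < len(_REGION_NAMES) else f"region_{i + 1:02d}")
        for i in range(n_regions)
    }
    return RegionAtlas(labels, names)


# ---------------------------------------------------------------------------
# movie rendering


def _blob(shape: tuple[int, int, int], center, scale) -> np.ndarray:
    """Anisotropic Gaussian blob, truncated at 3 scales, peak 1."""
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = ((zz - center[0]) / scale[0]) ** 2 + ((yy - center[1]) / scale[1]) ** 2 \
        + ((xx - center[2]) / scale[2]) ** 2
    m = np.exp(-0.5 * d2)
    m[d2 > 9.0] = 0.0
    return m


def _shift(x: np.ndarray, frames: int) -> np.ndarray:
    """Shift right by ``frames`` (negative = advance), zero padding."""
    if frames == 0:
        return x
    out = np.zeros_like(x)
    if frames > 0:
        out[frames:] = x[:-frames]
    else:
        out[:frames] = x[-frames:]
    return out


def _channel_drive(behavior: BehaviorTrace, channel: str, kernel: np.ndarray) -> np.ndarray:
    """Kernel-convolved behavior channel, unit-sum kernel.

    The unit-sum normalization makes a sustained bout drive the channel
    to 1, so a component's coupling is its fractional ΔF/F change during
    sustained behavior.
    """
    labels = np.asarray(behavior.label, dtype=object)
    if channel in ("walk", "groom", "flail"):
        base = (labels == channel).astype(np.float64)
    elif channel == "turn_left":
        base = behavior.rot_left
    elif channel == "turn_right":
        base = behavior.rot_right
    else:
        raise ValueError(f"unknown coupling channel {channel!r}")
    k = kernel / kernel.sum()
    return np.convolve(base, k)[:len(base)]


def render_movie(
    spec: SyntheticSpec,
    behavior: BehaviorTrace | None = None,
    kernel=None,
    meta: FlyMeta | None = None,
) -> tuple[VolumeSeries, GroundTruth]:
    """Render the fluorescence movie and return it with its ground truth.

    Component time course: a_k(t) = sum_ch c_k,ch * r_ch(t - lead) +
    eta_k(t), where r_ch is the kernel-convolved behavior channel and
    eta_k is seeded AR(1) noise.  Voxel fluorescence:
    F(v, t) = F0(v) * (1 + sum_k M_k(v) a_k(t)) plus Gaussian shot noise
    with sd proportional to sqrt(F) and additive read noise; negative
    values are clipped at zero and counted.
    """
    rng = np.random.default_rng(spec.seed)
    if behavior is None:
        behavior = simulate_behavior(spec, rng)
    if behavior.n_frames != spec.n_frames:
        raise ValueError("behavior length does not match spec.n_frames")
    if kernel is None or not isinstance(kernel, np.ndarray):
        from .regressors import KernelSpec, gcamp_kernel, kernel_for_variant
        kspec = kernel if isinstance(kernel, KernelSpec) else kernel_for_variant("6m")
        kernel = gcamp_kernel(kspec, spec.frame_rate_hz)

    T = spec.n_frames
    K = len(spec.components)
    drives: dict[str, np.ndarray] = {}
    maps = np.zeros((K,) + tuple(spec.shape))
    tcs = np.zeros((K, T))
    for k, comp in enumerate(spec.components):
        maps[k] = _blob(spec.shape, comp.center, comp.scale)
        a = np.zeros(T)
        for ch, gain in comp.coupling.items():
            if ch not in drives:
                drives[ch] = _channel_drive(behavior, ch, kernel)
            a += gain * _shift(drives[ch], int(round(comp.lead_s * spec.frame_rate_hz)))
        a += _ar1(T, comp.noise_ar, comp.noise_sd, rng)
        tcs[k] = a

    F0 = spec.baseline * (1.0 + spec.baseline_variation * (2.0 * rng.random(spec.shape) - 1.0))
    flat_maps = maps.reshape(K, -1)
    F = F0.reshape(1, -1) * (1.0 + tcs.T @ flat_maps)  # (T, V)
    if spec.shot_noise_scale > 0:
        F = F + rng.normal(size=F.shape) * (spec.shot_noise_scale * np.sqrt(np.clip(F, 0, None)))
    if spec.read_noise_sd > 0:
        F = F + rng.normal(0.0, spec.read_noise_sd, size=F.shape)
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("rendered movie contains non-finite values")
    n_clipped = int(np.count_nonzero(F < 0))
    if n_clipped:
        logger.info("clipped %d negative fluorescence values at 0", n_clipped)
        F = np.clip(F, 0.0, None)
    movie = VolumeSeries(F.reshape((T,) + tuple(spec.shape)), spec.frame_rate_hz,
                         space="raw", meta=meta or FlyMeta())
    truth = GroundTruth(maps, tcs, [c.name for c in spec.components],
                        [dict(c.coupling) for c in spec.components],
                        [c.lead_s for c in spec.components], F0, n_clipped)
    return movie, truth


def noiseless_movie(truth: GroundTruth) -> np.ndarray:
    """Reconstruct the noise-free movie (T, Z, Y, X) from the ground truth."""
    K = truth.maps.shape[0]
    flat = truth.maps.reshape(K, -1)
    F = truth.baseline.reshape(1, -1) * (1.0 + truth.time_courses.T @ flat)
    return F.reshape((truth.time_courses.shape[1],) + truth.baseline.shape)
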