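"""Functional component extraction: double SVD plus spatial ICA.

A first SVD estimates each voxel's noise level from the residual after
removing the dominant singular subspace; voxels are divided by their
noise sd so the second, rank-K SVD weighs them by signal-to-noise
rather than raw variance.  The K principal *spatial* maps are then
unmixed with ICA (the sources are the maps, which are sparse and
localized; the time courses may be strongly correlated across
components, which is exactly why the unmixing is spatial).  The same
K×K matrix — applied on the temporal side as its inverse — transforms
the time courses, so the rank-K reconstruction is preserved exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .preprocess import VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentSet",
    "NoiseNormalized",
    "Matching",
    "estimate_noise_and_normalize",
    "extract_components",
    "match_components",
    "default_rank",
]


@dataclass
class ComponentSet:
    """K spatial maps with matched time courses.

    ``maps`` is (K, Z, Y, X) (dimensionless weights), ``time_courses``
    (K, T).  ``maps[k]`` ⊗ ``time_courses[k]`` summed over k equals the
    retained rank-K reconstruction of the (noise-normalized) movie.
    Sign convention: each map's largest-magnitude voxel is positive.
    """

    maps: np.ndarray
    time_courses: np.ndarray
    singular_values: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    unmixing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.time_courses = np.asarray(self.time_courses, dtype=np.float64)
        if self.maps.shape[0] != self.time_courses.shape[0]:
            raise ValueError("maps and time_courses must share K")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def flat_maps(self) -> np.ndarray:
        return self.maps.reshape(self.n_components, -1)

    def reconstruction(self) -> np.ndarray:
        """(T, V) rank-K reconstruction in the normalized space."""
        return self.time_courses.T @ self.flat_maps()

    def maps_dff(self) -> np.ndarray:
        """Maps scaled back to ΔF/F units (undo the noise normalization)."""
        if self.noise_sd is None:
            return self.maps
        return (self.flat_maps() * self.noise_sd).reshape(self.maps.shape)


@dataclass
class NoiseNormalized:
    """Noise-normalized voxel matrix (T, V) plus the per-voxel sd."""

    matrix: np.ndarray
    noise_sd: np.ndarray
    signal_rank: int
    spatial_shape: tuple[int, int, int] | None = None


def _elbow(values: np.ndarray) -> int:
    """Index of the point farthest from the chord between the curve ends.

    A simple knee detector on the log singular-value scree (log so the
    detector responds to the signal/noise gap rather than being swamped
    by a single dominant mode); returns at least 1 so a dominant
    subspace is always removed.
    """
    n = len(values)
    if n < 3:
        return 1
    x = np.arange(n, dtype=float)
    v = np.asarray(values, dtype=float)
    y = np.log(np.maximum(v, v.max() * 1e-15))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / max(norm, 1e-300)
    return max(int(np.argmax(dist)), 1)


def estimate_noise_and_normalize(
    movie: VolumeSeries | np.ndarray,
    max_rank: int = 30,
    noise_floor_rel: float = 1e-6,
    random_state: int = 0,
) -> NoiseNormalized:
    """First SVD: estimate per-voxel noise sd and normalize by it.

    The top-k0 singular subspace (k0 from the scree elbow, floored at 1)
    is treated as signal; the per-voxel sd of the residual, with k0
    degrees of freedom removed, is the noise estimate.  Each voxel is
    divided by max(sd, floor), the floor being ``noise_floor_rel`` times
    the largest sd (so the result is invariant to rescaling the movie).
    """
    if isinstance(movie, VolumeSeries):
        X = movie.data.reshape(movie.n_frames, -1).astype(np.float64)
        shape = movie.spatial_shape
    else:
        X = np.asarray(movie, dtype=np.float64)
        shape = None
    T, V = X.shape
    if T < 2:
        raise ValueError("need at least 2 frames")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("no temporal variance in the movie")
    m = min(max_rank, T - 1, V)
    U, s, Vt = randomized_svd(X, n_components=m, random_state=random_state)
    k0 = min(_elbow(s), m)
    resid = X - (U[:, :k0] * s[:k0]) @ Vt[:k0]
    dof = max(T - k0, 1)
    sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    floor = noise_floor_rel * max(sd.max(), 1e-300)
    normalized = X / np.maximum(sd, floor)
    return NoiseNormalized(normalized, sd, k0, shape)


def default_rank(singular_values: np.ndarray, cap: int = 100) -> int:
    """Default K: singular values above the scree elbow, capped."""
    return min(_elbow(singular_values), cap)


def extract_components(
    normalized: NoiseNormalized | np.ndarray,
    K: int,
    seed: int = 0,
    spatial_shape: tuple[int, int, int] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    strict: bool = True,
) -> ComponentSet:
    """Second SVD to rank K, then spatial ICA.

    ICA (log-cosh contrast, seeded) runs on the K spatial singular
    vectors treated as mixed sources over voxels; the resulting mixing
    matrix A gives maps = A^{-1} V^T and time courses = U S A, so
    maps × time courses reproduces the rank-K SVD reconstruction
    exactly.  Components are sign-aligned (largest-|weight| voxel
    positive) and ordered by explained variance.
    """
    if isinstance(normalized, NoiseNormalized):
        X = normalized.matrix
        noise_sd = normalized.noise_sd
        spatial_shape = spatial_shape or normalized.spatial_shape
    else:
        X = np.asarray(normalized, dtype=np.float64)
        noise_sd = None
    T, V = X.shape
    if not 1 <= K <= min(T, V):
        raise ValueError(f"K={K} out of range for a {T}x{V} matrix")
    U, s, Vt = randomized_svd(X, n_components=K, random_state=seed)
    if s[-1] <= 1e-12 * s[0]:
        raise ValueError(f"K={K} exceeds the numerical rank of the data")

    if K == 1:
        unmix = np.ones((1, 1))
    else:
        # Whiten explicitly (the K spatial singular vectors are already
        # orthonormal over voxels, so this only absorbs the centering)
        # and run the ICA rotation on the whitened maps.
        Xc = Vt.T - Vt.T.mean(axis=0)
        C = (Xc.T @ Xc) / Xc.shape[0]
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 1e-12 * evals.max(), None)
        W_white = (evecs * evals ** -0.5) @ evecs.T  # symmetric C^{-1/2}
        # deterministic restarts: the fixed-point iteration occasionally
        # stalls from an unlucky initial rotation
        ica = None
        for attempt in range(5):
            trial_seed = (seed + 9973 * attempt) % 2**31
            cand = FastICA(whiten=False, fun="logcosh",
                           max_iter=max_iter, tol=tol, random_state=trial_seed)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cand.fit(Xc @ W_white)  # voxels as samples, maps as mixed signals
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                ica = cand
                break
        if ica is None:
            # a persistent limit cycle, typically confined to directions
            # carrying no non-Gaussian structure (pure-noise subspace)
            if strict:
                raise RuntimeError(
                    f"spatial ICA did not converge within {max_iter} iterations "
                    "in any of 5 restarts"
                )
            logger.warning(
                "spatial ICA hit the %d-iteration cap in all restarts; "
                "keeping the last rotation (non-Gaussian components are "
                "typically converged; the cycling directions carry no "
                "independent structure)", max_iter)
            ica = cand
        unmix = ica.components_ @ W_white  # sources = unmix @ (Vt - mean)
    maps = unmix @ Vt              # (K, V); per-map centering offset dropped
    tcs = ((U * s) @ np.linalg.inv(unmix)).T  # (K, T)

    # sign convention: peak |weight| voxel positive
    for k in range(K):
        j = np.argmax(np.abs(maps[k]))
        if maps[k, j] < 0:
            maps[k] *= -1.0
            tcs[k] *= -1.0
    # order by contribution to the reconstruction
    energy = (maps ** 2).sum(axis=1) * (tcs ** 2).sum(axis=1)
    order = np.argsort(energy)[::-1]
    maps, tcs = maps[order], tcs[order]
    unmix = unmix[order]

    if spatial_shape is not None:
        maps = maps.reshape((K,) + tuple(spatial_shape))
    else:
        maps = maps.reshape(K, 1, 1, V)
    return ComponentSet(maps, tcs, singular_values=s, noise_sd=noise_sd, unmixing=unmix)


@dataclass
class Matching:
    """One-to-one pairing between recovered and reference components."""

    pairs: list[tuple[int, int]]          # (recovered index, truth index)
    spatial_cosine: np.ndarray            # |cosine| per pair
    temporal_corr: np.ndarray             # |Pearson r| per pair (nan if unavailable)
    signs: np.ndarray                     # sign reconciling recovered -> truth


def _as_flat_maps(obj) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(obj, ComponentSet):
        return obj.flat_maps(), obj.time_courses
    maps = np.asarray(obj, dtype=np.float64)
    return maps.reshape(maps.shape[0], -1), None


def match_components(recovered, truth) -> Matching:
    """Optimal assignment maximizing summed |spatial cosine|.

    Accepts ComponentSets or bare map stacks; per pair the sign is the
    sign of the (un-absolute) spatial cosine, so ``sign * recovered``
    points the same way as the reference.
    """
    rec_maps, rec_tcs = _as_flat_maps(recovered)
    tru_maps, tru_tcs = _as_flat_maps(truth)
    if rec_maps.shape[1] != tru_maps.shape[1]:
        raise ValueError("map volumes differ in voxel count")

    def unit(M):
        n = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.maximum(n, 1e-300)

    C = unit(rec_maps) @ unit(tru_maps).T
    ri, ti = scipy.optimize.linear_sum_assignment(-np.abs(C))
    cos = np.abs(C[ri, ti])
    signs = np.sign(C[ri, ti])
    signs[signs == 0] = 1.0
    corr = np.full(len(ri), np.nan)
    if rec_tcs is not None and tru_tcs is not None and rec_tcs.shape[1] == tru_tcs.shape[1]:
        for n, (i, j) in enumerate(zip(ri, ti)):
            a, b = rec_tcs[i], tru_tcs[j]
            if np.std(a) > 0 and np.std(b) > 0:
                corr[n] = abs(np.corrcoef(a, b)[0, 1])
    return Matching(list(zip(ri.tolist(), ti.tolist())), cos, corr, signs)
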