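"""Diffusion tensor fields, fractional anisotropy, and deterministic tracking.

The tracker is FACT-like: fixed-step Euler integration along the trilinearly
interpolated principal eigenvector, grown bidirectionally from jittered seed
points.  A step is refused when the interpolated FA at the new point falls
below ``fa_threshold``, when the turning angle between consecutive step
directions exceeds ``angle_threshold_deg``, or when the point leaves the
field of view.  Growth stops once the streamline reaches ``max_length_mm``
(the streamline is kept, truncated); streamlines shorter than
``min_length_mm`` are discarded.  The eigenvector sign at each step is chosen
to continue the current direction, so the tracker is invariant to global sign
flips of the tensor field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Tractogram, VolumeGeometry

__all__ = [
    "TensorVolume", "TrackingConfig", "compute_fa", "track_streamlines",
    "streamline_mean_anisotropy", "eigen_to_lower_triangular",
    "lower_triangular_to_eigen",
]


@dataclass
class TensorVolume:
    """Per-voxel eigen-decomposition of a diffusion tensor field.

    ``eigenvalues``: (X, Y, Z, 3), sorted descending per voxel.
    ``eigenvectors``: (X, Y, Z, 3, 3) with ``[..., i, :]`` the unit
    eigenvector of ``eigenvalues[..., i]``; the three rows form an
    orthonormal frame.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvalues.shape != tuple(self.geometry.dims) + (3,):
            raise ValueError("eigenvalues shape mismatch with geometry")
        if self.eigenvectors.shape != tuple(self.geometry.dims) + (3, 3):
            raise ValueError("eigenvectors shape mismatch with geometry")
        if np.any(np.diff(self.eigenvalues, axis=-1) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        # orthonormality spot check on a deterministic subsample
        flat = self.eigenvectors.reshape(-1, 3, 3)
        probe = flat[:: max(1, len(flat) // 64)]
        gram = probe @ np.swapaxes(probe, -1, -2)
        if not np.allclose(gram, np.eye(3), atol=1e-5):
            raise ValueError("eigenvector frames not orthonormal (tol 1e-5)")

    @property
    def principal_direction(self) -> np.ndarray:
        """(X, Y, Z, 3) unit principal eigenvector field."""
        return self.eigenvectors[..., 0, :]


@dataclass
class TrackingConfig:
    """Termination and seeding rules for deterministic tracking."""

    fa_threshold: float = 0.14
    angle_threshold_deg: float = 45.0
    min_length_mm: float = 30.0
    max_length_mm: float = 300.0
    step_mm: float = 1.0
    seeds_per_voxel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must be in (0, 1)")
        if not 0 < self.angle_threshold_deg <= 90:
            raise ValueError("angle_threshold_deg must be in (0, 90]")
        if not self.min_length_mm < self.max_length_mm:
            raise ValueError("min_length_mm must be < max_length_mm")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


# ---------------------------------------------------------------------------
# fractional anisotropy
# ---------------------------------------------------------------------------

def fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||; zero tensor -> 0."""
    lam = np.asarray(lam, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.zeros_like(den)
    nz = den > 0
    out[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    return np.clip(out, 0.0, 1.0)


def compute_fa(tensors: TensorVolume, neg_tol: float = 1e-10) -> np.ndarray:
    """Scalar FA volume in [0, 1]; all-zero tensors map to FA = 0."""
    lam = tensors.eigenvalues
    scale = max(float(np.abs(lam).max()), 1.0)
    if lam.min() < -neg_tol * scale:
        raise ValueError(
            f"negative eigenvalue beyond tolerance: min {lam.min():.3e}")
    return fa_from_eigenvalues(np.clip(lam, 0.0, None))


# ---------------------------------------------------------------------------
# 6-component symmetric tensor converters (NIfTI lower-triangular order)
# ---------------------------------------------------------------------------

_LT = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]  # Dxx Dxy Dyy Dxz Dyz Dzz


def eigen_to_lower_triangular(eigenvalues: np.ndarray,
                              eigenvectors: np.ndarray) -> np.ndarray:
    """Compose D = sum_i lambda_i v_i v_i^T; return (..., 6) lower-tri."""
    v = np.asarray(eigenvectors, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)
    d = np.einsum("...i,...ij,...ik->...jk", lam, v, v)
    return np.stack([d[..., i, j] for i, j in _LT], axis=-1)


def lower_triangular_to_eigen(components: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose (..., 6) lower-tri tensors; descending eigenvalues."""
    c = np.asarray(components, dtype=float)
    d = np.zeros(c.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_LT):
        d[..., i, j] = c[..., k]
        d[..., j, i] = c[..., k]
    w, v = np.linalg.eigh(d)          # ascending, columns are vectors
    w = w[..., ::-1]
    v = np.swapaxes(v, -1, -2)[..., ::-1, :]   # rows, descending
    return w, v


# ---------------------------------------------------------------------------
# trilinear interpolation on the voxel grid
# ---------------------------------------------------------------------------

_OFFSETS = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                     for k in (0, 1)])


def _corner_weights(cvox: np.ndarray, dims) -> tuple[np.ndarray, np.ndarray]:
    """Corner indices (N, 8, 3) and trilinear weights (N, 8)."""
    dims = np.asarray(dims)
    base = np.floor(cvox).astype(np.int64)
    base = np.clip(base, 0, dims - 2)
    frac = cvox - base
    idx = base[:, None, :] + _OFFSETS[None, :, :]
    w1 = np.stack([1.0 - frac, frac], axis=-1)     # (N, 3, 2)
    w = (w1[:, 0, _OFFSETS[:, 0]] * w1[:, 1, _OFFSETS[:, 1]]
         * w1[:, 2, _OFFSETS[:, 2]])
    return idx, w


def _in_fov(cvox: np.ndarray, dims) -> np.ndarray:
    dims = np.asarray(dims)
    return np.all((cvox >= 0.0) & (cvox <= dims - 1.0), axis=-1)


def interpolate_scalar(volume: np.ndarray, geometry: VolumeGeometry,
                       points_mm: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a scalar volume at world points."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    cvox = np.atleast_2d(geometry.world_to_voxel(pts))
    idx, w = _corner_weights(cvox, geometry.dims)
    vals = volume[idx[..., 0], idx[..., 1], idx[..., 2]]
    out = (vals * w).sum(axis=1)
    return out if len(out) > 1 else out[0]


def _interp_direction(e1: np.ndarray, geometry: VolumeGeometry,
                      cvox: np.ndarray, ref: np.ndarray | None
                      ) -> np.ndarray:
    """Sign-aligned trilinear interpolation of the principal eigenvector.

    Each corner vector is flipped to have nonnegative dot product with the
    reference direction before averaging; the result is renormalised.  With
    ``ref=None`` the corner with the largest weight provides the reference.
    """
    idx, w = _corner_weights(cvox, geometry.dims)
    vecs = e1[idx[..., 0], idx[..., 1], idx[..., 2]]       # (N, 8, 3)
    if ref is None:
        ref = vecs[np.arange(len(cvox)), np.argmax(w, axis=1)]
    sign = np.sign(np.einsum("nkj,nj->nk", vecs, ref))
    sign[sign == 0] = 1.0
    d = np.einsum("nk,nkj->nj", w * sign, vecs)
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    ok = norm[:, 0] > 1e-12
    d = np.where(ok[:, None], d / np.where(ok[:, None], norm, 1.0), 0.0)
    return d


# ---------------------------------------------------------------------------
# streamline tracking
# ---------------------------------------------------------------------------

def _march(e1, fa, geometry, start, start_dir, budget_mm, config):
    """Vectorised one-directional Euler march from ``start`` points.

    Returns a list (per seed) of point arrays, excluding the start point,
    and the marched length per seed.
    """
    n = len(start)
    cos_max = np.cos(np.deg2rad(config.angle_threshold_deg))
    pts: list[list[np.ndarray]] = [[] for _ in range(n)]
    pos = start.copy()
    prev_dir = start_dir.copy()
    length = np.zeros(n)
    active = np.ones(n, dtype=bool) & (budget_mm >= config.step_mm)
    while active.any():
        ia = np.flatnonzero(active)
        cvox = np.atleast_2d(geometry.world_to_voxel(pos[ia]))
        d = _interp_direction(e1, geometry, cvox, prev_dir[ia])
        turn_ok = np.einsum("nj,nj->n", d, prev_dir[ia]) >= cos_max - 1e-12
        turn_ok &= np.linalg.norm(d, axis=1) > 0.5
        newp = pos[ia] + config.step_mm * d
        ncv = np.atleast_2d(geometry.world_to_voxel(newp))
        ok = turn_ok & _in_fov(ncv, geometry.dims)
        fa_new = np.full(len(ia), -1.0)
        if ok.any():
            io = np.flatnonzero(ok)
            idx, w = _corner_weights(ncv[io], geometry.dims)
            fa_new[io] = (fa[idx[..., 0], idx[..., 1], idx[..., 2]]
                          * w).sum(axis=1)
        ok &= fa_new >= config.fa_threshold
        for j in np.flatnonzero(ok):
            pts[ia[j]].append(newp[j])
        gi = ia[ok]
        pos[gi] = newp[ok]
        prev_dir[gi] = d[ok]
        length[gi] += config.step_mm
        active[ia[~ok]] = False
        active[gi] = length[gi] + config.step_mm <= budget_mm[gi]
    return pts, length


def track_streamlines(tensors: TensorVolume, config: TrackingConfig,
                      seed_mask: np.ndarray | None = None) -> Tractogram:
    """Whole-volume deterministic tracking from jittered grid seeds.

    Seeds are placed in every voxel of ``seed_mask`` (default: all voxels)
    whose FA meets ``fa_threshold``, jittered uniformly within the voxel
    (``seeds_per_voxel`` seeds each); the RNG is used only for this jitter,
    so a fixed ``config.seed`` makes the tractogram bit-reproducible.
    """
    geometry = tensors.geometry
    fa = compute_fa(tensors)
    e1 = np.ascontiguousarray(tensors.principal_direction)

    eligible = fa >= config.fa_threshold
    if seed_mask is not None:
        eligible &= np.asarray(seed_mask, dtype=bool)
    vox = np.argwhere(eligible)
    if len(vox) == 0:
        warnings.warn("empty seed mask: returning empty tractogram")
        return Tractogram([], length_mm=np.zeros(0),
                          mean_anisotropy=np.zeros(0))

    rng = np.random.default_rng(config.seed)
    vox = np.repeat(vox, config.seeds_per_voxel, axis=0)
    jitter = rng.uniform(-0.5, 0.5, size=vox.shape)
    seeds = np.atleast_2d(geometry.voxel_to_world(vox + jitter))

    # seed-point validity: inside FOV with FA above threshold
    cvox = np.atleast_2d(geometry.world_to_voxel(seeds))
    valid = _in_fov(cvox, geometry.dims)
    fa_seed = np.zeros(len(seeds))
    iv = np.flatnonzero(valid)
    if iv.size:
        idx, w = _corner_weights(cvox[iv], geometry.dims)
        fa_seed[iv] = (fa[idx[..., 0], idx[..., 1], idx[..., 2]]
                       * w).sum(axis=1)
    valid &= fa_seed >= config.fa_threshold
    seeds = seeds[valid]
    cvox = cvox[valid]
    if len(seeds) == 0:
        return Tractogram([], length_mm=np.zeros(0),
                          mean_anisotropy=np.zeros(0))

    d0 = _interp_direction(e1, geometry, cvox, None)
    good = np.linalg.norm(d0, axis=1) > 0.5
    seeds, d0 = seeds[good], d0[good]

    budget = np.full(len(seeds), config.max_length_mm)
    fwd_pts, fwd_len = _march(e1, fa, geometry, seeds, d0, budget, config)
    # the backward march continues against the first forward step, so the
    # turning angle across the seed junction also obeys the threshold
    back_ref = -d0
    for i, p in enumerate(fwd_pts):
        if p:
            step_dir = (p[0] - seeds[i]) / config.step_mm
            back_ref[i] = -step_dir
    bwd_pts, bwd_len = _march(e1, fa, geometry, seeds, back_ref,
                              budget - fwd_len, config)

    streamlines, lengths = [], []
    for i in range(len(seeds)):
        total = fwd_len[i] + bwd_len[i]
        npts = len(fwd_pts[i]) + len(bwd_pts[i]) + 1
        if npts < 2 or not (config.min_length_mm <= total
                            <= config.max_length_mm):
            continue
        line = np.vstack(list(reversed(bwd_pts[i])) + [seeds[i]]
                         + fwd_pts[i])
        streamlines.append(line)
        lengths.append(total)

    ma = np.array([streamline_mean_anisotropy(s, fa, geometry)
                   for s in streamlines])
    tractogram = Tractogram(streamlines, length_mm=np.array(lengths),
                            mean_anisotropy=ma)
    _validate_tractogram(tractogram, fa, geometry, config)
    return tractogram


def streamline_mean_anisotropy(streamline: np.ndarray, fa_volume: np.ndarray,
                               geometry: VolumeGeometry) -> float:
    """Arithmetic mean of FA trilinearly interpolated at every point."""
    vals = np.atleast_1d(interpolate_scalar(fa_volume, geometry, streamline))
    return float(vals.mean())


def _validate_tractogram(tractogram: Tractogram, fa: np.ndarray,
                         geometry: VolumeGeometry,
                         config: TrackingConfig) -> None:
    """Post-hoc contract check, run on every tracking call."""
    for s, length in zip(tractogram.streamlines, tractogram.length_mm):
        vals = np.atleast_1d(interpolate_scalar(fa, geometry, s))
        assert vals.min() >= config.fa_threshold - 1e-9, \
            "retained streamline dips below the FA threshold"
        steps = np.diff(s, axis=0)
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        if len(steps) > 1:
            cosang = np.clip(np.einsum("ij,ij->i", steps[:-1], steps[1:]),
                             -1.0, 1.0)
            max_turn = np.degrees(np.arccos(cosang)).max()
            assert max_turn <= config.angle_threshold_deg + 1e-6, \
                "turning angle exceeds threshold"
        assert (config.min_length_mm - 1e-9 <= length
                <= config.max_length_mm + 1e-9), "length outside bounds"
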