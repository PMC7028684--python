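"""Synthetic phantoms, meshes, cohorts and lesion masks with known truth.

Every generator is deterministic given its seed, so downstream stages can be
tested end-to-end without any external data.  The pieces emulate:

* tensor phantoms — fiber bundles (cylinders around parametric centerlines)
  with axially symmetric anisotropic tensors embedded in a low-FA background;
* sphere meshes — stand-ins for the cortical GM-WM interface (the pipeline's
  math is geometry-agnostic, so no folding is simulated);
* cohorts — a control group and two patient groups (CSVD with normal
  cognition, CSVD with MCI) whose FiCD maps are a shared template scaled by
  group-specific regional reduction factors and multiplicative log-normal
  subject noise, plus covariates, lesion volumes and cognitive scores;
* lesion masks — connected blobs hitting a target volume on a voxel grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree

from .io import VolumeGeometry
from .mapping import FiCDMap
from .mesh import SurfaceMesh
from .tractography import TensorVolume, fa_from_eigenvalues

__all__ = [
    "StraightSegment", "CircularArc", "PolylineCurve", "BundleSpec",
    "PhantomSpec", "CohortSpec", "CovariateModel", "LesionVolumeModel",
    "ScoreModel", "make_tensor_phantom", "make_sphere_surface",
    "make_cohort", "make_lesion_masks", "diffusivities_for_fa",
]

GROUPS = ("control", "CSVD-NC", "CSVD-MCI")


# ---------------------------------------------------------------------------
# centerline curves (world mm)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StraightSegment:
    start: tuple
    end: tuple

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        a, b = np.asarray(self.start, float), np.asarray(self.end, float)
        length = np.linalg.norm(b - a)
        n = max(2, int(np.ceil(length / spacing)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        pts = a + t * (b - a)
        tan = np.tile((b - a) / length, (n, 1))
        return pts, tan


@dataclass(frozen=True)
class CircularArc:
    """Arc of given radius in the plane spanned by two orthonormal axes."""

    center: tuple
    radius: float
    u_axis: tuple                      # unit vector at angle 0
    v_axis: tuple                      # unit vector at angle 90 deg
    angle_start_deg: float
    angle_end_deg: float

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        u = np.asarray(self.u_axis, float)
        v = np.asarray(self.v_axis, float)
        if abs(u @ v) > 1e-8 or abs(np.linalg.norm(u) - 1) > 1e-8 \
                or abs(np.linalg.norm(v) - 1) > 1e-8:
            raise ValueError("u_axis/v_axis must be orthonormal")
        a0, a1 = np.deg2rad([self.angle_start_deg, self.angle_end_deg])
        arclen = abs(a1 - a0) * self.radius
        n = max(2, int(np.ceil(arclen / spacing)) + 1)
        th = np.linspace(a0, a1, n)[:, None]
        pts = c + self.radius * (np.cos(th) * u + np.sin(th) * v)
        tan = (-np.sin(th) * u + np.cos(th) * v) * np.sign(a1 - a0)
        return pts, tan


@dataclass(frozen=True)
class PolylineCurve:
    points: tuple            # sequence of 3-D control points, mm

    def sample(self, spacing: float) -> tuple[np.ndarray, np.ndarray]:
        ctrl = np.asarray(self.points, float)
        seg = np.diff(ctrl, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        total = s[-1]
        n = max(2, int(np.ceil(total / spacing)) + 1)
        si = np.linspace(0.0, total, n)
        pts = np.column_stack([np.interp(si, s, ctrl[:, k])
                               for k in range(3)])
        tan = np.gradient(pts, si, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return pts, tan


# ---------------------------------------------------------------------------
# bundle and phantom specs
# ---------------------------------------------------------------------------

def diffusivities_for_fa(fa: float, mean_diffusivity: float = 0.7e-3
                         ) -> tuple[float, float]:
    """Axial/radial diffusivity of an axially symmetric tensor with given FA.

    For eigenvalues (a, r, r), FA = (a - r) / sqrt(a^2 + 2 r^2); holding the
    mean diffusivity fixed gives the closed form delta = FA / sqrt(3 - 2 FA^2)
    with a = MD (1 + 2 delta), r = MD (1 - delta).
    """
    if not 0 <= fa <= 1:
        raise ValueError("fa must be in [0, 1]")
    delta = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    return (mean_diffusivity * (1.0 + 2.0 * delta),
            mean_diffusivity * (1.0 - delta))


@dataclass(frozen=True)
class BundleSpec:
    centerline: object
    radius_mm: float
    fa: float
    axial_diffusivity: float
    radial_diffusivity: float

    def __post_init__(self) -> None:
        if not 0 < self.fa <= 1:
            raise ValueError("bundle fa must be in (0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.axial_diffusivity <= 0 or self.radial_diffusivity < 0:
            raise ValueError("diffusivities must be positive")
        lam = np.array([self.axial_diffusivity, self.radial_diffusivity,
                        self.radial_diffusivity])
        got = float(fa_from_eigenvalues(lam[None, :])[0])
        if abs(got - self.fa) > 1e-6:
            raise ValueError(
                f"diffusivities give FA {got:.8f}, field says {self.fa}")

    @classmethod
    def from_fa(cls, centerline, radius_mm: float, fa: float,
                mean_diffusivity: float = 0.7e-3) -> "BundleSpec":
        ad, rd = diffusivities_for_fa(fa, mean_diffusivity)
        return cls(centerline, radius_mm, fa, ad, rd)


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple
    voxel_size_mm: tuple
    bundles: tuple
    background_fa: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError("shape must be 3 integers, all >= 8")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not 0 <= self.background_fa < 1:
            raise ValueError("background_fa must be in [0, 1)")
        for b in self.bundles:
            if b.fa <= self.background_fa:
                raise ValueError("background_fa must be below every "
                                 "bundle's fa")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry.from_spacing(self.shape, self.voxel_size_mm)


def _complete_frame(e1: np.ndarray) -> np.ndarray:
    """Orthonormal frames (n, 3, 3) with given unit first rows."""
    n = len(e1)
    helper = np.tile([1.0, 0.0, 0.0], (n, 1))
    bad = np.abs(e1[:, 0]) > 0.9
    helper[bad] = [0.0, 1.0, 0.0]
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def make_tensor_phantom(spec: PhantomSpec) -> TensorVolume:
    """Cylindrical fiber bundles in a low-anisotropy background.

    Voxels within ``radius_mm`` of a bundle centerline carry an axially
    symmetric tensor whose principal eigenvector is the centerline tangent at
    the nearest sample; other voxels carry a tensor with FA equal to
    ``background_fa`` and a seeded random orientation.  Voxels claimed by
    several bundles go to the nearest centerline (with a warning).
    """
    geom = spec.geometry()
    rng = np.random.default_rng(spec.seed)
    dims = tuple(spec.shape)
    nvox = int(np.prod(dims))

    ijk = np.indices(dims).reshape(3, -1).T
    centers = np.atleast_2d(geom.voxel_to_world(ijk))

    # background: axially symmetric FA = background_fa, random orientation
    md = 0.7e-3
    ad_bg, rd_bg = diffusivities_for_fa(spec.background_fa, md)
    lam = np.tile([ad_bg, rd_bg, rd_bg], (nvox, 1))
    if spec.background_fa > 0:
        v = rng.normal(size=(nvox, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frames = _complete_frame(v)
    else:
        frames = np.tile(np.eye(3), (nvox, 1, 1))

    best = np.full(nvox, np.inf)
    claimed = np.zeros(nvox, dtype=bool)
    spacing = min(spec.voxel_size_mm) / 4.0
    conflict = False
    for bundle in spec.bundles:
        pts, tan = bundle.centerline.sample(spacing)
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers)
        inside = dist <= bundle.radius_mm
        conflict |= bool(np.any(inside & claimed & (dist < best)))
        take = inside & (dist < best)
        best[take] = dist[take]
        claimed |= inside
        lam[take] = [bundle.axial_diffusivity, bundle.radial_diffusivity,
                     bundle.radial_diffusivity]
        frames[take] = _complete_frame(tan[nearest[take]])
    if conflict:
        warnings.warn("overlapping bundles: voxels assigned to the nearest "
                      "centerline")

    if spec.noise_sd > 0:
        pert = 1.0 + rng.normal(scale=spec.noise_sd, size=lam.shape)
        lam = np.clip(lam * pert, 0.0, None)
        order = np.argsort(-lam, axis=1, kind="stable")
        lam = np.take_along_axis(lam, order, axis=1)
        frames = np.take_along_axis(frames, order[:, :, None], axis=1)

    return TensorVolume(
        eigenvalues=lam.reshape(dims + (3,)),
        eigenvectors=frames.reshape(dims + (3, 3)),
        geometry=geom)


# ---------------------------------------------------------------------------
# sphere surface
# ---------------------------------------------------------------------------

def make_sphere_surface(n_vertices: int, radius_mm: float = 50.0
                        ) -> SurfaceMesh:
    """Closed genus-0 triangulation of a sphere with exactly n vertices.

    Vertices are a Fibonacci lattice on the sphere; the triangulation is the
    convex hull (every lattice point is in convex position, so the vertex
    count is exact), with faces flipped to consistent outward orientation.
    """
    if n_vertices < 100:
        raise ValueError("n_vertices must be >= 100")
    i = np.arange(n_vertices)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return SurfaceMesh(pts * radius_mm, faces)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateModel:
    """Demographics matched across groups (age/sex/education)."""

    age_mean: float = 63.5
    age_sd: float = 6.7
    sex_p_male: float = 0.6
    education_mean: float = 9.0
    education_sd: float = 3.5


@dataclass(frozen=True)
class LesionVolumeModel:
    """Per-group log-normal lesion burdens (ml), heavier in CSVD-MCI."""

    wmh_median_ml: tuple = (0.5, 6.0, 13.0)
    wmh_log_sd: float = 0.8
    lacune_median_ml: tuple = (0.0, 0.25, 0.7)
    lacune_log_sd: float = 0.7
    rbv_mean: tuple = (0.80, 0.79, 0.77)
    rbv_sd: float = 0.025


@dataclass(frozen=True)
class ScoreModel:
    """Cognitive scores linearly linked to regional FiCD plus noise."""

    names: tuple = ("composite",)
    baseline: float = 10.0
    slope: float = 8.0        # score units per unit relative FiCD change
    noise_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: tuple = (35, 34, 22)
    effect_regions: tuple = ()   # ((cu_ids, (f_ctrl, f_nc, f_mci)), ...)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    lesion_volume_model: LesionVolumeModel = field(
        default_factory=LesionVolumeModel)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    map_noise_sigma: float = 0.1    # log-normal sigma on per-CU values
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 3 for n in self.n_per_group):
            raise ValueError("need 3 group sizes, each >= 3")
        for region, factors in self.effect_regions:
            if len(region) == 0:
                raise ValueError("effect region is empty")
            if any(not 0 < f <= 1 for f in factors):
                raise ValueError("reduction factors must be in (0, 1]")


def make_cohort(spec: CohortSpec, template_map: FiCDMap
                ) -> tuple[list[FiCDMap], pd.DataFrame]:
    """Per-subject FiCD maps plus the cohort covariate table.

    Each subject's CU values are the template times the group's regional
    reduction factors times multiplicative log-normal noise.  Covariates,
    lesion volumes, relative brain volume and cognitive scores follow the
    configured distribution models; everything derives from one seeded RNG.
    """
    rng = np.random.default_rng(spec.seed)
    n_units = template_map.n_units
    for region, _ in spec.effect_regions:
        if max(region) >= n_units or min(region) < 0:
            raise ValueError("effect region references invalid CU ids")

    group_factor = np.ones((3, n_units))
    for region, factors in spec.effect_regions:
        idx = np.fromiter(region, dtype=np.int64)
        for g in range(3):
            group_factor[g, idx] *= factors[g]

    effect_cus = sorted({c for region, _ in spec.effect_regions
                         for c in region})
    roi = (np.fromiter(effect_cus, dtype=np.int64) if effect_cus
           else np.arange(n_units))
    template_roi_mean = float(template_map.cu_values[roi].mean())

    cov = spec.covariate_model
    les = spec.lesion_volume_model
    sco = spec.score_model
    maps: list[FiCDMap] = []
    rows = []
    sid = 0
    for g, n in enumerate(spec.n_per_group):
        for _ in range(n):
            noise = np.exp(rng.normal(scale=spec.map_noise_sigma,
                                      size=n_units))
            cu_vals = template_map.cu_values * group_factor[g] * noise
            subject = f"sub-{sid:03d}"
            maps.append(FiCDMap(cu_values=cu_vals,
                                vertex_cu=(None if template_map.vertex_cu
                                           is None else
                                           template_map.vertex_cu.copy()),
                                vertex_values=(None if template_map.vertex_cu
                                               is not None else
                                               cu_vals.copy()),
                                subject_id=subject))
            age = rng.normal(cov.age_mean, cov.age_sd)
            sex = int(rng.random() < cov.sex_p_male)
            edu = max(0, round(rng.normal(cov.education_mean,
                                          cov.education_sd)))
            wmh = (les.wmh_median_ml[g]
                   * np.exp(rng.normal(scale=les.wmh_log_sd))
                   if les.wmh_median_ml[g] > 0 else 0.0)
            lac = (les.lacune_median_ml[g]
                   * np.exp(rng.normal(scale=les.lacune_log_sd))
                   if les.lacune_median_ml[g] > 0 else 0.0)
            rbv = float(np.clip(rng.normal(les.rbv_mean[g], les.rbv_sd),
                                0.5, 1.0))
            regional = float(cu_vals[roi].mean())
            row = {"subject_id": subject, "group": GROUPS[g],
                   "age": round(age, 1), "sex": sex, "education": edu,
                   "wmh_volume_ml": wmh, "lacune_volume_ml": lac,
                   "relative_brain_volume": rbv}
            for name in sco.names:
                rel = regional / template_roi_mean - 1.0
                row[name] = (sco.baseline + sco.slope * rel
                             + rng.normal(scale=sco.noise_sd))
            rows.append(row)
            sid += 1
    return maps, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------

def make_lesion_masks(volume_target_ml: float, grid: VolumeGeometry,
                      n_components: int = 1, seed: int = 0) -> np.ndarray:
    """Binary mask of ``n_components`` blobs totalling the target volume.

    The voxel count is the target volume rounded to the nearest voxel, split
    as evenly as possible across components; each component is the set of
    unclaimed voxels nearest its center, which yields compact connected
    blobs.  Deterministic given seed.
    """
    vv = grid.voxel_volume_mm3
    if volume_target_ml * 1000.0 < vv:
        raise ValueError(f"target {volume_target_ml} ml is smaller than one "
                         f"voxel ({vv} mm^3)")
    total = max(1, int(round(volume_target_ml * 1000.0 / vv)))
    if n_components < 1 or n_components > total:
        raise ValueError("n_components must be in [1, total voxels]")
    counts = np.full(n_components, total // n_components)
    counts[: total % n_components] += 1

    dims = np.array(grid.dims)
    rng = np.random.default_rng(seed)
    for _ in range(200):
        mask = np.zeros(grid.dims, dtype=bool)
        radii = np.cbrt(3.0 * counts * vv / (4.0 * np.pi)) \
            / np.asarray(grid.voxel_size_mm).min()
        centers = []
        ok = True
        for r in radii:
            for _ in range(200):
                c = rng.uniform(r + 1, dims - r - 1)
                if all(np.linalg.norm(c - o) > r + ro + 2.5
                       for o, ro in centers):
                    centers.append((c, r))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        ijk = np.indices(grid.dims).reshape(3, -1).T
        world = np.atleast_2d(grid.voxel_to_world(ijk))
        claimed = np.zeros(len(ijk), dtype=bool)
        for (c, _), m in zip(centers, counts):
            cw = np.asarray(grid.voxel_to_world(c))
            d = np.linalg.norm(world - cw, axis=1)
            d[claimed] = np.inf
            pick = np.argsort(d, kind="stable")[:m]
            claimed[pick] = True
            mask[tuple(ijk[pick].T)] = True
        labeled, found = ndimage.label(mask)
        if found == n_components and int(mask.sum()) == total:
            return mask
    raise RuntimeError("could not place the requested lesion components; "
                       "grid too small for the target volume")
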