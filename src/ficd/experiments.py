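"""Canonical phantoms and simulation experiments for pipeline validation.

The phantom builders fix the geometries used throughout the test suite and
the analysis scripts: a straight 80-mm bundle, a 40-mm-radius circular arc,
a pair of bundles straddling the minimum-length filter, and a serpentine
bundle longer than the maximum length.  The experiment drivers quantify the
statistical behaviour of the full vertex-wise pipeline on synthetic cohorts:
family-wise false-positive rate on null cohorts, and spatial recovery
(Dice overlap) of an injected regional FiCD reduction.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .mapping import FiCDMap, smooth_columns
from .mesh import SurfaceMesh
from .parcellation import Parcellation, parcellate_surface
from .stats import (GLMDesign, estimate_residual_fwhm,
                    monte_carlo_cluster_correction, ols_residuals,
                    vertexwise_glm)
from .synthetic import (BundleSpec, CircularArc, CohortSpec, PhantomSpec,
                        PolylineCurve, StraightSegment, make_cohort,
                        make_sphere_surface)

__all__ = [
    "straight_bundle_phantom", "arc_bundle_phantom", "two_bundle_phantom",
    "serpentine_bundle_phantom", "make_template_map",
    "null_fwer_experiment", "recovery_experiment", "geodesic_cap_cus",
]


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def straight_bundle_phantom(length_mm: float = 80.0, fa: float = 0.8,
                            background_fa: float = 0.05,
                            radius_mm: float = 4.0, noise_sd: float = 0.0,
                            seed: int = 0) -> PhantomSpec:
    """One straight bundle along +x on a 1-mm grid, 10-mm margins."""
    shape = (int(length_mm) + 20, 25, 25)
    c = 12.0
    bundle = BundleSpec.from_fa(
        StraightSegment((10.0, c, c), (10.0 + length_mm, c, c)),
        radius_mm, fa)
    return PhantomSpec(shape=shape, voxel_size_mm=(1.0, 1.0, 1.0),
                       bundles=(bundle,), background_fa=background_fa,
                       noise_sd=noise_sd, seed=seed)


def arc_bundle_phantom(arc_radius_mm: float = 40.0,
                       sweep_deg: float = 150.0, fa: float = 0.8,
                       background_fa: float = 0.05, radius_mm: float = 3.0,
                       seed: int = 0) -> PhantomSpec:
    """Circular-arc bundle in the xy plane (arc length r * sweep)."""
    center = (48.0, 14.0, 12.0)
    bundle = BundleSpec.from_fa(
        CircularArc(center=center, radius=arc_radius_mm,
                    u_axis=(1.0, 0.0, 0.0), v_axis=(0.0, 1.0, 0.0),
                    angle_start_deg=15.0,
                    angle_end_deg=15.0 + sweep_deg),
        radius_mm, fa)
    return PhantomSpec(shape=(100, 72, 25), voxel_size_mm=(1.0, 1.0, 1.0),
                       bundles=(bundle,), background_fa=background_fa,
                       seed=seed)


def two_bundle_phantom(short_mm: float = 20.0, long_mm: float = 80.0,
                       fa: float = 0.8, background_fa: float = 0.05,
                       radius_mm: float = 3.0, seed: int = 0) -> PhantomSpec:
    """Two parallel straight bundles straddling the length filter."""
    shape = (int(max(short_mm, long_mm)) + 20, 25, 45)
    b_short = BundleSpec.from_fa(
        StraightSegment((10.0, 12.0, 12.0), (10.0 + short_mm, 12.0, 12.0)),
        radius_mm, fa)
    b_long = BundleSpec.from_fa(
        StraightSegment((10.0, 12.0, 32.0), (10.0 + long_mm, 12.0, 32.0)),
        radius_mm, fa)
    return PhantomSpec(shape=shape, voxel_size_mm=(1.0, 1.0, 1.0),
                       bundles=(b_short, b_long),
                       background_fa=background_fa, seed=seed)


def serpentine_bundle_phantom(total_length_mm: float = 350.0,
                              amplitude_mm: float = 25.0,
                              wavelength_mm: float = 100.0,
                              fa: float = 0.8, background_fa: float = 0.05,
                              radius_mm: float = 3.0,
                              seed: int = 0) -> PhantomSpec:
    """A gently curving sine-wave bundle of the requested arc length.

    With the default amplitude/wavelength the per-millimetre turning is a
    few degrees, far below the 45-degree threshold, so length (not angle)
    terminates tracking.
    """
    x = np.arange(0.0, 5000.0, 0.25)
    y = amplitude_mm * np.sin(2.0 * np.pi * x / wavelength_mm)
    pts = np.column_stack([x, y, np.zeros_like(x)])
    s = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    keep = s <= total_length_mm
    pts = pts[keep]
    x_extent = float(pts[:, 0].max())
    offset = np.array([10.0, amplitude_mm + radius_mm + 8.0, 12.0])
    pts = pts + offset
    shape = (int(np.ceil(x_extent)) + 20,
             int(np.ceil(2 * (amplitude_mm + radius_mm + 8.0))) + 2, 25)
    bundle = BundleSpec.from_fa(PolylineCurve(tuple(map(tuple, pts))),
                                radius_mm, fa)
    return PhantomSpec(shape=shape, voxel_size_mm=(1.0, 1.0, 1.0),
                       bundles=(bundle,), background_fa=background_fa,
                       seed=seed)


# ---------------------------------------------------------------------------
# template maps and regions
# ---------------------------------------------------------------------------

def make_template_map(parcellation: Parcellation, mesh: SurfaceMesh,
                      seed: int = 0, base_value: float = 0.12,
                      log_sd: float = 0.25,
                      smoothness_fwhm_mm: float = 15.0) -> FiCDMap:
    """Smooth, strictly positive template FiCD map on a parcellated surface.

    Spatially correlated log-normal values around ``base_value`` mimic the
    regional variation of a real connectivity-density map.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mesh.n_vertices)
    sm = smooth_columns(mesh, noise[:, None], smoothness_fwhm_mm)[:, 0]
    sm = (sm - sm.mean()) / sm.std()
    cu_vals = np.array([base_value * np.exp(log_sd * sm[u.vertex_ids].mean())
                        for u in parcellation.units])
    return FiCDMap(cu_values=cu_vals, vertex_cu=parcellation.labels.copy(),
                   subject_id="template")


def geodesic_cap_cus(parcellation: Parcellation, mesh: SurfaceMesh,
                     center_vertex: int, radius_mm: float) -> frozenset:
    """CUs whose medoid lies within a geodesic radius of a center vertex."""
    d = dijkstra(mesh.edge_graph(), directed=False, indices=center_vertex)
    return frozenset(u.cu_id for u in parcellation.units
                     if d[u.medoid_vertex] <= radius_mm)


# ---------------------------------------------------------------------------
# pipeline-level statistical experiments
# ---------------------------------------------------------------------------

def _cohort_setting(mesh_vertices: int, k_units: int, seed: int
                    ) -> tuple[SurfaceMesh, Parcellation, FiCDMap]:
    mesh = make_sphere_surface(mesh_vertices, radius_mm=50.0)
    parc = parcellate_surface(mesh, k_units, seed=seed)
    template = make_template_map(parc, mesh, seed=seed)
    return mesh, parc, template


def _compare_two_groups(maps, table, mesh, group_a, group_b, fwhm_mm,
                        cluster_p, mc_iter, mc_seed):
    sel = table["group"].isin([group_a, group_b]).to_numpy()
    rows = np.flatnonzero(sel)
    used = [maps[i] for i in rows]
    mat = np.column_stack([m.vertex_values for m in used])
    sm = smooth_columns(mesh, mat, fwhm_mm)
    smoothed = [FiCDMap(cu_values=m.cu_values, vertex_values=sm[:, j],
                        smoothed=True, fwhm_mm=fwhm_mm)
                for j, m in enumerate(used)]
    ind = (table.iloc[rows]["group"] == group_a).to_numpy(float)
    design = GLMDesign(np.column_stack([np.ones(len(ind)), ind]),
                       [0.0, 1.0], ("intercept", "group"))
    t_map, _, df = vertexwise_glm(smoothed, design)
    # the null must match the smoothness of the data residual field, which
    # exceeds the applied kernel because FiCD values are constant within a
    # CU before smoothing; estimate it from the residuals
    null_fwhm = estimate_residual_fwhm(ols_residuals(smoothed, design),
                                       mesh)
    return monte_carlo_cluster_correction(
        t_map, df, mesh, cluster_p=cluster_p, n_iter=mc_iter,
        fwhm_mm=null_fwhm, seed=mc_seed)


def null_fwer_experiment(n_replicates: int = 500, n_per_group: int = 20,
                         mesh_vertices: int = 2562, k_units: int = 256,
                         mc_iter: int = 500, cluster_p: float = 0.01,
                         fwhm_mm: float = 10.0, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Family-wise false-positive rate of the full pipeline on null cohorts.

    Each replicate draws a cohort with no group effect, smooths, runs the
    vertex-wise GLM and Monte Carlo cluster correction, and records whether
    any cluster is significant at ``alpha``.  Returns the empirical rate and
    its binomial 95% interval around the nominal level.
    """
    mesh, parc, template = _cohort_setting(mesh_vertices, k_units, seed)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        s1, s2 = rng.integers(2 ** 31, size=2)
        spec = CohortSpec(n_per_group=(n_per_group, n_per_group, 3),
                          effect_regions=(), seed=int(s1))
        maps, table = make_cohort(spec, template)
        clusters = _compare_two_groups(maps, table, mesh, "control",
                                       "CSVD-NC", fwhm_mm, cluster_p,
                                       mc_iter, int(s2))
        if any(c.corrected_p < alpha for c in clusters):
            hits += 1
    rate = hits / n_replicates
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_replicates)
    return {"fwer": rate, "n_replicates": n_replicates, "hits": hits,
            "nominal": alpha,
            "binomial_interval": (alpha - half, alpha + half)}


def recovery_experiment(n_replicates: int = 20, reduction: float = 0.7,
                        region_radius_mm: float = 18.0,
                        n_per_group: int = 20, mesh_vertices: int = 2562,
                        k_units: int = 256, mc_iter: int = 500,
                        cluster_p: float = 0.01, fwhm_mm: float = 10.0,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Spatial recovery of an injected regional FiCD reduction.

    A geodesic-cap region of CUs gets its FiCD multiplied by ``reduction``
    in the patient group; per replicate the Dice overlap between the union
    of significant cluster vertices and the injected region's vertices is
    recorded.
    """
    mesh, parc, template = _cohort_setting(mesh_vertices, k_units, seed)
    region = geodesic_cap_cus(parc, mesh, center_vertex=0,
                              radius_mm=region_radius_mm)
    region_vertices = np.isin(parc.labels, list(region))
    rng = np.random.default_rng(seed + 1)
    dices = []
    for _ in range(n_replicates):
        s1, s2 = rng.integers(2 ** 31, size=2)
        spec = CohortSpec(n_per_group=(n_per_group, n_per_group, 3),
                          effect_regions=((region, (1.0, reduction, 1.0)),),
                          seed=int(s1))
        maps, table = make_cohort(spec, template)
        clusters = _compare_two_groups(maps, table, mesh, "control",
                                       "CSVD-NC", fwhm_mm, cluster_p,
                                       mc_iter, int(s2))
        detected = np.zeros(mesh.n_vertices, dtype=bool)
        for c in clusters:
            if c.corrected_p < alpha:
                detected[c.member_vertices] = True
        inter = np.sum(detected & region_vertices)
        denom = detected.sum() + region_vertices.sum()
        dices.append(2.0 * inter / denom if denom else 0.0)
    dices = np.array(dices)
    return {"dice": dices, "median_dice": float(np.median(dices)),
            "fraction_dice_ge_half": float(np.mean(dices >= 0.5)),
            "n_replicates": n_replicates}
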