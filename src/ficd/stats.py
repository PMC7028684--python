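"""Vertex-wise group inference and cohort-level statistics.

Vertex-wise comparisons use an ordinary-least-squares general linear model
(group indicators plus covariates) with a t contrast per vertex, followed by
cluster-extent family-wise correction: contiguous vertices with uncorrected
two-sided p below the cluster-forming threshold are grouped, and each
cluster's extent (summed vertex area, mm^2) is compared against a Monte
Carlo null distribution of maximal extents from synthesized smooth Gaussian
noise maps subjected to the same thresholding.

Cohort-level pieces: the global-FiCD reduction ratio relative to controls,
regional means, pooled z-scoring of cognitive scores, partial Pearson
correlation by residualization, per-marker regressions of global FiCD, and
one-way ANOVA with Bonferroni and Tamhane-T2 post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components, dijkstra

from .mapping import FiCDMap, smooth_columns
from .mesh import SurfaceMesh

__all__ = [
    "GLMDesign", "ClusterResult", "group_contrast_design", "vertexwise_glm",
    "ols_residuals", "estimate_residual_fwhm",
    "monte_carlo_cluster_correction", "reduction_ratio", "regional_ficd",
    "zscore_scores", "partial_pearson", "global_regressions", "group_anova",
]


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMDesign:
    """Design matrix (subjects x predictors) and a contrast over predictors."""

    matrix: np.ndarray
    contrast: np.ndarray
    columns: tuple = ()

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float)
        n, p = self.matrix.shape
        if len(self.contrast) != p:
            raise ValueError("contrast length must match predictor count")
        if not self.columns:
            self.columns = tuple(f"x{j}" for j in range(p))
        if np.linalg.matrix_rank(self.matrix) < p:
            r = np.abs(np.diag(np.linalg.qr(self.matrix, mode="r")))
            bad = [self.columns[j] for j in np.flatnonzero(
                r < 1e-10 * max(r.max(), 1.0))]
            raise ValueError(f"design matrix is rank deficient; collinear "
                             f"columns: {bad or 'unidentified'}")


def group_contrast_design(table: pd.DataFrame, group_a: str, group_b: str,
                          covariates: tuple = ()) -> tuple[GLMDesign,
                                                           np.ndarray]:
    """Two-group contrast (a minus b) with optional covariate columns.

    Returns the design and the row indices of the used subjects.
    """
    sel = table["group"].isin([group_a, group_b]).to_numpy()
    rows = np.flatnonzero(sel)
    sub = table.iloc[rows]
    ind = (sub["group"] == group_a).to_numpy(float)
    cols = [np.ones(len(sub)), ind]
    names = ["intercept", f"{group_a}_vs_{group_b}"]
    for c in covariates:
        cols.append(sub[c].to_numpy(float))
        names.append(c)
    contrast = np.zeros(len(cols))
    contrast[1] = 1.0
    return GLMDesign(np.column_stack(cols), contrast, tuple(names)), rows


def vertexwise_glm(maps: list[FiCDMap], design: GLMDesign
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-vertex OLS t and two-sided p for the contrast.

    Returns ``(t_map, p_map, df)`` with df the residual degrees of freedom.
    """
    y = np.stack([m.vertex_values for m in maps])          # (n, V)
    x = design.matrix
    n, p = x.shape
    if len(y) != n:
        raise ValueError("number of maps does not match design rows")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                                # (p, V)
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    c = design.contrast
    var_c = float(c @ xtx_inv @ c)
    se = np.sqrt(np.maximum(sigma2 * var_c, 0.0))
    # a vanishing residual variance means an exact fit: define t = 0 there
    floor = 1e-10 * np.sqrt(var_c) * (np.sqrt((y ** 2).mean()) + 1.0)
    ok = se > floor
    t = np.where(ok, (c @ beta) / np.where(ok, se, 1.0), 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return t, pvals, df


def ols_residuals(maps: list[FiCDMap], design: GLMDesign) -> np.ndarray:
    """Per-vertex OLS residual matrix (subjects x vertices)."""
    y = np.stack([m.vertex_values for m in maps])
    x = design.matrix
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def estimate_residual_fwhm(residuals: np.ndarray, mesh: SurfaceMesh
                           ) -> float:
    """Effective Gaussian FWHM of a residual field from its autocorrelation.

    For white noise convolved with a Gaussian kernel of spatial sd s, the
    field autocorrelation at geodesic lag d is exp(-d^2 / (4 s^2)) and
    FWHM = sqrt(8 ln 2) s.  The estimate first inverts the mean correlation
    over mesh edges (single lag), then refines s by a through-origin fit of
    -log rho against d^2 over geodesic lags out to one
    FWHM (the scale that governs threshold-excursion extents), which
    captures structure a single lag misses.  This is the smoothness the
    Monte Carlo null should reproduce; the applied kernel understates it
    whenever the data carry intrinsic spatial structure (e.g. values
    constant within a CU before smoothing).
    """
    r = np.asarray(residuals, dtype=float)
    r = r - r.mean(axis=0)
    sd = r.std(axis=0)
    rn = r / np.where(sd > 0, sd, 1.0)
    e = mesh.edges()
    h_bar = float(np.linalg.norm(
        mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean())
    rho1 = float((rn[:, e[:, 0]] * rn[:, e[:, 1]]).mean())
    rho1 = min(max(rho1, 1e-6), 1.0 - 1e-9)
    fwhm0 = float(np.sqrt(8.0 * np.log(2.0)
                          * (-h_bar ** 2 / (4.0 * np.log(rho1)))))

    sources = np.arange(0, mesh.n_vertices,
                        max(1, mesh.n_vertices // 100))
    dist = dijkstra(mesh.edge_graph(), directed=False, indices=sources,
                    limit=fwhm0)
    d_all, rho_all = [], []
    for si, s in enumerate(np.atleast_1d(sources)):
        row = np.atleast_2d(dist)[si]
        j = np.flatnonzero(np.isfinite(row) & (row > 0))
        if j.size == 0:
            continue
        d_all.append(row[j])
        rho_all.append((rn[:, s][:, None] * rn[:, j]).mean(axis=0))
    d = np.concatenate(d_all)
    rho = np.concatenate(rho_all)
    keep = rho > 0.05
    if keep.sum() < 10:
        return fwhm0
    x = d[keep] ** 2
    y = -np.log(rho[keep])
    s2 = float((x @ x) / (x @ y)) / 4.0
    return float(np.sqrt(8.0 * np.log(2.0) * s2))


# ---------------------------------------------------------------------------
# Monte Carlo cluster-extent correction
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    cluster_id: int
    size_mm2: float
    peak_vertex: int
    peak_coordinate_mm: np.ndarray
    member_vertices: np.ndarray
    corrected_p: float


def _clusters_from_mask(mask: np.ndarray, adjacency: sp.csr_matrix
                        ) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    _, comp = connected_components(sub, directed=False)
    return [idx[comp == c] for c in range(comp.max() + 1)]


def _max_null_extents(mesh: SurfaceMesh, cluster_p: float, n_iter: int,
                      fwhm_mm: float, seed: int) -> np.ndarray:
    """Max cluster extent (mm^2) per synthesized smooth Gaussian null map."""
    rng = np.random.default_rng(seed)
    v = mesh.n_vertices
    noise = rng.standard_normal((v, n_iter))
    smoothed = smooth_columns(mesh, noise, fwhm_mm)
    smoothed -= smoothed.mean(axis=0)
    smoothed /= smoothed.std(axis=0, ddof=0)
    z_crit = sps.norm.isf(cluster_p / 2.0)
    areas = mesh.vertex_areas()
    adj = mesh.adjacency()
    out = np.zeros(n_iter)
    for i in range(n_iter):
        mask = np.abs(smoothed[:, i]) > z_crit
        clusters = _clusters_from_mask(mask, adj)
        if clusters:
            out[i] = max(areas[c].sum() for c in clusters)
    return out


def monte_carlo_cluster_correction(t_map: np.ndarray, df: int,
                                   mesh: SurfaceMesh,
                                   cluster_p: float = 0.01,
                                   n_iter: int = 10000,
                                   fwhm_mm: float = 10.0,
                                   seed: int = 0) -> list[ClusterResult]:
    """Cluster-extent correction against a smooth-Gaussian-noise null.

    Observed clusters are contiguous vertices with two-sided uncorrected
    p < ``cluster_p``; each cluster's corrected p is the fraction of null
    iterations whose maximal cluster extent is at least the observed extent.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    t_map = np.asarray(t_map, dtype=float)
    p_map = 2.0 * sps.t.sf(np.abs(t_map), df)
    mask = (p_map < cluster_p) if cluster_p < 1.0 \
        else np.ones_like(p_map, dtype=bool)
    clusters = _clusters_from_mask(mask, mesh.adjacency())
    if not clusters:
        return []
    null_max = _max_null_extents(mesh, cluster_p, n_iter, fwhm_mm, seed)
    areas = mesh.vertex_areas()
    results = []
    order = np.argsort([-areas[c].sum() for c in clusters])
    for rank, ci in enumerate(order):
        members = clusters[ci]
        extent = float(areas[members].sum())
        peak = int(members[np.argmax(np.abs(t_map[members]))])
        results.append(ClusterResult(
            cluster_id=rank, size_mm2=extent, peak_vertex=peak,
            peak_coordinate_mm=mesh.vertices[peak].copy(),
            member_vertices=members,
            corrected_p=float(np.mean(null_max >= extent))))
    return results


# ---------------------------------------------------------------------------
# summaries and correlations
# ---------------------------------------------------------------------------

def reduction_ratio(control_mean: float, group_mean: float) -> float:
    """(control - group) / control as a percentage."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - group_mean) / control_mean


def regional_ficd(ficd_map: FiCDMap, roi_cu_ids) -> float:
    """Unweighted mean FiCD over the ROI's CUs."""
    idx = np.fromiter(roi_cu_ids, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("ROI is empty")
    return float(ficd_map.cu_values[idx].mean())


def zscore_scores(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Z-transform each score column over all subjects pooled (sample sd)."""
    out = table.copy()
    for c in columns:
        x = out[c].to_numpy(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"score column '{c}' is constant; cannot "
                             "z-transform")
        out[c] = (x - x.mean()) / sd
    return out


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_pearson(x, y, covariates) -> tuple[float, float]:
    """Pearson r of x and y after removing the covariates by OLS.

    p from the t transform with n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(x):
        cov = cov.T
    n, k = cov.shape
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("degenerate residuals (constant after adjustment)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_ * r_))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def global_regressions(table: pd.DataFrame, global_ficd_values,
                       wmh_zero_offset_ml: float = 0.001) -> pd.DataFrame:
    """Simple regressions of global FiCD on each CSVD marker.

    WMH volume is log transformed (natural log); zero volumes are offset by
    ``wmh_zero_offset_ml`` (one 1-mm voxel by default) before the log.
    """
    g = np.asarray(global_ficd_values, dtype=float)
    needed = ["lacune_volume_ml", "wmh_volume_ml", "relative_brain_volume",
              "age", "sex"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    wmh = table["wmh_volume_ml"].to_numpy(float)
    log_wmh = np.log(np.where(wmh > 0, wmh, wmh_zero_offset_ml))
    predictors = {
        "lacune_volume_ml": table["lacune_volume_ml"].to_numpy(float),
        "log_wmh_volume": log_wmh,
        "relative_brain_volume":
            table["relative_brain_volume"].to_numpy(float),
        "age": table["age"].to_numpy(float),
        "sex": table["sex"].to_numpy(float),
    }
    rows = []
    for name, x in predictors.items():
        res = sps.linregress(x, g)
        rows.append({"predictor": name, "r": res.rvalue, "p": res.pvalue,
                     "slope": res.slope, "intercept": res.intercept})
    return pd.DataFrame(rows)


def group_anova(values, groups) -> dict:
    """One-way ANOVA with Bonferroni and Tamhane-T2 post hoc comparisons.

    Bonferroni: pooled-variance pairwise t, p multiplied by the number of
    comparisons (clipped at 1).  Tamhane T2: Welch pairwise t with
    Sidak-type adjustment 1 - (1 - p)^m for unequal variances.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    samples = [values[groups == lab] for lab in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group '{lab}' has fewer than 2 subjects")
    f, p = sps.f_oneway(*samples)
    m = len(labels) * (len(labels) - 1) // 2
    pairwise = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            tb, pb = sps.ttest_ind(samples[i], samples[j], equal_var=True)
            tw, pw = sps.ttest_ind(samples[i], samples[j], equal_var=False)
            pairwise.append({
                "group_a": labels[i], "group_b": labels[j],
                "t_pooled": float(tb), "p_raw": float(pb),
                "p_bonferroni": float(min(1.0, m * pb)),
                "t_welch": float(tw),
                "p_tamhane_t2": float(1.0 - (1.0 - pw) ** m)})
    return {"F": float(f), "p": float(p), "pairwise": pairwise}
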