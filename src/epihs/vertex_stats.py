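"""Vertex-wise group GLMs with nonisotropic random-field-theory cluster
correction, a Freedman-Lane permutation oracle, and cluster effect sizes.

Analyses run on a :class:`~epihs.harmonization.FeatureMatrix` in the
ipsi/contra frame: the search region is the disjoint union of the two
hemisphere meshes (both carried by the symmetric template's left geometry).

RFT machinery
-------------
Smoothness is estimated from normalized residuals: for each mesh edge the
squared across-subject difference of the unit-norm residual field gives a
local estimate of the derivative variance ``lambda = s_e / d_e^2``; triangle
resels are ``area * lambda / (4 ln 2)`` (resel = area in units of the local
FWHM squared). Cluster-level FWE uses the expected-Euler-characteristic
cluster count for a t field,

    rho_2(t) = (4 ln 2) / (2 pi)^{3/2}
               * Gamma((nu+1)/2) / (sqrt(nu/2) Gamma(nu/2))
               * t * (1 + t^2/nu)^{-(nu-1)/2},

with the exponential approximation for cluster extent in resels
(``P(S >= k) = exp(-E[m] k / E[A])`` in two dimensions), and

    p_FWE(k) = 1 - exp(-E[m] P(S >= k)).

Both one-sided excursion sets (patients > controls and patients < controls)
are extracted at the one-sided cluster-defining threshold (p = 0.025 by
default) and the expected cluster count is doubled so that alpha = 0.05 is
controlled over the two directions jointly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from . import _mesh
from .harmonization import FeatureMatrix
from .surface_core import SurfaceModel, VertexMap

LN4 = 4.0 * np.log(2.0)

__all__ = [
    "DesignMatrix", "GLMResult", "ReselEstimate", "ClusterResult",
    "AnalysisDomain", "build_design", "fit_glm", "estimate_resels",
    "rft_cluster_correct", "permutation_cluster_test", "cluster_cohens_d",
    "uncorrected_tmap_export",
]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Subjects x predictors matrix, rows aligned to the FeatureMatrix."""

    X: np.ndarray
    columns: list[str]
    subject_ids: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(self.X, rowvar=False)
            corr = np.nan_to_num(corr)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"design matrix is rank deficient (rank {r} < "
                f"{self.X.shape[1]}); most collinear columns: "
                f"{self.columns[i]!r}, {self.columns[j]!r}")

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    def contrast(self, column: str) -> np.ndarray:
        c = np.zeros(len(self.columns))
        c[self.columns.index(column)] = 1.0
        return c


def build_design(meta, covariates: tuple[str, ...] = ("age_years",),
                 ) -> DesignMatrix:
    """Intercept + patient indicator + covariates from a metadata table."""
    cols = [np.ones(len(meta)), (meta.group == "patient").to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        cols.append(meta[cov].to_numpy(float))
        names.append(cov)
    return DesignMatrix(np.column_stack(cols), names, list(meta.id))


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    beta: np.ndarray                     # (p, 2V)
    t: np.ndarray                        # (2V,), NaN outside mask
    residuals: np.ndarray                # (n, 2V)
    df: int
    sigma: np.ndarray                    # (2V,)
    mask: np.ndarray                     # (2V,) columns entering inference
    degenerate: np.ndarray               # (2V,) zero-variance flags
    contrast: np.ndarray
    feature_name: str = ""


def fit_glm(matrix: FeatureMatrix, design: DesignMatrix,
            contrast: np.ndarray) -> GLMResult:
    """Ordinary least squares per vertex with a t contrast.

    ``t(v) = c'beta / (sigma(v) sqrt(c'(X'X)^-1 c))``; zero-residual
    (degenerate) vertices are masked from inference rather than clipped.
    """
    if design.subject_ids != matrix.subject_ids:
        raise ValueError("design rows do not match feature-matrix subjects")
    X = design.X
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > rank(X) + 1 subjects")
    c = np.asarray(contrast, float)
    Y = matrix.data
    col_ok = np.all(np.isfinite(Y), axis=0)
    Yf = np.where(col_ok, Y, 0.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Yf
    resid = Yf - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    sigma = np.sqrt(sigma2)
    cxc = float(c @ xtx_inv @ c)
    degenerate = col_ok & (sigma2 <= 1e-24)
    mask = col_ok & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / (sigma * np.sqrt(cxc))
    t[~mask] = np.nan
    beta[:, ~col_ok] = np.nan
    return GLMResult(beta, t, resid, df, sigma, mask, degenerate, c,
                     matrix.feature_name)


# ---------------------------------------------------------------------------
# search-region geometry
# ---------------------------------------------------------------------------

class AnalysisDomain:
    """Disjoint union of the two hemisphere blocks over one template mesh."""

    def __init__(self, surface: SurfaceModel):
        self.surface = surface
        V = surface.n_vertices
        self.n_vertices = 2 * V
        e = surface.edges
        self.edges = np.vstack([e, e + V])
        self.edge_lengths = np.tile(surface.edge_lengths, 2)
        f = surface.faces
        self.faces = np.vstack([f, f + V])
        self.tri_areas = np.tile(
            _mesh.triangle_areas(surface.vertices_white, surface.faces), 2)
        self.vertex_areas = np.tile(surface.vertex_areas, 2)
        self.n_components = 2
        # face -> edge-row lookup, built once (reused every resel estimate)
        eid = {tuple(edge): k for k, edge in enumerate(map(sorted,
                                                           self.edges))}
        self.face_edges = np.array(
            [[eid[tuple(sorted((a, b)))], eid[tuple(sorted((b, c)))],
              eid[tuple(sorted((c, a)))]] for a, b, c in self.faces])


# ---------------------------------------------------------------------------
# resels
# ---------------------------------------------------------------------------

@dataclass
class ReselEstimate:
    """Nonisotropic smoothness of the residual field on the search region."""

    edge_fwhm: np.ndarray                # per retained edge, mm
    vertex_resels: np.ndarray            # (2V,) resel density per vertex
    total_resels: float                  # R_2
    search_area_mm2: float
    global_fwhm_mm: float
    n_components: int

    def __post_init__(self):
        if np.any(self.edge_fwhm <= 0):
            raise ValueError("edge FWHM must be positive")


def estimate_resels(residuals: np.ndarray, domain: AnalysisDomain,
                    mask: np.ndarray) -> ReselEstimate:
    """Worsley-style smoothness from normalized residuals.

    Residuals are normalized to unit norm across subjects per vertex; the
    across-subject variance of along-edge differences, scaled by the edge
    length, yields a local FWHM per edge, integrated into triangle resels.
    """
    if residuals.shape[0] < 3:
        raise ValueError("need >= 3 residual maps")
    mask = np.asarray(mask, bool)
    if mask.sum() < 100:
        raise ValueError("mask too small for smoothness estimation "
                         f"({int(mask.sum())} < 100 vertices)")
    norm = np.sqrt((residuals ** 2).sum(axis=0))
    ok = mask & (norm > 0)
    u = np.where(ok, residuals / np.where(norm > 0, norm, 1.0), np.nan)
    e = domain.edges
    keep = ok[e[:, 0]] & ok[e[:, 1]]
    diff2 = ((u[:, e[keep, 0]] - u[:, e[keep, 1]]) ** 2).sum(axis=0)
    d2 = domain.edge_lengths[keep] ** 2
    lam_edge = np.maximum(diff2, 1e-12) / d2
    edge_fwhm = np.sqrt(LN4 / lam_edge)

    lam_full = np.full(len(e), np.nan)
    lam_full[keep] = lam_edge
    f = domain.faces
    with np.errstate(invalid="ignore"):
        lam_tri = np.nanmean(lam_full[domain.face_edges], axis=1)
    tri_ok = (ok[f[:, 0]] & ok[f[:, 1]] & ok[f[:, 2]]
              & np.isfinite(lam_tri))
    resel_tri = np.where(tri_ok, domain.tri_areas * lam_tri / LN4, 0.0)
    vertex_resels = np.zeros(domain.n_vertices)
    for k in range(3):
        np.add.at(vertex_resels, f[:, k], resel_tri / 3.0)
    total = float(resel_tri.sum())
    area = float(domain.tri_areas[tri_ok].sum())
    return ReselEstimate(edge_fwhm, vertex_resels, total, area,
                         float(np.sqrt(area / total)) if total > 0 else np.inf,
                         domain.n_components)


# ---------------------------------------------------------------------------
# RFT cluster inference
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    vertices: np.ndarray                 # indices into the 2V frame
    peak_t: float
    area_mm2: float
    extent_resels: float
    p_fwe: float
    direction: str                       # 'positive' | 'negative'
    cohen_d: float | None = None
    p_perm: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_fwe < 0.05


def _ec_density_t(t: float, nu: int) -> tuple[float, float, float]:
    """(rho_0, rho_1, rho_2) EC densities of a t field at threshold t."""
    if not np.isfinite(t):               # cdt_p = 1 -> threshold at -inf
        return (1.0, 0.0, 0.0) if t < 0 else (0.0, 0.0, 0.0)
    rho0 = float(stats.t.sf(t, nu))
    base = (1.0 + t * t / nu) ** (-(nu - 1) / 2.0)
    rho1 = np.sqrt(LN4) / (2 * np.pi) * base
    lgam = gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0)
    rho2 = (LN4 / (2 * np.pi) ** 1.5 * np.exp(lgam)
            / np.sqrt(nu / 2.0) * t * base)
    return rho0, rho1, float(rho2)


def _extract_clusters(tmap: np.ndarray, domain: AnalysisDomain,
                      mask: np.ndarray, t_c: float,
                      vertex_resels: np.ndarray,
                      ) -> list[tuple[np.ndarray, float, float, float]]:
    """(vertices, peak_t, area_mm2, extent_resels) per excursion component."""
    supra = mask & np.isfinite(tmap) & (tmap > t_c)
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return []
    e = domain.edges
    keep = supra[e[:, 0]] & supra[e[:, 1]]
    remap = -np.ones(domain.n_vertices, np.int64)
    remap[idx] = np.arange(len(idx))
    sub = remap[e[keep]]
    g = sparse.coo_matrix((np.ones(len(sub)), (sub[:, 0], sub[:, 1])),
                          shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(g, directed=False)
    out = []
    for c in range(n_comp):
        verts = idx[labels == c]
        out.append((verts, float(np.nanmax(tmap[verts])),
                    float(domain.vertex_areas[verts].sum()),
                    float(vertex_resels[verts].sum())))
    return out


def expected_clusters(t_c: float, nu: int, resels: ReselEstimate,
                      two_sided: bool = True) -> tuple[float, float]:
    """(E[m], E[A]) cluster count and supra-threshold area, in resels."""
    rho0, _rho1, rho2 = _ec_density_t(t_c, nu)
    em = resels.total_resels * rho2 + resels.n_components * rho0
    ea = resels.total_resels * rho0
    k = 2.0 if two_sided else 1.0
    return k * em, k * ea


def cluster_p_fwe(extent_resels: float, t_c: float, nu: int,
                  resels: ReselEstimate, two_sided: bool = True) -> float:
    em, ea = expected_clusters(t_c, nu, resels, two_sided)
    if em <= 0 or ea <= 0:
        return 1.0
    p_tail = np.exp(-em / ea * extent_resels)
    return float(1.0 - np.exp(-em * p_tail))


def rft_cluster_correct(glm: GLMResult, resels: ReselEstimate,
                        domain: AnalysisDomain, cdt_p: float = 0.025,
                        alpha: float = 0.05, two_sided: bool = True,
                        ) -> list[ClusterResult]:
    """Cluster-extent FWE correction of a vertex-wise t map.

    Extracts edge-connected excursion clusters above the one-sided
    cluster-defining threshold in each direction and assigns each the
    corrected p of its resel extent. An empty list is a valid outcome.
    """
    if glm.df < 3:
        raise ValueError("need error df >= 3 for RFT inference")
    t_c = float(stats.t.isf(cdt_p, glm.df))
    clusters: list[ClusterResult] = []
    directions = (("positive", glm.t), ("negative", -glm.t))
    if not two_sided:
        directions = directions[:1]
    for name, tmap in directions:
        for verts, peak, area, ext in _extract_clusters(
                tmap, domain, glm.mask, t_c, resels.vertex_resels):
            p = cluster_p_fwe(ext, t_c, glm.df, resels, two_sided)
            clusters.append(ClusterResult(verts, peak, area, ext, p, name))
    clusters.sort(key=lambda cl: cl.p_fwe)
    return clusters


# ---------------------------------------------------------------------------
# permutation oracle
# ---------------------------------------------------------------------------

def permutation_cluster_test(matrix: FeatureMatrix, design: DesignMatrix,
                             contrast: np.ndarray, domain: AnalysisDomain,
                             cdt_p: float = 0.025, n_perm: int = 500,
                             seed: int = 0, two_sided: bool = True,
                             ) -> list[ClusterResult]:
    """Freedman-Lane max-cluster-extent permutation test.

    Nuisance effects (all design columns with zero contrast weight) are
    regressed out; their residuals are permuted, refit under the full model,
    and the maximum cluster resel extent over both directions forms the
    null distribution. ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    import warnings
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p",
                      stacklevel=2)
    glm = fit_glm(matrix, design, contrast)
    resels = estimate_resels(glm.residuals, domain, _tile_mask(matrix))
    observed = rft_cluster_correct(glm, resels, domain, cdt_p,
                                   two_sided=two_sided)
    t_c = float(stats.t.isf(cdt_p, glm.df))

    X = design.X
    c = np.asarray(contrast, float)
    nuisance = np.abs(c) == 0
    Z = X[:, nuisance]
    Y = np.where(np.isfinite(matrix.data), matrix.data, 0.0)
    Rz = np.eye(len(Y)) - Z @ np.linalg.pinv(Z)
    Y0 = Rz @ Y
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    cxc = float(c @ xtx_inv @ c)
    df = len(Y) - X.shape[1]
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(Y))
        Yp = Y0[perm]
        beta = pinv @ Yp
        resid = Yp - X @ beta
        sigma2 = (resid ** 2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ beta) / np.sqrt(sigma2 * cxc)
        m = 0.0
        sides = (t, -t) if two_sided else (t,)
        for tmap in sides:
            for _v, _p, _a, ext in _extract_clusters(
                    tmap, domain, glm.mask, t_c, resels.vertex_resels):
                m = max(m, ext)
        null_max[b] = m
    for cl in observed:
        cl.p_perm = float((1 + np.sum(null_max >= cl.extent_resels))
                          / (1 + n_perm))
    return observed


def _tile_mask(matrix: FeatureMatrix) -> np.ndarray:
    return np.concatenate([matrix.mask, matrix.mask])


# ---------------------------------------------------------------------------
# effect sizes and export
# ---------------------------------------------------------------------------

def cluster_cohens_d(matrix: FeatureMatrix, patient_ids: list[str],
                     cluster_vertices: np.ndarray) -> float:
    """Cohen's d of subject-level cluster means, pooled-SD denominator."""
    if len(cluster_vertices) == 0:
        raise ValueError("empty cluster")
    pat = np.array([s in set(patient_ids) for s in matrix.subject_ids])
    if pat.all() or not pat.any():
        raise ValueError("both groups must be non-empty")
    means = np.nanmean(matrix.data[:, cluster_vertices], axis=1)
    x, y = means[pat], means[~pat]
    n1, n2 = len(x), len(y)
    sp = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                 / (n1 + n2 - 2))
    return float((x.mean() - y.mean()) / sp)


def uncorrected_tmap_export(glm: GLMResult) -> dict[str, VertexMap]:
    """Raw t maps per hemisphere block (NaN sentinel outside the mask)."""
    V2 = len(glm.t)
    V = V2 // 2
    out = {}
    for name, sl in (("ipsi", slice(0, V)), ("contra", slice(V, V2))):
        out[name] = VertexMap(glm.t[sl], f"t_{glm.feature_name}", "left",
                              mask=glm.mask[sl])
    return out
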