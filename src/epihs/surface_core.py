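"""Geometric data model and I/O for cortical surfaces, per-vertex maps and
intensity volumes, plus mesh-diffusion Gaussian smoothing.

Conventions
-----------
* All world coordinates are millimetres, RAS orientation; voxel indices are
  0-based (NIfTI's dominant dialect).
* A :class:`SurfaceModel` bundles the white (gray-white interface) and pial
  surfaces of one hemisphere with a shared vertex indexing on a symmetric
  template, so the same index refers to the same anatomical location on the
  white surface, the pial surface, and the mirror position on the other
  hemisphere.
* Masked-out vertices in a :class:`VertexMap` carry NaN, never a silent zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import sparse

from . import _mesh

LN2_8 = 8.0 * np.log(2.0)  #: fwhm**2 / LN2_8 = gaussian variance per axis

__all__ = [
    "SurfaceModel", "VertexMap", "IntensityVolume", "SmoothingKernelSpec",
    "SurfaceFormatError", "read_surface", "write_surface",
    "read_vertex_map", "write_vertex_map", "read_volume", "write_volume",
    "SmoothingOperator", "smooth_vertex_map",
]


class SurfaceFormatError(ValueError):
    """Malformed or structurally inconsistent surface/volume file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceModel:
    """Paired white/pial triangulated meshes of one hemisphere.

    ``vertices_white`` and ``vertices_pial`` share vertex count and ordering;
    ``faces`` is a single connected 2-manifold triangle list.
    """

    vertices_white: np.ndarray          # (V, 3) mm
    vertices_pial: np.ndarray           # (V, 3) mm
    faces: np.ndarray                   # (F, 3) int
    hemisphere: str                     # 'left' | 'right'
    template_id: str = "synthetic-sym"

    def __post_init__(self) -> None:
        self.vertices_white = np.asarray(self.vertices_white, float)
        self.vertices_pial = np.asarray(self.vertices_pial, float)
        self.faces = np.asarray(self.faces, np.int64)
        if self.vertices_white.shape != self.vertices_pial.shape:
            raise SurfaceFormatError(
                f"white/pial vertex counts differ: "
                f"{len(self.vertices_white)} vs {len(self.vertices_pial)}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices_white)

    # geometry caches ------------------------------------------------------
    @property
    def edges(self) -> np.ndarray:
        if not hasattr(self, "_edges"):
            self._edges = _mesh.unique_edges(self.faces)
        return self._edges

    @property
    def edge_lengths(self) -> np.ndarray:
        if not hasattr(self, "_edge_lengths"):
            e = self.edges
            self._edge_lengths = np.linalg.norm(
                self.vertices_white[e[:, 0]] - self.vertices_white[e[:, 1]],
                axis=1)
        return self._edge_lengths

    @property
    def vertex_areas(self) -> np.ndarray:
        if not hasattr(self, "_vertex_areas"):
            self._vertex_areas = _mesh.vertex_areas(self.vertices_white,
                                                    self.faces)
        return self._vertex_areas

    @property
    def white_normals(self) -> np.ndarray:
        if not hasattr(self, "_normals"):
            self._normals = _mesh.vertex_normals(self.vertices_white,
                                                 self.faces)
        return self._normals

    def validate(self) -> None:
        """Enforce the manifold/degeneracy invariants (raises on violation)."""
        if self.faces.max() >= self.n_vertices:
            raise SurfaceFormatError("face index out of range")
        areas = _mesh.triangle_areas(self.vertices_white, self.faces)
        if np.any(areas <= 0):
            raise SurfaceFormatError("degenerate zero-area triangle")
        if not _mesh.is_connected_subset(self.faces,
                                         np.arange(self.n_vertices),
                                         self.n_vertices):
            raise SurfaceFormatError("surface is not connected")


@dataclass
class VertexMap:
    """A per-vertex scalar field on the template (thickness, contrast, RI,
    z, or t). Masked vertices are NaN."""

    values: np.ndarray
    feature_name: str
    hemisphere: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float).copy()
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, bool).copy()
            if self.mask.shape != self.values.shape:
                raise ValueError("mask length must equal vertex count")
        self.values[~self.mask] = np.nan

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    def masked_mean(self) -> float:
        return float(np.nanmean(self.values[self.mask]))


@dataclass
class IntensityVolume:
    """A 3-D scalar grid with a voxel-to-world (mm, RAS) affine."""

    grid: np.ndarray
    affine: np.ndarray
    modality: str = "T1"                # 'T1' | 'FLAIR' | 'label'

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("volume affine is singular")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(xyz)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def sample(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear samples at world positions; returns (values, inside)."""
        from scipy.ndimage import map_coordinates
        ijk = self.world_to_voxel(xyz)
        shape = np.asarray(self.grid.shape)
        inside = np.all((ijk >= 0) & (ijk <= shape - 1), axis=1)
        vals = map_coordinates(self.grid.astype(float), ijk.T, order=1,
                               mode="nearest")
        vals[~inside] = np.nan
        return vals, inside


@dataclass
class SmoothingKernelSpec:
    """Diffusion schedule realising a Gaussian kernel of ``fwhm_mm``.

    The invariant ``n_iterations * per_step_variance == fwhm_mm**2 / (8 ln 2)``
    holds by construction (within 1%).
    """

    fwhm_mm: float
    n_iterations: int
    per_step_variance: float            # mm^2, per axis

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        total = self.fwhm_mm ** 2 / LN2_8
        if self.fwhm_mm > 0:
            achieved = self.n_iterations * self.per_step_variance
            if abs(achieved - total) > 0.01 * total:
                raise ValueError("n_iterations * per_step_variance must equal "
                                 "fwhm^2/(8 ln 2) within 1%")

    @classmethod
    def for_surface(cls, surface: SurfaceModel, fwhm_mm: float,
                    min_iterations: int = 20) -> "SmoothingKernelSpec":
        """Schedule with >= ``min_iterations`` explicit-diffusion steps."""
        if fwhm_mm == 0:
            return cls(0.0, 0, 0.0)
        total = fwhm_mm ** 2 / LN2_8
        # 0.95 safety margin keeps the per-step mixing weight below 1 even
        # when a mask restricts the operator to a slightly denser subgraph
        v_full = 0.95 * _full_step_variance(surface)
        n = max(min_iterations, int(np.ceil(total / v_full)))
        return cls(fwhm_mm, n, total / n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_STAMP = "created by epihs"


def _read_one_geometry(path: str) -> tuple[np.ndarray, np.ndarray]:
    path = str(path)
    try:
        if path.endswith(".gii"):
            img = nib.load(path)
            coords = img.darrays[0].data.astype(float)
            faces = img.darrays[1].data.astype(np.int64)
        else:
            coords, faces = nib.freesurfer.read_geometry(path)
    except SurfaceFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise parse failures
        raise SurfaceFormatError(f"cannot parse surface file {path}: {exc}")
    return np.asarray(coords, float), np.asarray(faces, np.int64)


def read_surface(white_path: str, pial_path: str, hemisphere: str,
                 template_id: str = "synthetic-sym") -> SurfaceModel:
    """Read a white/pial pair (FreeSurfer binary or GIFTI ``.gii``)."""
    vw, fw = _read_one_geometry(white_path)
    vp, fp = _read_one_geometry(pial_path)
    if len(vw) != len(vp):
        raise SurfaceFormatError(
            f"pial ({len(vp)}) and white ({len(vw)}) vertex counts differ")
    if not np.array_equal(fw, fp):
        raise SurfaceFormatError("pial and white triangulations differ")
    return SurfaceModel(vw, vp, fw, hemisphere, template_id)


def write_surface(surface: SurfaceModel, white_path: str,
                  pial_path: str) -> None:
    """Write both surfaces; format chosen by extension (.gii -> GIFTI)."""
    for coords, path in ((surface.vertices_white, white_path),
                         (surface.vertices_pial, pial_path)):
        path = str(path)
        if path.endswith(".gii"):
            img = nib.gifti.GiftiImage(darrays=[
                nib.gifti.GiftiDataArray(coords.astype(np.float32),
                                         intent="NIFTI_INTENT_POINTSET"),
                nib.gifti.GiftiDataArray(surface.faces.astype(np.int32),
                                         intent="NIFTI_INTENT_TRIANGLE"),
            ])
            nib.save(img, path)
        else:
            nib.freesurfer.write_geometry(path, coords, surface.faces,
                                          create_stamp=_STAMP)


def read_vertex_map(path: str, feature_name: str,
                    hemisphere: str) -> VertexMap:
    """Read a per-vertex scalar map (FreeSurfer curv/MGH or GIFTI func)."""
    path = str(path)
    if path.endswith(".gii"):
        values = nib.load(path).darrays[0].data.astype(float)
    elif path.endswith((".mgh", ".mgz")):
        values = np.asarray(nib.load(path).get_fdata()).reshape(-1)
    else:
        values = nib.freesurfer.read_morph_data(path).astype(float)
    return VertexMap(values, feature_name, hemisphere)


def write_vertex_map(vmap: VertexMap, path: str) -> None:
    path = str(path)
    if path.endswith(".gii"):
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(vmap.values.astype(np.float32),
                                     intent="NIFTI_INTENT_NONE")])
        nib.save(img, path)
    elif path.endswith((".mgh", ".mgz")):
        data = vmap.values.astype(np.float32).reshape(-1, 1, 1)
        nib.save(nib.MGHImage(data, np.eye(4)), path)
    else:
        nib.freesurfer.write_morph_data(path, vmap.values)


def read_volume(path: str) -> IntensityVolume:
    img = nib.load(str(path))
    modality = "label" if img.get_data_dtype().kind in "iu" else "T1"
    return IntensityVolume(np.asarray(img.dataobj), img.affine, modality)


def write_volume(vol: IntensityVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.grid, vol.affine), str(path))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _full_step_variance(surface: SurfaceModel) -> float:
    """Per-axis variance (mm^2) added by one diffusion step at alpha = 1."""
    e, ln = surface.edges, surface.edge_lengths
    w = 1.0 / ln
    row_w = np.zeros(surface.n_vertices)
    row_wl2 = np.zeros(surface.n_vertices)  # sum_j w_ij d_ij^2 = sum_j d_ij
    for k in (0, 1):
        np.add.at(row_w, e[:, k], w)
        np.add.at(row_wl2, e[:, k], ln)
    d_max = row_w.max()
    # one full step moves mass (1/d_max) * w_ij to each neighbour;
    # per-axis second moment is half the 2-D squared displacement
    return float(np.mean(row_wl2) / d_max / 2.0)


class SmoothingOperator:
    """Iterated symmetric doubly-stochastic diffusion on the white mesh graph.

    ``S = I - (alpha / d_max) (D - W)`` with inverse-edge-length weights W.
    Double stochasticity makes every step preserve the mean over in-mask
    vertices exactly; masked vertices neither receive nor donate mass
    (the operator is built on the masked subgraph).
    """

    def __init__(self, surface: SurfaceModel, spec: SmoothingKernelSpec,
                 mask: np.ndarray | None = None):
        self.surface = surface
        self.spec = spec
        V = surface.n_vertices
        self.mask = np.ones(V, bool) if mask is None else np.asarray(mask, bool)
        self.idx = np.flatnonzero(self.mask)
        e, ln = surface.edges, surface.edge_lengths
        keep = self.mask[e[:, 0]] & self.mask[e[:, 1]]
        e, ln = e[keep], ln[keep]
        remap = -np.ones(V, np.int64)
        remap[self.idx] = np.arange(len(self.idx))
        e = remap[e]
        n = len(self.idx)
        w = 1.0 / ln
        W = _mesh.edge_adjacency(n, e, w)
        deg = np.asarray(W.sum(axis=1)).ravel()
        d_max = deg.max() if n else 1.0
        if spec.n_iterations == 0:
            self.S = sparse.identity(n, format="csr")
            self.n_iter = 0
            return
        v_full = float((ln.sum() * 2 / max(n, 1)) / d_max / 2.0)
        # a masked subgraph may support less variance per stable step than
        # the full mesh; add iterations, keeping the cumulative variance
        total = spec.n_iterations * spec.per_step_variance
        n_iter = max(spec.n_iterations, int(np.ceil(total / v_full)))
        alpha = total / (n_iter * v_full)
        c = min(alpha, 1.0) / d_max
        L = sparse.diags(deg) - W
        self.S = (sparse.identity(n) - c * L).tocsr()
        self.n_iter = n_iter

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Smooth columns of (V,) or (V, k) data; NaNs outside mask kept."""
        out = np.array(values, float, copy=True)
        x = out[self.idx]
        for _ in range(self.n_iter):
            x = self.S @ x
        out[self.idx] = x
        return out

    def noise_std(self) -> np.ndarray:
        """Exact per-(in-mask-)vertex std of the smoothed unit white noise.

        S is symmetric, so row norms of S^n are obtained by pushing identity
        columns through the iteration (chunked to bound memory).
        """
        if not hasattr(self, "_noise_std"):
            n = len(self.idx)
            out = np.empty(n)
            chunk = 1024
            for s in range(0, n, chunk):
                X = np.zeros((n, min(chunk, n - s)))
                X[np.arange(s, s + X.shape[1]), np.arange(X.shape[1])] = 1.0
                for _ in range(self.n_iter):
                    X = self.S @ X
                out[s:s + X.shape[1]] = np.linalg.norm(X, axis=0)
            self._noise_std = out
        return self._noise_std

    def correlated_noise(self, rng: np.random.Generator,
                         n_maps: int) -> np.ndarray:
        """(V, n_maps) smooth fields with exactly unit variance per vertex."""
        V = self.surface.n_vertices
        out = np.full((V, n_maps), np.nan)
        x = rng.standard_normal((len(self.idx), n_maps))
        for _ in range(self.n_iter):
            x = self.S @ x
        out[self.idx] = x / self.noise_std()[:, None]
        return out


def smooth_vertex_map(vmap: VertexMap, surface: SurfaceModel,
                      spec: SmoothingKernelSpec) -> VertexMap:
    """Gaussian-diffusion smoothing of a vertex map within its mask."""
    if vmap.n_vertices != surface.n_vertices:
        raise ValueError("map is not defined on this surface's template")
    if spec.fwhm_mm == 0:
        return replace(vmap, values=vmap.values.copy())
    mean_edge = float(surface.edge_lengths.mean())
    if spec.fwhm_mm < 0.5 * mean_edge:
        warnings.warn("smoothing FWHM below half the mean edge length; "
                      "returning the map unchanged", stacklevel=2)
        return replace(vmap, values=vmap.values.copy())
    op = SmoothingOperator(surface, spec, vmap.mask)
    return replace(vmap, values=op.apply(vmap.values))
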