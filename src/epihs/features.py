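"""Per-vertex cortical features: thickness, gray-white intensity contrast,
and normalized intracortical FLAIR.

Definitions
-----------
thickness    T(v) = mean of the two directed minimum point-to-mesh distances
             between corresponding pial and white vertices (mm).
contrast     C(v) = |GM(v)| / |WM(v)|, GM sampled on T1 at 30% of the
             cortical thickness above the gray-white boundary, WM sampled
             1 mm below the boundary along the inward white normal.
             Blurring of the boundary drives C toward 1 from below.
FLAIR RI     RI(v) = (I(v) - GMpeak) / (GMpeak - B), I sampled at 50%
             cortical depth; GMpeak is the histogram mode of the mid-depth
             samples pooled across the brain, B the mode at the boundary.
             RI is invariant to any positive affine rescaling of the raw
             FLAIR volume, which is the point of the normalization.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _mesh
from .surface_core import (IntensityVolume, SmoothingKernelSpec, SurfaceModel,
                           VertexMap, read_surface, read_volume,
                           smooth_vertex_map, write_vertex_map)

__all__ = [
    "DepthSampleSpec", "FlairNormalizationContext", "compute_thickness",
    "sample_intensity_at_depth", "compute_gwc", "estimate_mode",
    "normalize_flair", "build_flair_context", "extract_subject_features",
]


@dataclass(frozen=True)
class DepthSampleSpec:
    """Where to sample an intensity relative to the cortical ribbon.

    ``depth_fraction`` measures up from the gray-white boundary (0) toward
    the pial surface (1); ``offset_mm`` moves below the boundary along the
    inward white normal.
    """

    depth_fraction: float = 0.5
    offset_mm: float = 0.0
    interpolation: str = "trilinear"

    def __post_init__(self):
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must lie in [0, 1]")
        if self.offset_mm < 0:
            raise ValueError("offset_mm must be >= 0")


@dataclass
class FlairNormalizationContext:
    """Per-subject FLAIR normalization anchors.

    GMpeak: mode of the mid-depth (50%) FLAIR histogram across the brain.
    B: mode of the gray-white boundary histogram.
    """

    gm_peak: float
    boundary: float
    histogram_bins: int = 100
    robust_range: tuple[float, float] = (2.0, 98.0)

    def __post_init__(self):
        if self.gm_peak == self.boundary:
            raise ValueError("GMpeak equals B; FLAIR normalization undefined")


def compute_thickness(surface: SurfaceModel) -> VertexMap:
    """Symmetric mean-minimum-distance cortical thickness (mm)."""
    d_p2w = _mesh.point_mesh_distance(surface.vertices_pial,
                                      surface.vertices_white, surface.faces)
    d_w2p = _mesh.point_mesh_distance(surface.vertices_white,
                                      surface.vertices_pial, surface.faces)
    t = 0.5 * (d_p2w + d_w2p)
    if np.any(t <= 1e-9):
        warnings.warn("zero-thickness vertices present (pial touches white)",
                      stacklevel=2)
    return VertexMap(t, "thickness", surface.hemisphere)


def sample_intensity_at_depth(volume: IntensityVolume, surface: SurfaceModel,
                              spec: DepthSampleSpec) -> VertexMap:
    """Trilinear intensity at white + f*(pial-white) - offset*n_white.

    Out-of-grid sample positions are masked (NaN), not clipped.
    """
    pos = (surface.vertices_white
           + spec.depth_fraction * (surface.vertices_pial
                                    - surface.vertices_white)
           - spec.offset_mm * surface.white_normals)
    vals, inside = volume.sample(pos)
    if not inside.any():
        raise ValueError("surface lies entirely outside the volume grid; "
                         "space mismatch?")
    return VertexMap(vals, f"{volume.modality}@{spec.depth_fraction:g}"
                     f"-{spec.offset_mm:g}mm", surface.hemisphere,
                     mask=inside)


def compute_gwc(gm: VertexMap, wm: VertexMap) -> VertexMap:
    """Gray/white intensity ratio C(v) = |GM|/|WM|; WM == 0 is masked."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(gm.values) / np.abs(wm.values)
    c[np.abs(wm.values) == 0] = np.nan
    return VertexMap(c, "gwc", gm.hemisphere)


def compute_gwc_percent(gm: VertexMap, wm: VertexMap) -> VertexMap:
    """Percent-contrast variant 100*(WM-GM)/(0.5*(WM+GM)) (config option)."""
    num = wm.values - gm.values
    den = 0.5 * (wm.values + gm.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 100.0 * num / den
    c[den == 0] = np.nan
    return VertexMap(c, "gwc_percent", gm.hemisphere)


def estimate_mode(samples: np.ndarray, bins: int = 100,
                  robust_range: tuple[float, float] = (2.0, 98.0)) -> float:
    """Histogram mode with parabolic refinement through the peak bin.

    The histogram spans the robust percentile range to keep outliers from
    stretching the bins.
    """
    x = np.asarray(samples, float)
    x = x[np.isfinite(x)]
    if len(x) < 100:
        raise ValueError("need >= 100 samples to estimate a mode")
    lo, hi = np.percentile(x, robust_range)
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if k == 0 or k == bins - 1:
        return float(centers[k])
    y0, y1, y2 = counts[k - 1], counts[k], counts[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[k])
    delta = 0.5 * (y0 - y2) / denom
    return float(centers[k] + np.clip(delta, -0.5, 0.5) * (edges[1] - edges[0]))


def build_flair_context(flair_mid: list[VertexMap],
                        flair_boundary: list[VertexMap],
                        bins: int = 100,
                        robust_range: tuple[float, float] = (2.0, 98.0),
                        ) -> FlairNormalizationContext:
    """Fit GMpeak and B from the subject's own maps, pooling hemispheres."""
    mid = np.concatenate([m.values[m.mask] for m in flair_mid])
    bnd = np.concatenate([m.values[m.mask] for m in flair_boundary])
    ctx = FlairNormalizationContext(
        gm_peak=estimate_mode(mid, bins, robust_range),
        boundary=estimate_mode(bnd, bins, robust_range),
        histogram_bins=bins, robust_range=robust_range)
    return ctx


def normalize_flair(flair_mid: VertexMap,
                    ctx: FlairNormalizationContext) -> VertexMap:
    """RI(v) = (I(v) - GMpeak) / (GMpeak - B)."""
    ri = (flair_mid.values - ctx.gm_peak) / (ctx.gm_peak - ctx.boundary)
    return VertexMap(ri, "flair_ri", flair_mid.hemisphere,
                     mask=flair_mid.mask)


GM_DEPTH = DepthSampleSpec(depth_fraction=0.30)
WM_DEPTH = DepthSampleSpec(depth_fraction=0.0, offset_mm=1.0)
FLAIR_MID = DepthSampleSpec(depth_fraction=0.50)
BOUNDARY = DepthSampleSpec(depth_fraction=0.0)


def extract_subject_features(subject_dir: str | Path,
                             smoothing_fwhm_mm: float = 10.0,
                             gwc_variant: str = "ratio",
                             histogram_bins: int = 100,
                             write: bool = True,
                             ) -> dict[str, dict[str, VertexMap]]:
    """Run the full per-subject feature chain on a subject directory.

    Expects ``{left,right}.{white,pial}.surf.gii``, ``T1.nii.gz`` and
    ``FLAIR.nii.gz`` (the synthetic generator's layout). Returns
    ``{feature: {hemisphere: smoothed VertexMap}}`` and, when ``write``,
    stores maps plus a provenance log next to the inputs.
    """
    subject_dir = Path(subject_dir)
    t1 = read_volume(subject_dir / "T1.nii.gz")
    t1.modality = "T1"
    flair = read_volume(subject_dir / "FLAIR.nii.gz")
    flair.modality = "FLAIR"
    surfaces = {side: read_surface(subject_dir / f"{side}.white.surf.gii",
                                   subject_dir / f"{side}.pial.surf.gii",
                                   side)
                for side in ("left", "right")}
    mid, bnd = {}, {}
    out: dict[str, dict[str, VertexMap]] = {f: {} for f in
                                            ("thickness", "gwc", "flair_ri")}
    for side, surf in surfaces.items():
        out["thickness"][side] = compute_thickness(surf)
        gm = sample_intensity_at_depth(t1, surf, GM_DEPTH)
        wm = sample_intensity_at_depth(t1, surf, WM_DEPTH)
        gwc_fn = compute_gwc if gwc_variant == "ratio" else compute_gwc_percent
        out["gwc"][side] = gwc_fn(gm, wm)
        mid[side] = sample_intensity_at_depth(flair, surf, FLAIR_MID)
        bnd[side] = sample_intensity_at_depth(flair, surf, BOUNDARY)
    ctx = build_flair_context(list(mid.values()), list(bnd.values()),
                              bins=histogram_bins)
    for side in surfaces:
        out["flair_ri"][side] = normalize_flair(mid[side], ctx)
    for feat in out:
        for side, surf in surfaces.items():
            spec = SmoothingKernelSpec.for_surface(surf, smoothing_fwhm_mm)
            out[feat][side] = smooth_vertex_map(out[feat][side], surf, spec)
    if write:
        for feat in out:
            for side in surfaces:
                write_vertex_map(out[feat][side],
                                 subject_dir / f"feat_{feat}.{side}.mgh")
        prov = {"gm_peak": ctx.gm_peak, "boundary": ctx.boundary,
                "histogram_bins": ctx.histogram_bins,
                "smoothing_fwhm_mm": smoothing_fwhm_mm,
                "gwc_variant": gwc_variant,
                "n_masked": {side: int((~out["flair_ri"][side].mask).sum())
                             for side in surfaces}}
        (subject_dir / "features_provenance.json").write_text(
            json.dumps(prov, indent=1, sort_keys=True))
    return out
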