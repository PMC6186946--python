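"""Self-contained synthetic cohort generator.

Emulates the inputs of a pediatric temporal-lobe-epilepsy surface study:
mirrored spherical-shell "hemispheres" on a symmetric template, T1/FLAIR
volumes with a linear intracortical intensity profile, ellipsoidal
hippocampal label masks, and a demographics table whose marginals follow the
published group table (22 patients, 30 controls, patient age 10.53 +/- 3.32,
13:9 left:right lateralisation, 9/22 febrile convulsions, ...).

Planted pathology, all on the ipsilesional side in template coordinates:

* a temporal-pole patch of FLAIR hyperintensity (Cohen's d = 1.48),
  gray-white contrast blurring (d = 2.06) and cortical thinning (d = 0.95)
  -- the published cluster effect sizes are the generator defaults;
* ipsilateral hippocampal atrophy (2780 +/- 341 mm^3 vs ~3300 mm^3 in
  controls) with bilateral hippocampal FLAIR hyperintensity;
* age slopes on the cortical features;
* an additive febrile-convulsion modulation of patch FLAIR.

Two fidelities: ``fast`` emits per-vertex feature maps directly (for
statistical validation), ``full`` voxelises T1/FLAIR volumes and label masks
so the feature-extraction samplers have something physical to sample.
A :class:`GroundTruth` records what was planted; the analysis pipeline never
reads it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import _mesh
from .surface_core import (IntensityVolume, SmoothingKernelSpec,
                           SmoothingOperator, SurfaceModel, VertexMap,
                           write_surface, write_vertex_map, write_volume)

FEATURES = ("thickness", "gwc", "flair_ri")

#: baseline level, between-subject SD, and age slope (per year, centred at
#: 12 y) for each feature in its native units. Thickness baseline comes from
#: the planted template field; the SDs are typical single-site values.
FEATURE_SCALES = {
    "thickness": {"baseline": None, "sd": 0.25, "age_slope": -0.02},
    "gwc": {"baseline": 0.80, "sd": 0.05, "age_slope": -0.002},
    "flair_ri": {"baseline": 0.00, "sd": 0.30, "age_slope": -0.005},
}

# nominal synthetic tissue intensities (arbitrary scanner units)
T1_WM, T1_GM_BOUNDARY, T1_GM_PIAL, T1_CSF = 125.0, 106.0, 86.0, 40.0
FLAIR_WM, FLAIR_GM, FLAIR_CSF = 80.0, 120.0, 30.0
FLAIR_SCALE = FLAIR_GM - FLAIR_WM        # (GMpeak - B) of the noise-free world


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """Mirrored left/right spherical-shell template with index-identity
    cross-hemisphere correspondence."""

    left: SurfaceModel
    right: SurfaceModel
    level: int
    radius_white: float
    center_offset: float                 # |x| of each hemisphere centre
    base_thickness: np.ndarray           # (V,) planted thickness field, mm

    @property
    def n_vertices(self) -> int:
        return self.left.n_vertices

    def hemi(self, side: str) -> SurfaceModel:
        return self.left if side == "left" else self.right

    def center(self, side: str) -> np.ndarray:
        return np.array([-self.center_offset if side == "left"
                         else self.center_offset, 0.0, 0.0])

    @property
    def unit_dirs(self) -> np.ndarray:
        """Unit directions of the left hemisphere vertices."""
        return _mesh.icosphere(self.level)[0]


def _thickness_field(unit_dirs: np.ndarray) -> np.ndarray:
    """Smooth mirror-symmetric field in [3, 5] mm (independent of x sign).

    Pediatric temporal cortex runs thick (3-4.5 mm); staying >= 3 mm also
    leaves room for a trilinear sampling footprint at 1 mm voxels between
    the gray-white transition and the mid-depth plateau.
    """
    y, z = unit_dirs[:, 1], unit_dirs[:, 2]
    t = 4.0 + 0.6 * z + 0.35 * np.cos(2.0 * y)
    return np.clip(t, 3.0, 5.0)


@lru_cache(maxsize=4)
def build_template(subdivision_level: int = 4, radius_white: float = 49.0,
                   center_offset: float | None = None) -> Template:
    """Mirrored icosphere-shell pair; level 4 gives 2562 vertices/hemisphere.

    White surface: sphere of ``radius_white``. Pial: white inflated outward
    along the radial normal by a smoothly varying 3-5 mm thickness field, so
    the pial-white distance equals the planted field exactly.
    """
    if subdivision_level < 2:
        raise ValueError("subdivision level must be >= 2")
    u, faces = _mesh.icosphere(subdivision_level)
    thick = _thickness_field(u)
    if center_offset is None:
        center_offset = radius_white + 10.0
    cl = np.array([-center_offset, 0.0, 0.0])
    white_l = cl + radius_white * u
    pial_l = cl + (radius_white + thick)[:, None] * u
    left = SurfaceModel(white_l, pial_l, faces, "left")
    mirror = np.array([-1.0, 1.0, 1.0])
    # mirroring flips orientation; swap two face indices to stay outward
    faces_r = faces[:, [0, 2, 1]]
    right = SurfaceModel(white_l * mirror, pial_l * mirror, faces_r, "right")
    return Template(left, right, subdivision_level, radius_white,
                    center_offset, thick)


def mirror_template(template: Template) -> Template:
    """Swap hemispheres (an involution; vertex indices are unchanged)."""
    return Template(template.right, template.left, template.level,
                    template.radius_white, template.center_offset,
                    template.base_thickness)


def temporal_pole_seed(template: Template) -> int:
    """Canonical anterior-inferior seed vertex for the planted patch."""
    d = np.array([0.55, -0.6, -0.58])
    d /= np.linalg.norm(d)
    return int(np.argmax(template.unit_dirs @ d))


# ---------------------------------------------------------------------------
# effect and cohort specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """A planted between-group effect on a connected template patch."""

    feature: str
    cohen_d: float                       # magnitude, between-subject SD units
    direction: int = 1                   # +1 increase in patients, -1 decrease
    # 25 mm geodesic radius ~ 2000 mm^2, ~6.5% of the shell hemisphere --
    # the scale of an extensive mesial-plus-lateral anterior temporal patch
    radius_mm: float = 25.0
    seed_vertex: int | None = None       # default: temporal-pole seed
    fc_shift_sd: float = 0.0             # extra shift if febrile convulsions
    blurring_shift_sd: float = 0.0       # extra shift if radiological blurring
    edge_fwhm_mm: float = 6.0            # taper of the patch profile

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.cohen_d < 0:
            raise ValueError("cohen_d is a magnitude; use direction for sign")

    def region(self, template: Template) -> np.ndarray:
        seed = (temporal_pole_seed(template) if self.seed_vertex is None
                else self.seed_vertex)
        surf = template.left
        reg = _mesh.geodesic_disc(surf.vertices_white, surf.faces, seed,
                                  self.radius_mm)
        if len(reg) == 0 or not _mesh.is_connected_subset(
                surf.faces, reg, surf.n_vertices):
            raise ValueError("effect region empty or disconnected")
        return reg

    def profile(self, template: Template) -> np.ndarray:
        """Tapered indicator of the region, max 1 on the plateau."""
        surf = template.left
        ind = np.zeros(surf.n_vertices)
        ind[self.region(template)] = 1.0
        if self.edge_fwhm_mm > 0:
            spec = SmoothingKernelSpec.for_surface(surf, self.edge_fwhm_mm)
            ind = SmoothingOperator(surf, spec).apply(ind)
            m = ind.max()
            if m > 0:
                ind /= m
        return ind


def default_effects() -> list[EffectSpec]:
    """The published temporal-pole cluster effect sizes, plus the clinical
    modulations the study reports (FC on FLAIR; radiological blurring on
    contrast and FLAIR)."""
    return [
        EffectSpec("flair_ri", 1.48, +1, fc_shift_sd=0.4,
                   blurring_shift_sd=1.2),
        EffectSpec("gwc", 2.06, +1, blurring_shift_sd=0.6),
        EffectSpec("thickness", 0.95, -1),
    ]


@dataclass
class CohortSpec:
    """Statistical description of the simulated cohort.

    Defaults follow the published group table (sample sizes, age, sex,
    lateralisation, febrile convulsions) and hippocampal volumetry; the
    spatial noise correlation FWHM is a generator choice (no within-cohort
    spatial covariance is published).
    """

    n_patients: int = 22
    n_controls: int = 30
    left_lesion_frac: float = 13 / 22
    patient_age: tuple[float, float] = (10.53, 3.32)
    control_age: tuple[float, float] = (14.33, 3.01)
    patient_age_range: tuple[float, float] = (4.5, 15.1)
    control_age_range: tuple[float, float] = (10.0, 19.75)
    onset: tuple[float, float] = (3.02, 3.20)
    female_frac_patients: float = 13 / 22
    female_frac_controls: float = 13 / 30
    fc_frac: float = 9 / 22
    blurring_frac: float = 10 / 22
    surgery_frac: float = 9 / 22
    # hippocampus (mm^3 means/SDs from the published volumetry)
    hippo_patient_ipsi: tuple[float, float] = (2780.0, 341.0)
    hippo_patient_contra: tuple[float, float] = (3210.0, 388.0)
    hippo_control_left: tuple[float, float] = (3310.0, 278.0)
    hippo_control_right: tuple[float, float] = (3280.0, 312.0)
    hippo_ri_shift_ipsi: float = 0.25    # RI units; bilateral hyperintensity
    hippo_ri_shift_contra: float = 0.15
    hippo_ri_sd: float = 0.20
    hippo_icv_coupling: float = 150.0    # mm^3 per ICV SD
    icv: tuple[float, float] = (1.40e6, 1.2e5)
    # noise model
    noise_fwhm_mm: float = 15.0          # spatial correlation of subject noise
    voxel_noise_sd: float = 2.0          # full fidelity, intensity units
    # geometry
    template_level: int = 4
    template_radius: float = 49.0
    voxel_size_mm: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("patient_age", "control_age", "onset", "icv",
                     "hippo_patient_ipsi", "hippo_patient_contra",
                     "hippo_control_left", "hippo_control_right"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        for name in ("left_lesion_frac", "female_frac_patients",
                     "female_frac_controls", "fc_frac", "blurring_frac",
                     "surgery_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_patients < 1 or self.n_controls < 2:
            raise ValueError("need >= 1 patient and >= 2 controls")
        if self.hippo_ri_sd < 0 or self.noise_fwhm_mm < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted. Never consumed by the pipeline."""

    regions: dict[str, np.ndarray]       # feature -> template vertex indices
    profiles: dict[str, np.ndarray]      # feature -> (V,) tapered profile
    effects: list[EffectSpec]
    age_slopes: dict[str, float]
    base_thickness: np.ndarray
    hippo_means: dict[str, tuple[float, float]]
    subject_effect_sd: dict[str, float]


@dataclass
class Cohort:
    """In-memory synthetic cohort (fast fidelity unless volumes were built)."""

    spec: CohortSpec
    meta: pd.DataFrame
    template: Template
    features: dict[str, np.ndarray]      # feature -> (n_subjects, 2V), [L|R]
    hippo: pd.DataFrame
    ground_truth: GroundTruth
    out_dir: Path | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def control_ids(self) -> list[str]:
        return list(self.meta.loc[self.meta.group == "control", "id"])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _fixed_count_labels(rng, n: int, frac: float, yes, no) -> np.ndarray:
    """Shuffled label vector with exactly round(frac*n) positives."""
    k = int(round(frac * n))
    lab = np.array([yes] * k + [no] * (n - k), dtype=object)
    return lab[rng.permutation(n)]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(x, lo, hi)


def sample_metadata(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table with the published marginals (fixed counts, shuffled)."""
    n_p, n_c = spec.n_patients, spec.n_controls
    rows = []
    age_p = _truncated_normal(rng, *spec.patient_age, *spec.patient_age_range,
                              size=n_p)
    age_c = _truncated_normal(rng, *spec.control_age, *spec.control_age_range,
                              size=n_c)
    side = _fixed_count_labels(rng, n_p, spec.left_lesion_frac, "left", "right")
    sex_p = _fixed_count_labels(rng, n_p, spec.female_frac_patients, "F", "M")
    sex_c = _fixed_count_labels(rng, n_c, spec.female_frac_controls, "F", "M")
    fc = _fixed_count_labels(rng, n_p, spec.fc_frac, True, False)
    blur = _fixed_count_labels(rng, n_p, spec.blurring_frac, True, False)
    surg = _fixed_count_labels(rng, n_p, spec.surgery_frac, True, False)
    onset = np.minimum(
        _truncated_normal(rng, *spec.onset, 0.2, 14.0, size=n_p),
        age_p - 0.5)
    icv = rng.normal(*spec.icv, size=n_p + n_c)
    for i in range(n_p):
        rows.append(dict(id=f"sub-{i + 1:03d}", group="patient",
                         age_years=round(age_p[i], 2), sex=sex_p[i],
                         lesion_side=side[i],
                         onset_years=round(float(onset[i]), 2),
                         duration_years=round(float(age_p[i] - onset[i]), 2),
                         febrile_convulsions=bool(fc[i]),
                         radiological_blurring=bool(blur[i]),
                         surgery=bool(surg[i]), icv_mm3=round(icv[i], 1)))
    for j in range(n_c):
        rows.append(dict(id=f"sub-{n_p + j + 1:03d}", group="control",
                         age_years=round(age_c[j], 2), sex=sex_c[j],
                         lesion_side="none", onset_years=np.nan,
                         duration_years=np.nan, febrile_convulsions=False,
                         radiological_blurring=False, surgery=False,
                         icv_mm3=round(icv[n_p + j], 1)))
    return pd.DataFrame(rows)


@lru_cache(maxsize=4)
def _noise_operator(level: int, radius: float, fwhm: float) -> SmoothingOperator:
    template = build_template(level, radius)
    spec = SmoothingKernelSpec.for_surface(template.left, fwhm)
    op = SmoothingOperator(template.left, spec)
    op.noise_std()  # warm the normalisation cache
    return op


def _feature_maps(spec: CohortSpec, effects, meta, template,
                  rng) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Fast-path per-vertex maps (n_subjects, 2V) per feature."""
    V = template.n_vertices
    n = len(meta)
    op = _noise_operator(spec.template_level, spec.template_radius,
                         spec.noise_fwhm_mm)
    is_patient = (meta.group == "patient").to_numpy()
    left_lesion = (meta.lesion_side == "left").to_numpy()
    age_c = meta.age_years.to_numpy() - 12.0
    fc = meta.febrile_convulsions.to_numpy(bool)
    blur = meta.radiological_blurring.to_numpy(bool)

    regions, profiles = {}, {}
    maps: dict[str, np.ndarray] = {}
    for feat in FEATURES:
        sc = FEATURE_SCALES[feat]
        base = (template.base_thickness if sc["baseline"] is None
                else np.full(V, sc["baseline"]))
        noise_l = op.correlated_noise(rng, n)        # (V, n)
        noise_r = op.correlated_noise(rng, n)
        Y = np.empty((n, 2 * V))
        Y[:, :V] = base + sc["age_slope"] * age_c[:, None] \
            + sc["sd"] * noise_l.T
        Y[:, V:] = base + sc["age_slope"] * age_c[:, None] \
            + sc["sd"] * noise_r.T
        for eff in effects:
            if eff.feature != feat:
                continue
            prof = eff.profile(template)
            # ground-truth "cluster region": where the expected planted
            # group difference is at least half a between-subject SD
            d_tot = (eff.cohen_d + eff.fc_shift_sd * spec.fc_frac
                     + eff.blurring_shift_sd * spec.blurring_frac)
            thr = min(0.5 / max(d_tot, 1e-9), 0.95)
            regions[feat] = np.flatnonzero(prof >= thr)
            profiles[feat] = prof
            amp = eff.direction * sc["sd"] * (
                eff.cohen_d
                + eff.fc_shift_sd * fc
                + eff.blurring_shift_sd * blur)
            amp = amp * is_patient
            lesion_block = np.where(left_lesion, 0, 1)
            for s in np.flatnonzero(amp != 0):
                off = lesion_block[s] * V
                Y[s, off:off + V] += amp[s] * prof
        maps[feat] = Y

    gt = GroundTruth(
        regions=regions, profiles=profiles, effects=list(effects),
        age_slopes={f: FEATURE_SCALES[f]["age_slope"] for f in FEATURES},
        base_thickness=template.base_thickness,
        hippo_means={"patient_ipsi": spec.hippo_patient_ipsi,
                     "patient_contra": spec.hippo_patient_contra,
                     "control_left": spec.hippo_control_left,
                     "control_right": spec.hippo_control_right},
        subject_effect_sd={f: FEATURE_SCALES[f]["sd"] for f in FEATURES})
    return maps, gt


def _hippo_table(spec: CohortSpec, meta, rng) -> pd.DataFrame:
    """Per-subject hippocampal volume and mean RI per side (fast path)."""
    b = spec.hippo_icv_coupling
    rows = []
    for _, r in meta.iterrows():
        icv_z = (r.icv_mm3 - spec.icv[0]) / spec.icv[1]
        def vol(mean, sd):
            resid = max(sd ** 2 - b ** 2, 100.0) ** 0.5
            return float(mean + b * icv_z + rng.normal(0, resid))
        if r.group == "patient":
            ipsi, contra = ((("left", "right") if r.lesion_side == "left"
                             else ("right", "left")))
            v = {ipsi: vol(*spec.hippo_patient_ipsi),
                 contra: vol(*spec.hippo_patient_contra)}
            ri = {ipsi: spec.hippo_ri_shift_ipsi
                  + rng.normal(0, spec.hippo_ri_sd),
                  contra: spec.hippo_ri_shift_contra
                  + rng.normal(0, spec.hippo_ri_sd)}
        else:
            v = {"left": vol(*spec.hippo_control_left),
                 "right": vol(*spec.hippo_control_right)}
            ri = {"left": rng.normal(0, spec.hippo_ri_sd),
                  "right": rng.normal(0, spec.hippo_ri_sd)}
        for side in ("left", "right"):
            rows.append(dict(id=r.id, side=side,
                             volume_mm3=round(v[side], 1),
                             mean_ri=round(float(ri[side]), 4),
                             icv_mm3=r.icv_mm3))
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, effects: list[EffectSpec] | None = None,
                    out_dir: str | Path | None = None,
                    fidelity: str = "fast") -> Cohort:
    """Generate a seeded cohort; ``spec.seed`` fully determines the output.

    fast: per-vertex feature maps with the planted statistics (cheap).
    full: additionally voxelises T1/FLAIR volumes, hippocampal masks and
    subject surfaces per subject under ``out_dir``.
    """
    spec.validate()
    if effects is None:
        effects = default_effects()
    for eff in effects:
        if eff.feature not in FEATURES:
            raise ValueError(f"effect on unknown feature {eff.feature}")
    template = build_template(spec.template_level, spec.template_radius)
    rng = np.random.default_rng([spec.seed, 2018])
    meta = sample_metadata(spec, rng)
    maps, gt = _feature_maps(spec, effects, meta, template, rng)
    hippo = _hippo_table(spec, meta, rng)
    cohort = Cohort(spec, meta, template, maps, hippo, gt,
                    Path(out_dir) if out_dir else None)
    if fidelity == "full":
        if out_dir is None:
            raise ValueError("full fidelity requires out_dir")
        _write_full(cohort, effects, rng)
    if out_dir is not None:
        _write_fast(cohort)
    return cohort


# ---------------------------------------------------------------------------
# volume synthesis (full fidelity)
# ---------------------------------------------------------------------------

def _world_grid(template: Template, voxel: float, margin: float = 4.0):
    r = template.radius_white + template.base_thickness.max() + margin
    c = template.center_offset
    lo = np.array([-(c + r), -r, -r])
    hi = np.array([c + r, r, r])
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = lo
    return shape, affine


def synthesize_subject_volumes(
        template: Template,
        thickness: dict[str, np.ndarray],
        gwc_mix: dict[str, np.ndarray] | None = None,
        flair_amp_ri: dict[str, np.ndarray] | None = None,
        noise_sd: float = 0.0,
        rng: np.random.Generator | None = None,
        voxel_size_mm: float = 1.0,
) -> tuple[IntensityVolume, IntensityVolume]:
    """Voxelise T1 and FLAIR for one subject.

    Voxels inside the white sphere get WM intensity, the cortical ribbon a
    linear depth profile, everything else CSF. ``gwc_mix`` (0..1 per vertex)
    mixes WM into supra-boundary gray matter (boundary blurring);
    ``flair_amp_ri`` raises mid-depth FLAIR by the given amount in RI units.
    """
    shape, affine = _world_grid(template, voxel_size_mm)
    ii = np.indices(shape).reshape(3, -1).T
    xyz = ii * voxel_size_mm + affine[:3, 3]
    t1 = np.full(len(xyz), T1_CSF)
    flair = np.full(len(xyz), FLAIR_CSF)
    u_left = template.unit_dirs
    tree = cKDTree(u_left)
    mirror = np.array([-1.0, 1.0, 1.0])
    for side in ("left", "right"):
        rel = xyz - template.center(side)
        r = np.linalg.norm(rel, axis=1)
        t_max = thickness[side].max()
        near = r <= template.radius_white + t_max + 1.0
        d = rel[near] / np.maximum(r[near], 1e-9)[:, None]
        if side == "right":
            d = d * mirror
        _, vi = tree.query(d)
        t_v = thickness[side][vi]
        depth = (r[near] - template.radius_white) / t_v
        wm = depth <= 0
        gm = (depth > 0) & (depth < 1)
        t1_loc = np.full(near.sum(), T1_CSF)
        fl_loc = np.full(near.sum(), FLAIR_CSF)
        t1_loc[wm] = T1_WM
        fl_loc[wm] = FLAIR_WM
        prof = T1_GM_BOUNDARY + (T1_GM_PIAL - T1_GM_BOUNDARY) * depth[gm]
        if gwc_mix is not None:
            mu = gwc_mix[side][vi][gm] * (depth[gm] <= 0.5)
            prof = (1.0 - mu) * prof + mu * T1_WM
        t1_loc[gm] = prof
        # FLAIR rises from the WM value at the boundary (keeps the boundary
        # histogram mode at B = FLAIR_WM) to the GM plateau within 1.2 mm,
        # below the mid-depth sampling point of a >= 3 mm cortex
        depth_mm = depth[gm] * t_v[gm]
        ramp = np.clip((depth_mm - 0.3) / 0.9, 0.0, 1.0)
        fl_gm = FLAIR_WM + (FLAIR_GM - FLAIR_WM) * ramp
        if flair_amp_ri is not None:
            # trapezoidal depth profile: full amplitude on a mid-depth
            # plateau (|depth-0.5| <= 0.15) so that mid-cortex probes and
            # their trilinear footprints see the planted shift undiluted
            bump = np.clip((0.45 - np.abs(depth[gm] - 0.5)) / 0.3, 0.0, 1.0)
            fl_gm = fl_gm + flair_amp_ri[side][vi][gm] * FLAIR_SCALE * bump
        fl_loc[gm] = fl_gm
        t1[near] = np.where(wm | gm, t1_loc, t1[near])
        flair[near] = np.where(wm | gm, fl_loc, flair[near])
    t1 = t1.reshape(shape)
    flair = flair.reshape(shape)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        t1 = t1 + rng.normal(0, noise_sd, shape)
        flair = flair + rng.normal(0, noise_sd, shape)
    return (IntensityVolume(t1, affine, "T1"),
            IntensityVolume(flair, affine, "FLAIR"))


def hippocampus_mask(template: Template, side: str, volume_mm3: float,
                     like: IntensityVolume) -> IntensityVolume:
    """Ellipsoidal label whose voxel count realises ``volume_mm3`` exactly
    (to one voxel) on the grid of ``like``."""
    vox = like.voxel_volume_mm3
    n_target = int(round(volume_mm3 / vox))
    shape = like.grid.shape
    ii = np.indices(shape).reshape(3, -1).T
    xyz = ii @ like.affine[:3, :3].T + like.affine[:3, 3]
    rel = xyz - template.center(side)
    axes = np.array([1.3, 0.8, 0.7])
    q = ((rel / axes) ** 2).sum(axis=1)
    order = np.argsort(q, kind="stable")[:n_target]
    mask = np.zeros(np.prod(shape), dtype=np.uint8)
    mask[order] = 1
    return IntensityVolume(mask.reshape(shape), like.affine.copy(), "label")


def _write_full(cohort: Cohort, effects, rng) -> None:
    spec, template, meta = cohort.spec, cohort.template, cohort.meta
    sc = FEATURE_SCALES
    gt = cohort.ground_truth
    manifest = []
    op = _noise_operator(spec.template_level, spec.template_radius,
                         spec.noise_fwhm_mm)
    for s, row in meta.iterrows():
        sub_dir = cohort.out_dir / row.id
        sub_dir.mkdir(parents=True, exist_ok=True)
        is_pat = row.group == "patient"
        lesion = row.lesion_side if is_pat else None
        thickness, gwc_mix, flair_amp = {}, {}, {}
        for side_i, side in enumerate(("left", "right")):
            th = cohort.features["thickness"][
                s, side_i * template.n_vertices:(side_i + 1)
                * template.n_vertices].copy()
            thickness[side] = np.clip(th, 2.0, 6.0)
            mix = np.zeros(template.n_vertices)
            amp = np.zeros(template.n_vertices)
            if is_pat and side == lesion:
                for eff in effects:
                    extra = (eff.fc_shift_sd * row.febrile_convulsions
                             + eff.blurring_shift_sd
                             * row.radiological_blurring)
                    a = eff.direction * (eff.cohen_d + extra) \
                        * eff.profile(template)
                    if eff.feature == "gwc":
                        # delta-C of a*sd on the 0.3-depth ratio <-> mixing mu
                        mix += np.clip(a * sc["gwc"]["sd"] * T1_WM
                                       / (T1_WM - (T1_GM_BOUNDARY
                                          + 0.3 * (T1_GM_PIAL
                                                   - T1_GM_BOUNDARY))), 0, 1)
                    elif eff.feature == "flair_ri":
                        amp += a * sc["flair_ri"]["sd"]
            gwc_mix[side] = mix
            flair_amp[side] = amp
        sub_rng = np.random.default_rng([spec.seed, 77, s])
        t1, flair = synthesize_subject_volumes(
            template, thickness, gwc_mix, flair_amp,
            noise_sd=spec.voxel_noise_sd, rng=sub_rng,
            voxel_size_mm=spec.voxel_size_mm)
        hrows = cohort.hippo[cohort.hippo.id == row.id]
        for side in ("left", "right"):
            vol = float(hrows.loc[hrows.side == side, "volume_mm3"].iloc[0])
            ri = float(hrows.loc[hrows.side == side, "mean_ri"].iloc[0])
            mask = hippocampus_mask(template, side, vol, flair)
            inside = mask.grid.astype(bool)
            flair.grid[inside] = (FLAIR_GM + ri * FLAIR_SCALE
                                  + sub_rng.normal(0, spec.voxel_noise_sd,
                                                   inside.sum()))
            write_volume(mask, sub_dir / f"hippo_{side}.nii.gz")
            manifest.append(str(sub_dir / f"hippo_{side}.nii.gz"))
        write_volume(t1, sub_dir / "T1.nii.gz")
        write_volume(flair, sub_dir / "FLAIR.nii.gz")
        manifest += [str(sub_dir / "T1.nii.gz"), str(sub_dir / "FLAIR.nii.gz")]
        for side in ("left", "right"):
            hemi = template.hemi(side)
            pial = (hemi.vertices_white
                    + thickness[side][:, None]
                    * (hemi.vertices_white - template.center(side))
                    / np.linalg.norm(hemi.vertices_white
                                     - template.center(side),
                                     axis=1, keepdims=True))
            subj_surf = SurfaceModel(hemi.vertices_white, pial, hemi.faces,
                                     side, hemi.template_id)
            wp = sub_dir / f"{side}.white.surf.gii"
            pp = sub_dir / f"{side}.pial.surf.gii"
            write_surface(subj_surf, wp, pp)
            manifest += [str(wp), str(pp)]
    (cohort.out_dir / "manifest_volumes.json").write_text(
        json.dumps(sorted(manifest), indent=1))


def _write_fast(cohort: Cohort) -> None:
    out = cohort.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cohort.meta.to_csv(out / "subjects.csv", index=False)
    cohort.hippo.to_csv(out / "hippocampus.csv", index=False)
    manifest = {"subjects": list(cohort.meta.id), "files": []}
    V = cohort.template.n_vertices
    for s, row in cohort.meta.iterrows():
        sub_dir = out / row.id
        sub_dir.mkdir(exist_ok=True)
        for feat, Y in cohort.features.items():
            for side_i, side in enumerate(("left", "right")):
                vm = VertexMap(Y[s, side_i * V:(side_i + 1) * V], feat, side)
                p = sub_dir / f"{feat}.{side}.mgh"
                write_vertex_map(vm, p)
                manifest["files"].append(str(p.relative_to(out)))
    gt = cohort.ground_truth
    gt_json = {
        "regions": {k: v.tolist() for k, v in gt.regions.items()},
        "age_slopes": gt.age_slopes,
        "effects": [asdict(e) for e in gt.effects],
        "hippo_means": {k: list(v) for k, v in gt.hippo_means.items()},
        "subject_effect_sd": gt.subject_effect_sd,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_json, indent=1,
                                                      sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
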