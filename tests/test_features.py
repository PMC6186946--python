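"""Feature definitions on constructed geometry: thickness, depth sampling,
gray-white contrast, mode estimation, FLAIR normalization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epihs import _mesh
from epihs.features import (DepthSampleSpec, FlairNormalizationContext,
                            build_flair_context, compute_gwc,
                            compute_thickness, estimate_mode,
                            extract_subject_features, normalize_flair,
                            sample_intensity_at_depth)
from epihs.surface_core import (IntensityVolume, SmoothingKernelSpec,
                                SmoothingOperator, SurfaceModel, VertexMap)


def _concentric(level=4, r_w=49.0, r_p=52.0):
    u, f = _mesh.icosphere(level)
    return SurfaceModel(u * r_w, u * r_p, f, "left")


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def test_concentric_sphere_thickness_is_three_mm():
    t = compute_thickness(_concentric(level=5))
    np.testing.assert_allclose(t.values, 3.0, atol=1e-3)


def test_zero_thickness_degenerate_surface_warns():
    u, f = _mesh.icosphere(3)
    surf = SurfaceModel(u * 20, u * 20, f, "left")
    with pytest.warns(UserWarning, match="zero-thickness"):
        t = compute_thickness(surf)
    np.testing.assert_allclose(t.values, 0.0, atol=1e-9)


def test_planted_thickness_field_recovered(template3):
    t = compute_thickness(template3.left)
    assert np.max(np.abs(t.values - template3.base_thickness)) < 0.05


def test_thickness_invariant_under_rigid_motion(template3):
    surf = template3.left
    rot = stats.special_ortho_group.rvs(3, random_state=4)
    shift = np.array([13.0, -7.0, 42.0])
    moved = SurfaceModel(surf.vertices_white @ rot.T + shift,
                         surf.vertices_pial @ rot.T + shift,
                         surf.faces, "left")
    np.testing.assert_allclose(compute_thickness(moved).values,
                               compute_thickness(surf).values, atol=1e-8)


# ---------------------------------------------------------------------------
# depth sampling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def linear_profile_volume():
    """Concentric shell with a linear intensity profile across the ribbon:
    125 inside white (r<20), 106 -> 86 across 20 < r < 23, 40 outside."""
    n = 64
    aff = np.eye(4)
    aff[:3, 3] = -(n - 1) / 2.0
    ii = np.indices((n, n, n)).reshape(3, -1).T + aff[:3, 3]
    r = np.linalg.norm(ii, axis=1)
    depth = (r - 20.0) / 3.0
    g = np.where(depth <= 0, 125.0,
                 np.where(depth < 1, 106.0 + (86.0 - 106.0) * depth, 40.0))
    return IntensityVolume(g.reshape(n, n, n), aff, "T1")


def test_depth_sampling_recovers_linear_profile(linear_profile_volume):
    surf = _concentric(level=3, r_w=20.0, r_p=23.0)
    for frac, expected in ((0.5, 96.0), (0.3, 100.0), (0.7, 92.0)):
        vm = sample_intensity_at_depth(linear_profile_volume, surf,
                                       DepthSampleSpec(depth_fraction=frac))
        assert abs(np.nanmean(vm.values) - expected) / expected < 0.01
    wm = sample_intensity_at_depth(
        linear_profile_volume, surf,
        DepthSampleSpec(depth_fraction=0.0, offset_mm=1.0))
    assert abs(np.nanmean(wm.values) - 125.0) / 125.0 < 0.01


def test_depth_sampling_space_mismatch_errors(linear_profile_volume):
    surf = _concentric(level=3, r_w=500.0, r_p=503.0)
    with pytest.raises(ValueError, match="outside the volume"):
        sample_intensity_at_depth(linear_profile_volume, surf,
                                  DepthSampleSpec(0.5))


def test_depth_spec_validation():
    with pytest.raises(ValueError):
        DepthSampleSpec(depth_fraction=1.5)
    with pytest.raises(ValueError):
        DepthSampleSpec(depth_fraction=0.5, offset_mm=-1.0)


# ---------------------------------------------------------------------------
# gray-white contrast
# ---------------------------------------------------------------------------

def test_gwc_arithmetic_and_masking():
    gm = VertexMap(np.array([100.0, 100.0, 112.5, 50.0]), "gm", "left")
    wm = VertexMap(np.array([125.0, 100.0, 125.0, 0.0]), "wm", "left")
    c = compute_gwc(gm, wm)
    np.testing.assert_allclose(c.values[:3], [0.8, 1.0, 0.9])
    assert np.isnan(c.values[3])           # WM == 0 is masked


def test_gwc_mixing_model():
    """Mixing fraction mu pulls GM toward WM: GM' = (1-mu) GM + mu WM."""
    gm, wm, mu = 100.0, 125.0, 0.5
    gm_blurred = (1 - mu) * gm + mu * wm
    c = compute_gwc(VertexMap(np.array([gm_blurred]), "g", "left"),
                    VertexMap(np.array([wm]), "w", "left"))
    assert c.values[0] == pytest.approx(0.9)


@given(scale=st.floats(0.1, 10.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_gwc_invariant_under_global_intensity_scaling(scale):
    rng = np.random.default_rng(0)
    gm = rng.uniform(80, 120, 50)
    wm = rng.uniform(110, 140, 50)
    c1 = compute_gwc(VertexMap(gm, "g", "left"), VertexMap(wm, "w", "left"))
    c2 = compute_gwc(VertexMap(gm * scale, "g", "left"),
                     VertexMap(wm * scale, "w", "left"))
    np.testing.assert_allclose(c1.values, c2.values, rtol=1e-12)


# ---------------------------------------------------------------------------
# mode estimation and FLAIR normalization
# ---------------------------------------------------------------------------

def _kde_mode(x):
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 2000)
    return grid[np.argmax(kde(grid))]


def test_mode_of_normal_sample_matches_kde_oracle():
    x = np.random.default_rng(0).normal(120, 5, 100_000)
    m = estimate_mode(x, bins=100)
    assert abs(m - 120.0) < 0.5
    assert abs(m - _kde_mode(x)) < 0.5


def test_mode_picks_taller_peak_of_bimodal_mixture():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(80, 3, 40_000), rng.normal(120, 3, 60_000)])
    m = estimate_mode(x, bins=100)
    assert abs(m - 120.0) < 2.0
    assert abs(m - _kde_mode(x)) < 2.0


def test_mode_degenerate_and_small_samples():
    assert estimate_mode(np.full(200, 7.0)) == 7.0
    with pytest.raises(ValueError, match="100"):
        estimate_mode(np.arange(50.0))


def test_normalize_flair_substitutions():
    ctx = FlairNormalizationContext(gm_peak=120.0, boundary=80.0)
    vm = VertexMap(np.array([120.0, 80.0, 140.0]), "flair", "left")
    ri = normalize_flair(vm, ctx)
    np.testing.assert_allclose(ri.values, [0.0, -1.0, 0.5])
    with pytest.raises(ValueError, match="undefined"):
        FlairNormalizationContext(gm_peak=100.0, boundary=100.0)


@given(a=st.floats(0.1, 10.0), b=st.floats(-100.0, 100.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_ri_invariant_under_affine_flair_rescaling(a, b):
    """The point of the normalization: RI is unchanged when the raw FLAIR
    intensities are rescaled I -> aI + b (a > 0), context refit included."""
    rng = np.random.default_rng(2)
    mid = rng.normal(120, 6, 4000)
    bnd = rng.normal(80, 5, 4000)
    vm = VertexMap(mid[:500], "flair", "left")

    def ri_of(mid_s, bnd_s, values):
        ctx = build_flair_context(
            [VertexMap(mid_s, "m", "left")], [VertexMap(bnd_s, "b", "left")])
        return normalize_flair(VertexMap(values, "flair", "left"), ctx).values

    r1 = ri_of(mid, bnd, vm.values)
    r2 = ri_of(a * mid + b, a * bnd + b, a * vm.values + b)
    np.testing.assert_allclose(r1, r2, atol=1e-6)


# ---------------------------------------------------------------------------
# full extraction chain on the synthetic world
# ---------------------------------------------------------------------------

def test_extraction_chain_on_full_cohort(full_cohort):
    cohort = full_cohort
    sid = cohort.meta.id[0]
    feats = extract_subject_features(cohort.out_dir / sid)
    side = cohort.meta.lesion_side[0]
    # planted FLAIR patch raises mean regional RI above the rest
    gt = cohort.ground_truth.regions["flair_ri"]
    ri = feats["flair_ri"][side].values
    assert np.nanmean(ri[gt]) > np.nanmean(np.delete(ri, gt)) + 0.1
    # thickness matches the planted (smoothed) per-subject field
    V = cohort.template.n_vertices
    planted = np.clip(cohort.features["thickness"][0, :V], 2.0, 6.0)
    spec = SmoothingKernelSpec.for_surface(cohort.template.left, 10.0)
    op = SmoothingOperator(cohort.template.left, spec)
    err = np.nanmax(np.abs(feats["thickness"]["left"].values
                           - op.apply(planted)))
    assert err < 0.05
    # rerun is deterministic
    again = extract_subject_features(cohort.out_dir / sid, write=False)
    np.testing.assert_array_equal(again["gwc"][side].values,
                                  feats["gwc"][side].values)
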