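"""Hippocampal volumetry/FLAIR quantification and lateralization models."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epihs.features import FlairNormalizationContext
from epihs.hippocampus import (hippo_flair, hippo_group_model,
                               hippo_paired_tests, hippo_volume,
                               measures_to_lesion_frame)
from epihs.surface_core import IntensityVolume
from epihs.synthetic_cohort import CohortSpec, generate_cohort


def _mask(n_voxels, voxel=1.0, shape=(20, 20, 20)):
    g = np.zeros(shape, np.uint8)
    g.flat[:n_voxels] = 1
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return IntensityVolume(g, aff, "label")


# ---------------------------------------------------------------------------
# volume and FLAIR
# ---------------------------------------------------------------------------

def test_volume_is_count_times_voxel_volume():
    assert hippo_volume(_mask(3000, 1.0)) == pytest.approx(3000.0)
    assert hippo_volume(_mask(3000, 0.5)) == pytest.approx(375.0)
    with pytest.raises(ValueError, match="empty"):
        hippo_volume(_mask(0))


def test_volume_invariant_under_rigid_reorientation():
    m = _mask(1234)
    rot = stats.special_ortho_group.rvs(3, random_state=0)
    aff = np.eye(4)
    aff[:3, :3] = rot
    aff[:3, 3] = [5.0, -3.0, 2.0]
    rotated = IntensityVolume(m.grid, aff, "label")
    assert hippo_volume(rotated) == pytest.approx(hippo_volume(m))


def test_hippo_flair_substitutions_and_affine_invariance():
    ctx = FlairNormalizationContext(120.0, 80.0)
    m = _mask(500)
    flair = IntensityVolume(np.full(m.grid.shape, 120.0), m.affine, "FLAIR")
    assert hippo_flair(m, flair, ctx) == pytest.approx(0.0)
    flair.grid[:] = 80.0
    assert hippo_flair(m, flair, ctx) == pytest.approx(-1.0)
    # affine rescaling of the FLAIR volume with a matching context refit
    a, b = 2.5, 30.0
    flair.grid[:] = 97.0
    r1 = hippo_flair(m, flair, ctx)
    ctx2 = FlairNormalizationContext(a * 120.0 + b, a * 80.0 + b)
    flair2 = IntensityVolume(a * flair.grid + b, m.affine, "FLAIR")
    assert hippo_flair(m, flair2, ctx2) == pytest.approx(r1, abs=1e-12)


def test_hippo_flair_grid_mismatch_errors():
    ctx = FlairNormalizationContext(120.0, 80.0)
    m = _mask(100)
    flair = IntensityVolume(np.zeros((5, 5, 5)), np.eye(4), "FLAIR")
    with pytest.raises(ValueError, match="grids"):
        hippo_flair(m, flair, ctx)


def test_planted_hippocampal_ri_shift_recovered(full_cohort):
    """Full-fidelity masks + FLAIR reproduce the generator's planted mean
    RI within 0.05 (using the subject's own cortical context)."""
    import json
    from epihs.features import extract_subject_features
    from epihs.surface_core import read_volume
    cohort = full_cohort
    for sid in cohort.meta.id[:2]:
        extract_subject_features(cohort.out_dir / sid)
        prov = json.loads((cohort.out_dir / sid
                           / "features_provenance.json").read_text())
        ctx = FlairNormalizationContext(prov["gm_peak"], prov["boundary"])
        flair = read_volume(cohort.out_dir / sid / "FLAIR.nii.gz")
        for side in ("left", "right"):
            mask = read_volume(cohort.out_dir / sid / f"hippo_{side}.nii.gz")
            planted = float(cohort.hippo[(cohort.hippo.id == sid)
                                         & (cohort.hippo.side == side)]
                            .mean_ri.iloc[0])
            assert abs(hippo_flair(mask, flair, ctx) - planted) < 0.05


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def _measures(vol_ipsi, vol_contra, ri_ipsi=None, ri_contra=None):
    n = len(vol_ipsi)
    ri_ipsi = ri_ipsi if ri_ipsi is not None else np.zeros(n)
    ri_contra = ri_contra if ri_contra is not None else np.zeros(n)
    meta = pd.DataFrame([dict(id=f"p{i}", group="patient", age_years=10.0,
                              lesion_side="left", icv_mm3=1.4e6)
                         for i in range(n)])
    rows = []
    for i in range(n):
        rows.append(dict(id=f"p{i}", side="left", volume_mm3=vol_ipsi[i],
                         mean_ri=ri_ipsi[i], icv_mm3=1.4e6))
        rows.append(dict(id=f"p{i}", side="right", volume_mm3=vol_contra[i],
                         mean_ri=ri_contra[i], icv_mm3=1.4e6))
    return pd.DataFrame(rows), meta


def test_paired_t_matches_hand_computation():
    measures, meta = _measures([1.0, 2.0, 4.0], [2.0, 4.0, 5.0])
    out = hippo_paired_tests(measures, meta)
    assert out["volume"]["t"] == pytest.approx(-4.0)
    assert out["volume"]["df"] == 2
    # scipy as a second, independent route
    t, _ = stats.ttest_rel([1, 2, 4], [2, 4, 5])
    assert out["volume"]["t"] == pytest.approx(float(t))


def test_paired_t_sign_swap_negates_and_degenerates_flagged():
    m1, meta = _measures([1.0, 2.0, 4.0], [2.0, 4.0, 5.0])
    m2, _ = _measures([2.0, 4.0, 5.0], [1.0, 2.0, 4.0])
    t1 = hippo_paired_tests(m1, meta)["volume"]["t"]
    t2 = hippo_paired_tests(m2, meta)["volume"]["t"]
    assert t1 == pytest.approx(-t2)
    same, _ = _measures([3.0, 3.0, 4.0], [3.0, 3.0, 4.0])
    assert hippo_paired_tests(same, meta)["volume"]["t"] == 0.0
    const, _ = _measures([4.0, 5.0, 6.0], [3.0, 4.0, 5.0])
    out = hippo_paired_tests(const, meta)["volume"]
    assert out["degenerate"] and np.isinf(out["t"])


# ---------------------------------------------------------------------------
# group model
# ---------------------------------------------------------------------------

def test_group_model_matches_closed_form_ols():
    rng = np.random.default_rng(5)
    rows, meta_rows = [], []
    for i in range(6):
        grp = "patient" if i < 3 else "control"
        age, icv = 8.0 + i, 1.3e6 + float(rng.normal(0, 5e4))
        meta_rows.append(dict(id=f"s{i}", group=grp, age_years=age,
                              lesion_side="left" if grp == "patient"
                              else "none", icv_mm3=icv))
        for side in ("left", "right"):
            rows.append(dict(id=f"s{i}", side=side,
                             volume_mm3=3000.0 + 100 * i
                             + (-400 if grp == "patient"
                                and side == "left" else 0)
                             + rng.normal(0, 20),
                             mean_ri=rng.normal(0, 0.1), icv_mm3=icv))
    measures, meta = pd.DataFrame(rows), pd.DataFrame(meta_rows)
    out = hippo_group_model(measures, meta)
    # hand OLS on the exact table the ipsi model sees
    wide = measures_to_lesion_frame(measures, meta)
    pat = wide[wide.group == "patient"]
    ctrl = measures[measures.id.isin(wide[wide.group == "control"].id)]
    y, X = [], []
    for _, r in pat.iterrows():
        y.append(r.vol_ipsi)
        X.append([1.0, 1.0, r.age_years, r.icv_mm3])
    for _, r in ctrl.iterrows():
        age = float(meta.set_index("id").loc[r.id, "age_years"])
        y.append(r.volume_mm3)
        X.append([1.0, 0.0, age, r.icv_mm3])
    X, y = np.asarray(X), np.asarray(y)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - 4)
    t_hand = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
    assert out["volume_ipsi"]["t"] == pytest.approx(t_hand, abs=1e-10)


def test_group_model_recovers_ipsi_atrophy_not_contra():
    """Planted ipsilesional atrophy with a null contra side: the ipsi group
    term is significant and the contra term is not, in >= 90% of 20 seeds."""
    hits_ipsi, hits_contra = 0, 0
    for seed in range(20):
        spec = CohortSpec(seed=7000 + seed,
                          hippo_patient_contra=(3300.0, 300.0),
                          hippo_control_left=(3300.0, 300.0),
                          hippo_control_right=(3300.0, 300.0))
        cohort = generate_cohort(spec, effects=[])
        out = hippo_group_model(cohort.hippo, cohort.meta)
        hits_ipsi += out["volume_ipsi"]["p"] < 0.05
        hits_contra += out["volume_contra"]["p"] < 0.05
    assert hits_ipsi >= 18
    assert hits_contra <= 2


def test_group_model_null_p_uniform():
    """No planted group difference: the group-term p is uniform over
    50 seeds (KS test, alpha = 0.01)."""
    null = dict(hippo_patient_ipsi=(3300.0, 300.0),
                hippo_patient_contra=(3300.0, 300.0),
                hippo_control_left=(3300.0, 300.0),
                hippo_control_right=(3300.0, 300.0),
                hippo_ri_shift_ipsi=0.0, hippo_ri_shift_contra=0.0)
    ps = []
    for seed in range(50):
        cohort = generate_cohort(CohortSpec(seed=7100 + seed, **null),
                                 effects=[])
        ps.append(hippo_group_model(cohort.hippo, cohort.meta)
                  ["volume_ipsi"]["p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_group_model_requires_minimum_subjects():
    measures, meta = _measures([1.0, 2.0], [2.0, 3.0])
    with pytest.raises(ValueError, match=">= 3"):
        hippo_group_model(measures, meta)
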