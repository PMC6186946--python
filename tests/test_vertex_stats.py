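"""Vertex-wise GLM, smoothness/resel estimation, RFT cluster inference,
and the permutation oracle, each against an independent reference."""
import numpy as np
import pytest
from scipy import stats

from epihs.harmonization import FeatureMatrix
from epihs.synthetic_cohort import (CohortSpec, EffectSpec, build_template,
                                    generate_cohort, _noise_operator)
from epihs.vertex_stats import (AnalysisDomain, ClusterResult, DesignMatrix,
                                _tile_mask, build_design, cluster_cohens_d,
                                cluster_p_fwe, estimate_resels, fit_glm,
                                permutation_cluster_test, rft_cluster_correct,
                                uncorrected_tmap_export)

from conftest import analyze_feature


def _matrix(Y, ids=None):
    V = Y.shape[1] // 2
    ids = ids or [f"s{i}" for i in range(len(Y))]
    return FeatureMatrix(Y, ids, "x", np.ones(V, bool))


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def test_glm_matches_closed_form_normal_equations():
    """OLS t equals the hand-computed (X'X)^-1 X'y solution to 1e-10, and
    statsmodels agrees as an independent implementation."""
    rng = np.random.default_rng(8)
    n = 8
    X = np.column_stack([np.ones(n), np.r_[np.ones(4), np.zeros(4)],
                         rng.normal(10, 3, n)])
    design = DesignMatrix(X, ["intercept", "group", "age"],
                          [f"s{i}" for i in range(n)])
    Y = rng.normal(0, 1, (n, 6))
    glm = fit_glm(_matrix(Y), design, np.array([0.0, 1.0, 0.0]))
    xtx_inv = np.linalg.inv(X.T @ X)
    for v in range(6):
        beta = xtx_inv @ X.T @ Y[:, v]
        resid = Y[:, v] - X @ beta
        s2 = resid @ resid / (n - 3)
        t_hand = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
        assert abs(glm.t[v] - t_hand) < 1e-10
    import statsmodels.api as sm
    fit = sm.OLS(Y[:, 0], X).fit()
    assert abs(glm.t[0] - fit.tvalues[1]) < 1e-8


def test_glm_perfect_linear_fit_has_zero_residuals():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    X = np.column_stack([np.ones(5), x])
    design = DesignMatrix(X, ["intercept", "slope"],
                          [f"s{i}" for i in range(5)])
    Y = np.tile(x[:, None], (1, 2))
    glm = fit_glm(_matrix(Y), design, np.array([0.0, 1.0]))
    np.testing.assert_allclose(glm.beta[1], 1.0, atol=1e-12)
    np.testing.assert_allclose(glm.residuals, 0.0, atol=1e-12)
    assert glm.degenerate.all()            # zero variance flagged, not +inf


def test_glm_zero_variance_vertices_masked():
    n = 10
    group = np.r_[np.ones(5), np.zeros(5)]
    X = np.column_stack([np.ones(n), group])
    design = DesignMatrix(X, ["intercept", "group"],
                          [f"s{i}" for i in range(n)])
    Y = np.tile(group[:, None], (1, 4))    # exact group difference, sigma=0
    glm = fit_glm(_matrix(Y), design, np.array([0.0, 1.0]))
    assert glm.degenerate.all() and not glm.mask.any()
    assert np.isnan(glm.t).all()
    assert glm.df == n - 2


def test_rank_deficient_design_names_columns():
    n = 6
    age = np.arange(n, dtype=float)
    with pytest.raises(ValueError, match="age"):
        DesignMatrix(np.column_stack([np.ones(n), age, 2 * age]),
                     ["intercept", "age", "age2x"],
                     [f"s{i}" for i in range(n)])


def test_tmap_invariant_under_affine_feature_transform():
    rng = np.random.default_rng(9)
    n = 14
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                         rng.normal(12, 3, n)])
    design = DesignMatrix(X, ["intercept", "group", "age"],
                          [f"s{i}" for i in range(n)])
    Y = rng.normal(0, 1, (n, 10))
    c = np.array([0.0, 1.0, 0.0])
    t1 = fit_glm(_matrix(Y), design, c).t
    t2 = fit_glm(_matrix(3.5 * Y - 11.0), design, c).t
    np.testing.assert_allclose(t1, t2, atol=1e-9)


# ---------------------------------------------------------------------------
# smoothness / resels
# ---------------------------------------------------------------------------

def _noise_maps(op, rng, n_subj):
    left = op.correlated_noise(rng, n_subj)
    right = op.correlated_noise(rng, n_subj)
    return np.concatenate([left, right], axis=0).T


def test_resels_recover_applied_smoothness(template4, domain4):
    """Residual-based FWHM of white noise smoothed at 10 mm lands in
    [8.5, 11.5] for every one of 20 seeds."""
    from epihs.surface_core import SmoothingKernelSpec, SmoothingOperator
    op = SmoothingOperator(template4.left,
                           SmoothingKernelSpec.for_surface(template4.left,
                                                           10.0))
    ests = []
    for seed in range(20):
        maps = _noise_maps(op, np.random.default_rng(seed), 20)
        res = estimate_resels(maps, domain4,
                              np.ones(domain4.n_vertices, bool))
        ests.append(res.global_fwhm_mm)
    assert min(ests) > 8.5 and max(ests) < 11.5


def test_unsmoothed_noise_has_edge_scale_fwhm_and_more_resels(template4,
                                                              domain4):
    from epihs.surface_core import SmoothingKernelSpec, SmoothingOperator
    rng = np.random.default_rng(0)
    white = rng.standard_normal((20, domain4.n_vertices))
    res_white = estimate_resels(white, domain4,
                                np.ones(domain4.n_vertices, bool))
    edge = template4.left.edge_lengths.mean()
    assert 0.8 * edge < res_white.global_fwhm_mm < 1.8 * edge
    op = SmoothingOperator(template4.left,
                           SmoothingKernelSpec.for_surface(template4.left,
                                                           10.0))
    res_smooth = estimate_resels(_noise_maps(op, rng, 20), domain4,
                                 np.ones(domain4.n_vertices, bool))
    assert res_white.total_resels > res_smooth.total_resels


def test_resels_invariant_under_uniform_scaling(template4, domain4):
    """Doubling all edge lengths while doubling the kernel leaves the resel
    count unchanged (area and FWHM^2 scale together)."""
    tpl2 = build_template(4, 98.0)
    dom2 = AnalysisDomain(tpl2.left)
    r = []
    for tpl, dom, fwhm in ((build_template(4, 49.0), domain4, 10.0),
                           (tpl2, dom2, 20.0)):
        op = _noise_operator(4, tpl.radius_white, fwhm)
        maps = _noise_maps(op, np.random.default_rng(1), 20)
        r.append(estimate_resels(maps, dom,
                                 np.ones(dom.n_vertices, bool)).total_resels)
    assert abs(r[1] - r[0]) / r[0] < 0.05


def test_resels_preconditions(domain4):
    with pytest.raises(ValueError, match="3 residual"):
        estimate_resels(np.zeros((2, domain4.n_vertices)), domain4,
                        np.ones(domain4.n_vertices, bool))
    small = np.zeros(domain4.n_vertices, bool)
    small[:50] = True
    with pytest.raises(ValueError, match="mask too small"):
        estimate_resels(np.random.default_rng(0).normal(
            size=(5, domain4.n_vertices)), domain4, small)


# ---------------------------------------------------------------------------
# RFT cluster correction
# ---------------------------------------------------------------------------

def test_cdt_one_puts_whole_mask_in_per_component_clusters():
    cohort = generate_cohort(CohortSpec(n_patients=5, n_controls=6,
                                        template_level=3,
                                        template_radius=20.0, seed=21),
                             effects=[])
    _fm, glm, resels, _cl = analyze_feature(cohort, "gwc")
    domain = AnalysisDomain(cohort.template.left)
    clusters = rft_cluster_correct(glm, resels, domain, cdt_p=1.0)
    pos = [c for c in clusters if c.direction == "positive"]
    assert len(pos) == domain.n_components
    assert sum(len(c.vertices) for c in pos) == glm.mask.sum()


def test_rft_p_monotone_in_extent(template4, domain4):
    op = _noise_operator(4, 49.0, 15.0)
    maps = _noise_maps(op, np.random.default_rng(2), 30)
    res = estimate_resels(maps, domain4, np.ones(domain4.n_vertices, bool))
    t_c = float(stats.t.isf(0.025, 27))
    ps = [cluster_p_fwe(k, t_c, 27, res) for k in (0.5, 1.5, 3.0, 6.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    assert all(0.0 <= p <= 1.0 for p in ps)


def test_no_suprathreshold_vertices_yields_empty_list(template4, domain4):
    cohort = generate_cohort(CohortSpec(seed=22), effects=[])
    _fm, glm, resels, _ = analyze_feature(cohort, "flair_ri", domain=domain4)
    glm.t[:] = 0.0                          # flatten the field
    assert rft_cluster_correct(glm, resels, domain4) == []


# ---------------------------------------------------------------------------
# cluster effect sizes
# ---------------------------------------------------------------------------

def test_cohens_d_arithmetic_and_errors():
    V = 3
    # both groups get the same spread (pooled SD exactly 1), means 1 vs 0
    spread = np.array([-1.5, -0.5, 0.5, 1.5]) / np.sqrt(5 / 3)
    Y = np.vstack([1.0 + spread[:, None] * np.ones(2 * V),
                   0.0 + spread[:, None] * np.ones(2 * V)])
    fm = _matrix(Y)
    patients = [f"s{i}" for i in range(4)]
    assert cluster_cohens_d(fm, patients, np.arange(V)) == pytest.approx(1.0)
    # identical group compositions -> d = 0
    same = _matrix(np.vstack([spread[:, None] * np.ones(2 * V)] * 2))
    assert cluster_cohens_d(same, patients,
                            np.arange(V)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="non-empty"):
        cluster_cohens_d(fm, [], np.arange(V))
    with pytest.raises(ValueError, match="empty cluster"):
        cluster_cohens_d(fm, patients, np.array([], dtype=int))


def test_cluster_d_matches_analytic_generator_oracle():
    """The cluster-mean Cohen's d has a closed-form expectation under the
    generator: planted d attenuated by the mean patch profile and divided
    by the cluster-mean noise SD (from the noise-field covariance). The
    across-seed mean must match it."""
    eff = EffectSpec("flair_ri", 1.3, +1)
    spec0 = CohortSpec(seed=0)
    cohort0 = generate_cohort(spec0, effects=[eff])
    reg = cohort0.ground_truth.regions["flair_ri"]
    prof = cohort0.ground_truth.profiles["flair_ri"]
    op = _noise_operator(spec0.template_level, spec0.template_radius,
                         spec0.noise_fwhm_mm)
    w = np.zeros(cohort0.template.n_vertices)
    w[reg] = 1.0 / len(reg)
    b = w / op.noise_std()
    for _ in range(op.n_iter):
        b = op.S @ b
    noise_sd_cluster = float(np.sqrt(b @ b))
    sd = 0.30                               # flair between-subject SD
    slope = -0.005                          # flair age slope per year
    signal = 1.3 * sd * prof[reg].mean() + slope * (10.53 - 14.33)
    d_expected = signal / (sd * noise_sd_cluster)

    ds = []
    for seed in range(12):
        cohort = generate_cohort(CohortSpec(seed=600 + seed), effects=[eff])
        fm = _matrix(cohort.features["flair_ri"], list(cohort.meta.id))
        pat = list(cohort.meta.loc[cohort.meta.group == "patient", "id"])
        # measure in the lesion block per patient: flip raw data manually
        V = cohort.template.n_vertices
        data = fm.data.copy()
        for i, sid in enumerate(fm.subject_ids):
            if cohort.meta.set_index("id").loc[sid, "lesion_side"] == "right":
                data[i] = np.concatenate([data[i, V:], data[i, :V]])
        ds.append(cluster_cohens_d(_matrix(data, fm.subject_ids), pat, reg))
    assert abs(np.mean(ds) - d_expected) < 0.3


# ---------------------------------------------------------------------------
# permutation oracle
# ---------------------------------------------------------------------------

def test_permutation_null_p_bounded_and_strong_effect_detected(template4):
    domain = AnalysisDomain(template4.left)
    null = generate_cohort(CohortSpec(seed=31), effects=[])
    fm, _g, _r, _c = analyze_feature(null, "flair_ri", domain=domain)
    design = build_design(null.meta)
    cl = permutation_cluster_test(fm, design, design.contrast("group"),
                                  domain, n_perm=120, seed=1)
    assert all(c.p_perm >= 1.0 / 121.0 for c in cl)

    strong = generate_cohort(CohortSpec(seed=32),
                             effects=[EffectSpec("flair_ri", 2.0, +1)])
    fm2, _g, _r, _c = analyze_feature(strong, "flair_ri", domain=domain)
    design2 = build_design(strong.meta)
    cl2 = permutation_cluster_test(fm2, design2, design2.contrast("group"),
                                   domain, n_perm=199, seed=2)
    gt = strong.ground_truth.regions["flair_ri"]
    hits = [c for c in cl2 if c.direction == "positive"
            and len(np.intersect1d(c.vertices, gt)) > 0]
    # 199 permutations resolve p to 1/200; a strong effect sits at the floor
    assert hits and min(c.p_perm for c in hits) <= 2.0 / 200.0


def test_permutation_and_rft_agree_in_cluster_rank_order(template4):
    domain = AnalysisDomain(template4.left)
    cohort = generate_cohort(CohortSpec(seed=33),
                             effects=[EffectSpec("flair_ri", 0.9, +1)])
    fm, _g, _r, _c = analyze_feature(cohort, "flair_ri", domain=domain)
    design = build_design(cohort.meta)
    cl = permutation_cluster_test(fm, design, design.contrast("group"),
                                  domain, n_perm=150, seed=3)
    by_rft = sorted(cl, key=lambda c: c.p_fwe)
    perm_ps = [c.p_perm for c in by_rft]
    assert perm_ps == sorted(perm_ps)


def test_permutation_warns_on_few_permutations(template4):
    domain = AnalysisDomain(template4.left)
    cohort = generate_cohort(CohortSpec(n_patients=5, n_controls=6, seed=34),
                             effects=[])
    fm, _g, _r, _c = analyze_feature(cohort, "gwc", domain=domain)
    design = build_design(cohort.meta)
    with pytest.warns(UserWarning, match="n_perm"):
        permutation_cluster_test(fm, design, design.contrast("group"),
                                 domain, n_perm=50, seed=0)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def test_uncorrected_tmap_export_identity_and_sentinels():
    cohort = generate_cohort(CohortSpec(n_patients=5, n_controls=6, seed=41),
                             effects=[])
    fm, glm, _r, _c = analyze_feature(cohort, "thickness")
    out = uncorrected_tmap_export(glm)
    V = cohort.template.n_vertices
    np.testing.assert_array_equal(out["ipsi"].values[out["ipsi"].mask],
                                  glm.t[:V][out["ipsi"].mask])
    assert np.isnan(out["contra"].values[~out["contra"].mask]).all()
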