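"""Shared fixtures: small templates, cached synthetic cohorts, and the
standard analysis chain used by the statistical tests."""
from __future__ import annotations

import numpy as np
import pytest

from epihs.harmonization import (FeatureMatrix, flip_to_lesion_frame,
                                 zscore_vs_controls)
from epihs.pipeline import smooth_feature_stack
from epihs.synthetic_cohort import CohortSpec, build_template, generate_cohort
from epihs.vertex_stats import (AnalysisDomain, _tile_mask, build_design,
                                estimate_resels, fit_glm, rft_cluster_correct)


@pytest.fixture(scope="session")
def template3():
    """Level-3 (642 vertices/hemisphere) template, 20 mm white radius."""
    return build_template(3, 20.0)


@pytest.fixture(scope="session")
def template4():
    """Level-4 (2562 vertices/hemisphere) template at the default radius."""
    return build_template(4, 49.0)


@pytest.fixture(scope="session")
def domain4(template4):
    return AnalysisDomain(template4.left)


@pytest.fixture(scope="session")
def full_cohort(tmp_path_factory):
    """Small full-fidelity cohort (volumes + masks on disk), 2 x 2 subjects."""
    out = tmp_path_factory.mktemp("full_cohort")
    spec = CohortSpec(n_patients=2, n_controls=2, template_level=3,
                      template_radius=20.0, seed=7)
    return generate_cohort(spec, out_dir=out, fidelity="full")


def analyze_feature(cohort, feature: str, smoothing_fwhm: float = 10.0,
                    domain: AnalysisDomain | None = None):
    """The pipeline's statistical chain for one feature of a fast cohort:
    smooth, z-score vs controls, flip to lesion frame, GLM, resels, RFT."""
    V = cohort.template.n_vertices
    Y = smooth_feature_stack(cohort.features[feature], cohort.template,
                             smoothing_fwhm)
    fm = FeatureMatrix(Y, list(cohort.meta.id), feature, np.ones(V, bool))
    fm = zscore_vs_controls(fm, cohort.control_ids)
    fm = flip_to_lesion_frame(
        fm, dict(zip(cohort.meta.id, cohort.meta.lesion_side)))
    design = build_design(cohort.meta)
    glm = fit_glm(fm, design, design.contrast("group"))
    if domain is None:
        domain = AnalysisDomain(cohort.template.left)
    resels = estimate_resels(glm.residuals, domain, _tile_mask(fm))
    clusters = rft_cluster_correct(glm, resels, domain)
    return fm, glm, resels, clusters


def best_dice(clusters, truth, direction: str, alpha: float = 0.05) -> float:
    """Best Dice overlap of a significant cluster with the planted region."""
    best = 0.0
    for c in clusters:
        if c.direction != direction or c.p_fwe >= alpha:
            continue
        inter = len(np.intersect1d(c.vertices, truth))
        best = max(best, 2.0 * inter / (len(c.vertices) + len(truth)))
    return best
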