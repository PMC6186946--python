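"""Full-fidelity feature-extraction demonstration.

Voxelises T1/FLAIR volumes and hippocampal masks for a four-subject cohort
(level-3 template so the volumes stay small), runs the per-vertex feature
chain -- thickness, gray-white contrast, normalized FLAIR -- and reports how
well the extraction recovers what the generator planted.
"""
import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> int:
    from epihs.features import extract_subject_features
    from epihs.surface_core import SmoothingKernelSpec, SmoothingOperator
    from epihs.synthetic_cohort import CohortSpec, generate_cohort

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "cohort_full"
    spec = CohortSpec(n_patients=2, n_controls=2, template_level=3,
                      template_radius=20.0, seed=7)
    cohort = generate_cohort(spec, out_dir=out, fidelity="full")
    V = cohort.template.n_vertices
    spec10 = SmoothingKernelSpec.for_surface(cohort.template.left, 10.0)
    op = SmoothingOperator(cohort.template.left, spec10)

    summary = {}
    for i, sid in enumerate(cohort.meta.id):
        feats = extract_subject_features(out / sid)
        prov = json.loads((out / sid / "features_provenance.json")
                          .read_text())
        planted = np.clip(cohort.features["thickness"][i, :V], 2.0, 6.0)
        err = float(np.nanmax(np.abs(feats["thickness"]["left"].values
                                     - op.apply(planted))))
        summary[sid] = {"gm_peak": round(prov["gm_peak"], 2),
                        "boundary": round(prov["boundary"], 2),
                        "thickness_max_err_mm": round(err, 4)}
        print(f"{sid}: GMpeak={prov['gm_peak']:6.2f} B={prov['boundary']:6.2f} "
              f"(planted 120/80); thickness recovery err {err:.3f} mm")
    (RESULTS / "features_demo.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    print("wrote results/features_demo.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
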