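"""Pipeline orchestration: simulate -> features -> harmonize -> stats ->
hippocampus -> clinical -> report, with a manifest and structured logging.

Every stage's parameters default to the study's published values (sampling
depths 0.30/0.50/1 mm, 10 mm smoothing, CDT p = 0.025, alpha = 0.05, age and
ICV covariates); all defaults are echoed into the run log. One failing
subject does not abort the cohort.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import hippocampus as hq
from .features import FlairNormalizationContext, extract_subject_features
from .harmonization import (FeatureMatrix, flip_to_lesion_frame,
                            save_feature_matrix, zscore_vs_controls)
from .surface_core import (SmoothingKernelSpec, SmoothingOperator,
                           read_volume, write_vertex_map)
from .synthetic_cohort import (Cohort, CohortSpec, EffectSpec, FEATURES,
                               default_effects, generate_cohort)
from .vertex_stats import (AnalysisDomain, _tile_mask, build_design,
                           cluster_cohens_d, estimate_resels, fit_glm,
                           permutation_cluster_test, rft_cluster_correct,
                           uncorrected_tmap_export)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place (YAML-serialisable)."""

    out_dir: str = "run"
    seed: int = 0
    fidelity: str = "fast"               # 'fast' | 'full'
    gm_depth: float = 0.30
    flair_depth: float = 0.50
    wm_offset_mm: float = 1.0
    smoothing_fwhm_mm: float = 10.0
    gwc_variant: str = "ratio"
    histogram_bins: int = 100
    cdt_p: float = 0.025
    alpha: float = 0.05
    n_perm: int = 0                      # 0 skips the permutation oracle
    control_flip_policy: str = "as-is"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: list[EffectSpec] = field(default_factory=default_effects)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "effects" in raw:
            raw["effects"] = [EffectSpec(**e) for e in raw["effects"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Run directory bookkeeping: JSON-lines log + file manifest."""

    def __init__(self, out_dir: Path):
        self.dir = out_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.log_path = self.dir / "log.jsonl"
        self.log_path.write_text("")

    def log(self, stage: str, **info) -> None:
        with self.log_path.open("a") as f:
            f.write(json.dumps({"stage": stage, **info}, sort_keys=True,
                               default=str) + "\n")

    def register(self, *paths: Path) -> None:
        self.files.extend(paths)

    def write_json(self, name: str, payload) -> Path:
        p = self.dir / name
        p.write_text(json.dumps(payload, indent=1, sort_keys=True,
                                default=str))
        self.register(p)
        return p

    def finish(self, status: str) -> None:
        manifest = {str(p.relative_to(self.dir)): _sha256(p)
                    for p in sorted(set(self.files)) if p.is_file()}
        (self.dir / "manifest.json").write_text(
            json.dumps({"status": status, "files": manifest}, indent=1,
                       sort_keys=True))


def _full_path_features(cohort: Cohort, config: PipelineConfig, run: _Run,
                        ) -> tuple[dict, list[str], pd.DataFrame]:
    """Extract features from volumes per subject; tolerate failures."""
    maps_by_subject: dict[str, dict] = {}
    failed: list[str] = []
    hippo_rows = []
    for _, row in cohort.meta.iterrows():
        sub_dir = cohort.out_dir / row.id
        try:
            feats = extract_subject_features(
                sub_dir, smoothing_fwhm_mm=config.smoothing_fwhm_mm,
                gwc_variant=config.gwc_variant,
                histogram_bins=config.histogram_bins)
            maps_by_subject[row.id] = feats
            prov = json.loads(
                (sub_dir / "features_provenance.json").read_text())
            ctx = FlairNormalizationContext(prov["gm_peak"],
                                            prov["boundary"])
            flair = read_volume(sub_dir / "FLAIR.nii.gz")
            for side in ("left", "right"):
                mask = read_volume(sub_dir / f"hippo_{side}.nii.gz")
                hippo_rows.append(dict(
                    id=row.id, side=side,
                    volume_mm3=hq.hippo_volume(mask),
                    mean_ri=hq.hippo_flair(mask, flair, ctx),
                    icv_mm3=row.icv_mm3))
        except Exception as exc:  # noqa: BLE001 - per-subject containment
            failed.append(row.id)
            run.log("features", subject=row.id, status="failed",
                    error=str(exc))
    return maps_by_subject, failed, pd.DataFrame(hippo_rows)


_SMOOTH_CACHE: dict = {}


def smooth_feature_stack(data: np.ndarray, template, fwhm_mm: float,
                         ) -> np.ndarray:
    """Apply the per-feature surface smoothing to an (n, 2V) map stack.

    This is the smoothing the feature-extraction stage applies to each
    subject map; the fast simulation path emits unsmoothed maps, so the
    pipeline applies it here (cached operator per template/FWHM).
    """
    if fwhm_mm == 0:
        return data.copy()
    key = (id(template.left), fwhm_mm)
    op = _SMOOTH_CACHE.get(key)
    if op is None:
        spec = SmoothingKernelSpec.for_surface(template.left, fwhm_mm)
        op = SmoothingOperator(template.left, spec)
        _SMOOTH_CACHE[key] = op
    V = template.n_vertices
    out = np.empty_like(data)
    out[:, :V] = op.apply(data[:, :V].T).T
    out[:, V:] = op.apply(data[:, V:].T).T
    return out


def _cluster_table(clusters) -> pd.DataFrame:
    rows = []
    for k, cl in enumerate(clusters):
        rows.append(dict(cluster_id=k, direction=cl.direction,
                         n_vertices=len(cl.vertices),
                         peak_t=round(cl.peak_t, 4),
                         area_mm2=round(cl.area_mm2, 1),
                         extent_resels=round(cl.extent_resels, 4),
                         p_fwe=cl.p_fwe,
                         p_perm=cl.p_perm,
                         cohen_d=cl.cohen_d))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, post_simulate_hook=None) -> dict:
    """Run all stages; returns a results dict and populates the run dir.

    ``post_simulate_hook(cohort)``, if given, runs between simulation and
    feature extraction (instrumentation / fault-injection seam).
    """
    run = _Run(Path(config.out_dir))
    run.log("config", **{k: v for k, v in config.to_dict().items()
                         if k not in ("cohort", "effects")})
    run.log("config.cohort", **dataclasses.asdict(config.cohort))
    t0 = time.time()
    results: dict = {}

    # --- simulate ---------------------------------------------------------
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    cohort_dir = run.dir / "cohort"
    cohort = generate_cohort(spec, config.effects, out_dir=cohort_dir,
                             fidelity=config.fidelity)
    run.register(*cohort_dir.rglob("*"))
    run.log("simulate", n_subjects=cohort.n_subjects,
            fidelity=config.fidelity, seconds=round(time.time() - t0, 2))
    results["cohort"] = cohort
    meta = cohort.meta
    if post_simulate_hook is not None:
        post_simulate_hook(cohort)

    # --- features ---------------------------------------------------------
    V = cohort.template.n_vertices
    if config.fidelity == "full":
        maps_by_subject, failed, hippo_measures = _full_path_features(
            cohort, config, run)
        keep = [s for s in meta.id if s not in failed]
        meta = meta[meta.id.isin(keep)].reset_index(drop=True)
        feature_data = {}
        for feat in FEATURES:
            rows = []
            for sid in meta.id:
                m = maps_by_subject[sid]
                fkey = feat if feat in m else {"flair_ri": "flair_ri"}[feat]
                rows.append(np.concatenate([m[fkey]["left"].values,
                                            m[fkey]["right"].values]))
            feature_data[feat] = np.vstack(rows)
        run.register(*cohort_dir.rglob("feat_*.mgh"))
        run.log("features", n_failed=len(failed),
                n_subjects=len(meta), failed=failed)
    else:
        feature_data = {feat: smooth_feature_stack(
            Y, cohort.template, config.smoothing_fwhm_mm)
            for feat, Y in cohort.features.items()}
        hippo_measures = cohort.hippo
        run.log("features", path="fast", n_subjects=len(meta),
                smoothing_fwhm_mm=config.smoothing_fwhm_mm)
    results["meta"] = meta

    # --- harmonize --------------------------------------------------------
    control_ids = list(meta.loc[meta.group == "control", "id"])
    lesion = dict(zip(meta.id, meta.lesion_side))
    matrices: dict[str, FeatureMatrix] = {}
    for feat, data in feature_data.items():
        fm = FeatureMatrix(data, list(meta.id), feat,
                           np.all(np.isfinite(data), axis=0)[:V]
                           & np.all(np.isfinite(data), axis=0)[V:])
        fm = zscore_vs_controls(fm, control_ids)
        fm = flip_to_lesion_frame(fm, lesion,
                                  control_policy=config.control_flip_policy,
                                  seed=config.seed)
        matrices[feat] = fm
        p = run.dir / f"matrix_{feat}.h5"
        save_feature_matrix(fm, p)
        run.register(p, p.with_suffix(".h5.json"))
    run.log("harmonize", control_policy=config.control_flip_policy,
            n_flipped=sum(matrices[FEATURES[0]].flip_log.values()))
    results["matrices"] = matrices

    # --- vertex stats -----------------------------------------------------
    domain = AnalysisDomain(cohort.template.left)
    design = build_design(meta)
    contrast = design.contrast("group")
    patient_ids = list(meta.loc[meta.group == "patient", "id"])
    results["clusters"] = {}
    results["glm"] = {}
    for feat, fm in matrices.items():
        glm = fit_glm(fm, design, contrast)
        resels = estimate_resels(glm.residuals, domain, _tile_mask(fm))
        if config.n_perm > 0:
            clusters = permutation_cluster_test(
                fm, design, contrast, domain, cdt_p=config.cdt_p,
                n_perm=config.n_perm, seed=config.seed)
        else:
            clusters = rft_cluster_correct(glm, resels, domain,
                                           cdt_p=config.cdt_p,
                                           alpha=config.alpha)
        for cl in clusters:
            cl.cohen_d = cluster_cohens_d(fm, patient_ids, cl.vertices)
        tbl = _cluster_table(clusters)
        p = run.dir / f"clusters_{feat}.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        run.register(p)
        for name, vm in uncorrected_tmap_export(glm).items():
            mp = run.dir / f"tmap_{feat}_{name}.mgh"
            write_vertex_map(vm, mp)
            run.register(mp)
        results["clusters"][feat] = clusters
        results["glm"][feat] = glm
        run.log("stats", feature=feat, n_subjects=len(meta),
                df=glm.df, resels=round(resels.total_resels, 2),
                global_fwhm_mm=round(resels.global_fwhm_mm, 2),
                cdt_p=config.cdt_p, alpha=config.alpha,
                sidedness="both directions, one-sided CDT each",
                n_clusters=len(clusters),
                n_significant=sum(c.p_fwe < config.alpha for c in clusters))

    # --- hippocampus ------------------------------------------------------
    hippo_measures = hippo_measures[hippo_measures.id.isin(meta.id)]
    hp = run.dir / "hippocampus_measures.tsv"
    hippo_measures.to_csv(hp, sep="\t", index=False)
    run.register(hp)
    try:
        hippo_stats = {
            "group_model": hq.hippo_group_model(hippo_measures, meta),
            "paired": hq.hippo_paired_tests(hippo_measures, meta),
        }
        run.write_json("hippocampus_stats.json", hippo_stats)
        run.log("hippo", **{k: round(v["t"], 3) for k, v in
                            hippo_stats["group_model"].items()})
    except ValueError as exc:
        hippo_stats = None
        run.log("hippo", status="failed", error=str(exc))
    results["hippocampus"] = hippo_stats

    # --- clinical ---------------------------------------------------------
    clin_out: dict = {"demographics": clin.aggregate_demographics(
        _meta_to_records(meta))}
    pat = meta[meta.group == "patient"].set_index("id")
    for feat, target in (("flair_ri", "clinical_model"),
                         ("gwc", "onset_correlation")):
        clusters = [c for c in results["clusters"][feat]
                    if c.direction == ("negative" if feat == "thickness"
                                       else "positive")]
        if not clusters:
            clin_out[target] = None
            run.log("clinical", feature=feat, note="no cluster")
            continue
        best = clusters[0]            # most significant; logged either way
        fm = matrices[feat]
        means = np.nanmean(fm.data[:, best.vertices], axis=1)
        table = pat.copy()
        table[f"{feat}_cluster_mean"] = [
            means[fm.subject_ids.index(s)] for s in pat.index]
        try:
            if target == "clinical_model":
                clin_out[target] = clin.cluster_clinical_model(
                    table.assign(
                        febrile_convulsions=table.febrile_convulsions
                        .astype(float)), f"{feat}_cluster_mean")
                clin_out["blurring_flair"] = clin.blurring_subgroup_test(
                    table, f"{feat}_cluster_mean")
            else:
                clin_out[target] = clin.cluster_correlation(
                    table, "onset_years", f"{feat}_cluster_mean")
                clin_out["blurring_gwc"] = clin.blurring_subgroup_test(
                    table, f"{feat}_cluster_mean")
        except ValueError as exc:         # too few patients for the model
            clin_out[target] = None
            run.log("clinical", feature=feat, status="failed",
                    error=str(exc))
        clin_out[f"{feat}_cluster_significant"] = bool(
            best.p_fwe < config.alpha)
    run.write_json("clinical_stats.json", clin_out)
    run.log("clinical", done=True)
    results["clinical"] = clin_out

    run.log("pipeline", seconds=round(time.time() - t0, 2), status="complete")
    run.finish("complete")
    make_report(run.dir)
    return results


def _meta_to_records(meta: pd.DataFrame) -> list[clin.SubjectRecord]:
    recs = []
    for _, r in meta.iterrows():
        recs.append(clin.SubjectRecord(
            id=r.id, group=r.group, age_years=r.age_years, sex=r.sex,
            lesion_side=r.lesion_side,
            onset_years=None if pd.isna(r.onset_years) else r.onset_years,
            duration_years=(None if pd.isna(r.duration_years)
                            else r.duration_years),
            febrile_convulsions=bool(r.febrile_convulsions),
            radiological_blurring=bool(r.radiological_blurring),
            surgery=bool(r.surgery), icv_mm3=r.icv_mm3))
    return recs


def make_report(run_dir: str | Path) -> Path:
    """Compose a plain-markdown summary referencing only manifest files.

    Regeneration is idempotent; missing stages are marked absent rather
    than failing the report.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"files": {}})
    files = set(manifest.get("files", {}))
    lines = ["# Synthetic cohort analysis report", ""]

    def section(title: str, name: str, render) -> None:
        lines.append(f"## {title}")
        p = run_dir / name
        if name not in files or not p.exists():
            lines.append("_section absent_")
        else:
            render(p)
            lines.append(f"(source: `{name}`)")
        lines.append("")

    def render_clinical(p: Path) -> None:
        d = json.loads(p.read_text())
        demo = d.get("demographics", {})
        lines.append(f"- patients: {demo.get('n_patients')}, controls: "
                     f"{demo.get('n_controls')}")
        am = demo.get("age_mean")
        lines.append(f"- patient age mean: "
                     f"{am:.2f}" if am is not None else "- age absent")
        if d.get("clinical_model"):
            fc = d["clinical_model"]["terms"].get("febrile_convulsions", {})
            lines.append(f"- FC term on cluster FLAIR: t = "
                         f"{fc.get('t', float('nan')):.2f}, two-sided p = "
                         f"{fc.get('p_two_sided', float('nan')):.3f}")

    def render_hippo(p: Path) -> None:
        d = json.loads(p.read_text())
        for k, v in d.get("group_model", {}).items():
            lines.append(f"- {k}: t = {v['t']:.2f}, p = {v['p']:.4f}")

    section("Demographics and clinical models", "clinical_stats.json",
            render_clinical)
    section("Hippocampal quantification", "hippocampus_stats.json",
            render_hippo)

    lines.append("## Cluster tables")
    any_tbl = False
    for f in sorted(files):
        if f.startswith("clusters_") and f.endswith(".tsv"):
            any_tbl = True
            feat = f[len("clusters_"):-len(".tsv")]
            tbl = pd.read_csv(run_dir / f, sep="\t")
            n_sig = int((tbl.p_fwe < 0.05).sum()) if len(tbl) else 0
            lines.append(f"- {feat}: {len(tbl)} clusters, {n_sig} "
                         f"FWE-significant (`{f}`)")
    if not any_tbl:
        lines.append("_section absent_")
    lines.append("")
    lines.append("## Uncorrected t maps")
    tmaps = [f for f in sorted(files) if f.startswith("tmap_")]
    lines += ([f"- `{f}`" for f in tmaps] or ["_section absent_"])
    lines.append("")
    lines.append("## Parameters")
    log_path = run_dir / "log.jsonl"
    if log_path.exists():
        for line in log_path.read_text().splitlines():
            rec = json.loads(line)
            if rec.get("stage") == "config":
                for k in sorted(rec):
                    if k != "stage":
                        lines.append(f"- {k}: {rec[k]}")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
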