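"""End-to-end orchestration: synth -> aggregate -> correct -> agree ->
curves -> survival, writing every stage output as CSV into a run
directory together with a manifest and an exclusions log."""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from .aggregation import aggregate_cores, aggregate_patients, filter_central_segments
from .agreement import agreement_table
from .config import PipelineConfig
from .correction import correct_all
from .rater_curves import accuracy_curve
from .survival import cox_fit, km_estimate, logrank_test, median_split, split_quartiles
from .synthetic import (
    RaterModel,
    SurvivalModel,
    core_map_frame,
    generate_classifications,
    generate_cores,
    generate_expert_scores,
    generate_survival,
    patient_true_h,
    truth_frame,
)
from . import domain

log = logging.getLogger("crowdscore")

MANIFEST = "manifest.json"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sub_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _path(out_dir: str, name: str) -> str:
    return os.path.join(out_dir, name)


def _record(manifest: dict, stage: str, t0: float, **counts) -> None:
    manifest["stages"][stage] = {
        "wall_seconds": round(time.perf_counter() - t0, 3),
        **counts,
    }
    log.info("stage %s: %s", stage, counts)


def stage_synth(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    s_cores, s_class, s_expert, s_surv = _sub_seeds(cfg.seed, 4)
    cores = generate_cores(
        cfg.n_patients, cfg.cores_per_patient, marker_id=cfg.marker_id,
        seed=s_cores,
    )
    rater = RaterModel(
        p_miss_cancer=cfg.p_miss_cancer,
        p_false_cancer=cfg.p_false_cancer,
        proportion_noise_sd=cfg.proportion_noise_sd,
        intensity_noise_sd=cfg.intensity_noise_sd,
    )
    classifications = generate_classifications(
        cores,
        raters_per_segment=cfg.raters_per_segment,
        rater_model=rater,
        scheme=cfg.scheme,
        central_only=cfg.central_only,
        seed=s_class,
    )
    experts = generate_expert_scores(
        cores, cfg.expert_fraction, cfg.expert_noise_sd, seed=s_expert
    )
    surv_model = SurvivalModel(
        baseline_rate=cfg.baseline_rate,
        beta_h=cfg.beta_h,
        censor_rate=cfg.censor_rate,
    )
    patients = generate_survival(patient_true_h(cores), surv_model, seed=s_surv)

    domain.write_classifications_frame(
        classifications, _path(out_dir, "classifications.csv")
    )
    experts.to_csv(_path(out_dir, "expert_scores.csv"), index=False)
    core_map_frame(cores).to_csv(_path(out_dir, "core_map.csv"), index=False)
    out_patients = patients.copy()
    out_patients["event"] = np.where(out_patients["event"], "true", "false")
    out_patients["hydronephrosis"] = np.where(
        out_patients["hydronephrosis"], "true", "false"
    )
    out_patients.to_csv(_path(out_dir, "patients.csv"), index=False)
    truth_frame(cores).to_csv(_path(out_dir, "truth.csv"), index=False)
    _record(
        manifest, "synth", t0,
        n_cores=len(cores),
        n_classifications=len(classifications),
        n_expert_scores=len(experts),
        n_patients=len(patients),
    )


def stage_aggregate(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    classifications = domain.read_classifications_frame(
        _path(out_dir, "classifications.csv")
    )
    core_map = pd.read_csv(_path(out_dir, "core_map.csv"), dtype=str)
    if cfg.central_only:
        classifications = filter_central_segments(classifications)
    scores = aggregate_cores(classifications, cfg.scheme)
    scores = scores.drop(columns="marker_id").merge(
        core_map[["core_id", "marker_id"]], on="core_id", how="left"
    )

    # usable-core threshold: min raters per scored segment
    seg_counts = classifications.groupby("core_id")["segment_index"].nunique()
    needed = seg_counts * cfg.min_raters_per_segment
    usable = scores.set_index("core_id")["n_responses"] >= needed
    excluded = usable.index[~usable.reindex(scores["core_id"]).to_numpy()]
    if len(excluded):
        pd.DataFrame(
            {"core_id": sorted(set(excluded)), "reason": "below_min_responses"}
        ).to_csv(_path(out_dir, "exclusions.csv"), index=False)
    else:
        pd.DataFrame(columns=["core_id", "reason"]).to_csv(
            _path(out_dir, "exclusions.csv"), index=False
        )
    scores = scores[usable.reindex(scores["core_id"]).to_numpy()]
    out = scores[
        [
            "core_id", "marker_id", "proportion", "intensity", "n_responses",
            "n_cancer_responses", "n_intensity_responses", "all_no_cancer",
        ]
    ].copy()
    out["all_no_cancer"] = np.where(out["all_no_cancer"], "true", "false")
    out.to_csv(_path(out_dir, "core_scores.csv"), index=False)
    _record(
        manifest, "aggregate", t0,
        n_cores_in=int(classifications["core_id"].nunique()),
        n_cores_out=len(scores),
        n_excluded=int(len(set(excluded))),
    )


def _read_core_scores(out_dir: str) -> pd.DataFrame:
    scores = pd.read_csv(
        _path(out_dir, "core_scores.csv"), dtype={"core_id": str, "marker_id": str}
    )
    scores["all_no_cancer"] = scores["all_no_cancer"].astype(str).str.lower() == "true"
    return scores


def _read_experts(out_dir: str) -> pd.DataFrame:
    path = _path(out_dir, "expert_scores.csv")
    if not os.path.exists(path):
        raise FileNotFoundError(
            "expert_scores.csv not found: the correction stage needs expert "
            "gold-standard scores (run synth, or supply the file)"
        )
    return pd.read_csv(path, dtype={"core_id": str, "marker_id": str})


def stage_correct(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    scores = _read_core_scores(out_dir)
    experts = _read_experts(out_dir)
    corrected = correct_all(scores, experts, k_folds=cfg.k_folds, seed=cfg.seed)
    out = corrected.copy()
    for col in ("clipped_proportion", "clipped_intensity", "was_cv"):
        out[col] = np.where(out[col], "true", "false")
    out.to_csv(_path(out_dir, "corrected_scores.csv"), index=False)

    core_map = pd.read_csv(_path(out_dir, "core_map.csv"), dtype=str)
    patient_scores = aggregate_patients(corrected, core_map)
    patient_scores.to_csv(_path(out_dir, "patient_scores.csv"), index=False)
    _record(
        manifest, "correct", t0,
        n_cores=len(corrected),
        n_cv_corrected=int(corrected["was_cv"].sum()),
        n_patients=len(patient_scores),
    )


def _read_corrected(out_dir: str) -> pd.DataFrame:
    corrected = pd.read_csv(
        _path(out_dir, "corrected_scores.csv"),
        dtype={"core_id": str, "marker_id": str},
    )
    for col in ("clipped_proportion", "clipped_intensity", "was_cv"):
        corrected[col] = corrected[col].astype(str).str.lower() == "true"
    return corrected


def stage_agree(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    corrected = _read_corrected(out_dir)
    experts = _read_experts(out_dir)
    table = agreement_table(
        corrected, experts, n_boot=cfg.n_boot, seed=cfg.seed
    )
    table.to_csv(_path(out_dir, "agreement.csv"), index=False)
    _record(manifest, "agree", t0, n_rows=len(table))


def stage_curves(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    classifications = domain.read_classifications_frame(
        _path(out_dir, "classifications.csv")
    )
    experts = _read_experts(out_dir)
    curve = accuracy_curve(
        classifications,
        experts,
        scheme=cfg.scheme,
        n_values=cfg.curve_n_values,
        n_boot=cfg.curve_n_boot,
        seed=cfg.seed,
        k_folds=cfg.k_folds,
        marker_id=cfg.marker_id,
    )
    curve.to_csv(_path(out_dir, "curve.csv"), index=False)
    _record(manifest, "curves", t0, n_rows=len(curve))


def stage_survival(cfg: PipelineConfig, out_dir: str, manifest: dict) -> None:
    t0 = time.perf_counter()
    patients = pd.read_csv(
        _path(out_dir, "patients.csv"), dtype={"patient_id": str}
    )
    patients["event"] = patients["event"].astype(str).str.lower() == "true"
    patients["hydronephrosis"] = (
        patients["hydronephrosis"].astype(str).str.lower() == "true"
    )
    scores = pd.read_csv(
        _path(out_dir, "patient_scores.csv"),
        dtype={"patient_id": str, "marker_id": str},
    )
    rows = []
    km_rows = []
    for marker, marker_scores in scores.groupby("marker_id", sort=True):
        merged = patients.merge(
            marker_scores[["patient_id", "h_score"]], on="patient_id",
            how="inner",
        )
        merged["quartile"] = split_quartiles(merged["h_score"].to_numpy())
        merged["median_group"] = median_split(merged["h_score"].to_numpy())
        cohorts = ["combined"] + sorted(merged["cohort"].unique())
        for cohort in cohorts:
            sub = merged if cohort == "combined" else merged[
                merged["cohort"] == cohort
            ]
            try:
                res = cox_fit(
                    sub[["h_score"]], sub["time_months"], sub["event"]
                )
            except (ValueError, RuntimeError) as exc:
                log.warning("cox skipped for %s/%s: %s", marker, cohort, exc)
                continue
            frame = res.to_frame()
            frame.insert(0, "model", "univariable")
            frame.insert(0, "marker", marker)
            frame.insert(0, "cohort", cohort)
            rows.append(frame)
        if cfg.multivariable:
            multi = merged
            if cfg.exclude_cystectomy_multivariable:
                multi = merged[merged["cohort"] != "cystectomy"]
            design = multi[["h_score", "age", "t_stage", "n_stage", "grade"]].copy()
            design["sex_male"] = (multi["sex"] == "M").astype(float)
            design["hydronephrosis"] = multi["hydronephrosis"].astype(float)
            try:
                res = cox_fit(design, multi["time_months"], multi["event"])
                frame = res.to_frame()
                frame.insert(0, "model", "multivariable")
                frame.insert(0, "marker", marker)
                frame.insert(0, "cohort", "combined_rt")
                rows.append(frame)
            except (ValueError, RuntimeError) as exc:
                log.warning("multivariable cox skipped for %s: %s", marker, exc)
        # KM by median split on the combined cohorts
        for label in ("low", "high"):
            grp = merged[merged["median_group"] == label]
            if grp.empty:
                continue
            km = km_estimate(grp["time_months"], grp["event"])
            km.insert(0, "group", label)
            km.insert(0, "marker", marker)
            km_rows.append(km)
    if not rows:
        raise ValueError("no Cox model could be fitted on any cohort")
    cox_out = pd.concat(rows, ignore_index=True)
    cox_out.to_csv(_path(out_dir, "cox_results.csv"), index=False)
    pd.concat(km_rows, ignore_index=True).to_csv(
        _path(out_dir, "km_curves.csv"), index=False
    )
    _record(
        manifest, "survival", t0,
        n_cox_rows=len(cox_out),
        n_km_rows=sum(len(k) for k in km_rows),
    )


STAGES = {
    "synth": stage_synth,
    "aggregate": stage_aggregate,
    "correct": stage_correct,
    "agree": stage_agree,
    "curves": stage_curves,
    "survival": stage_survival,
}


def run_pipeline(
    cfg: PipelineConfig, out_dir: str, stages: list[str] | None = None
) -> dict:
    """Run the requested stages (default: all, curves only if configured).

    Returns the manifest dict, which is also written to manifest.json.
    """
    os.makedirs(out_dir, exist_ok=True)
    if stages is None:
        stages = ["synth", "aggregate", "correct", "agree"]
        if cfg.run_curves:
            stages.append("curves")
        stages.append("survival")
    manifest = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": {}}
    manifest_path = _path(out_dir, MANIFEST)
    if os.path.exists(manifest_path):
        with open(manifest_path, encoding="utf-8") as fh:
            prior = json.load(fh)
        if prior.get("config_hash") == manifest["config_hash"]:
            manifest["stages"].update(prior.get("stages", {}))
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage: {stage}")
        try:
            STAGES[stage](cfg, out_dir, manifest)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest
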