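"""End-to-end pipeline driver.

simulate -> GLM -> topography -> Jaccard -> RSA -> questionnaire scores ->
permutation statistics, with every result written as TSV (plus GIFTI for
surfaces/maps) and a config snapshot next to the outputs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as smio
from .config import PipelineConfig
from .exceptions import EmptyWinnerError, SomatomapError
from .glm import ActivationMap, GlmResult, average_runs, build_design_matrix, fit_glm
from .overlap import cross_group_similarity
from .phantom import cohort_demographics, score_table
from .rsa import classical_mds, crossnobis_rdm, estimate_noise_cov, mean_dissimilarity
from .stats import flag_outliers, perm_group_diff, perm_interaction_test
from .synthetic import CohortBundle, generate_cohort
from .topography import (WinnerMap, coverage_and_laterality,
                         signed_distance_to_anchor, weighted_cog,
                         winner_takes_all)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "topography", "jaccard", "rsa", "scores", "stats")


@dataclass
class PipelineReport:
    """In-memory bundle of every pipeline product."""

    cohort: CohortBundle
    activation: Dict[str, Dict[str, Dict[str, ActivationMap]]] = field(default_factory=dict)
    glm_results: Dict[str, Dict[str, List[GlmResult]]] = field(default_factory=dict)
    winner_maps: Dict[str, Dict[str, WinnerMap]] = field(default_factory=dict)
    hand_winner_maps: Dict[str, Dict[str, WinnerMap]] = field(default_factory=dict)
    distances: Optional[pd.DataFrame] = None
    laterality: Optional[pd.DataFrame] = None
    jaccard: Optional[pd.DataFrame] = None
    rdms: Optional[pd.DataFrame] = None
    mds: Optional[pd.DataFrame] = None
    scores: Optional[pd.DataFrame] = None
    demographics: Optional[pd.DataFrame] = None
    permutation: Optional[pd.DataFrame] = None


def _fit_subject(config: PipelineConfig, bundle: CohortBundle, subject,
                 hemisphere: str) -> List[GlmResult]:
    spec = bundle.spec
    results = []
    for run in subject.runs[hemisphere]:
        design = build_design_matrix(run.events, run.tr, run.n_volumes,
                                     conditions=spec.analysis_conditions,
                                     add_derivatives=config.glm_derivatives)
        results.append(fit_glm(run, design))
    return results


def run_pipeline(config: PipelineConfig, upto: str = "stats",
                 out_dir: Optional[str] = None) -> PipelineReport:
    """Execute the pipeline through stage ``upto`` and write its outputs.

    Any stage failure is re-raised annotated with the stage name.
    """
    if upto not in STAGES:
        raise SomatomapError(f"unknown stage {upto!r}")
    last = STAGES.index(upto)
    out = out_dir or config.out_dir
    os.makedirs(out, exist_ok=True)
    config.save(os.path.join(out, "config_snapshot.yaml"))
    log_path = os.path.join(out, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("somatomap")
    root.addHandler(handler)
    try:
        return _run(config, last, out)
    except Exception as exc:
        stage = getattr(exc, "_stage", "unknown")
        logger.error("pipeline failed in stage %s: %s", stage, exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage_guard(stage: str, exc: Exception) -> Exception:
    exc._stage = stage
    return exc


def _run(config: PipelineConfig, last: int, out: str) -> PipelineReport:
    spec = config.cohort
    face_conditions = tuple(c for c in spec.conditions if c != "thumb")

    # --- simulate ---------------------------------------------------------
    try:
        bundle = generate_cohort(spec)
    except Exception as exc:
        raise _stage_guard("simulate", exc)
    report = PipelineReport(cohort=bundle)
    smio.write_tsv(bundle.participants, os.path.join(out, "participants.tsv"))
    if config.write_gifti:
        smio.write_surface_gii(bundle.mesh, os.path.join(out, "patch.surf.gii"))
        for subj in bundle.subjects:
            for hemi, runs in subj.runs.items():
                for run in runs:
                    smio.write_run_nifti(run, os.path.join(
                        out, f"{subj.subject_id}_{hemi}_run{run.run_index}.nii.gz"))
    logger.info("simulated %d subjects", len(bundle.subjects))
    if last < 1:
        return report

    # --- glm --------------------------------------------------------------
    try:
        for subj in bundle.subjects:
            report.glm_results[subj.subject_id] = {}
            report.activation[subj.subject_id] = {}
            for hemi in spec.hemispheres:
                res = _fit_subject(config, bundle, subj, hemi)
                report.glm_results[subj.subject_id][hemi] = res
                report.activation[subj.subject_id][hemi] = average_runs(
                    res, kind=config.winner_statistic)
    except Exception as exc:
        raise _stage_guard("glm", exc)
    if last < 2:
        return report

    # --- topography -------------------------------------------------------
    mesh, rois = bundle.mesh, bundle.rois
    dist_rows, lat_rows = [], []
    try:
        for subj in bundle.subjects:
            for hemi in spec.hemispheres:
                maps = report.activation[subj.subject_id][hemi]
                wmap = winner_takes_all(maps, rois.s1_combined,
                                        threshold=config.wta_threshold,
                                        conditions=face_conditions)
                report.winner_maps.setdefault(subj.subject_id, {})[hemi] = wmap
                hand_wmap = winner_takes_all(maps, rois.hand,
                                             threshold=config.wta_threshold,
                                             conditions=face_conditions)
                report.hand_winner_maps.setdefault(subj.subject_id, {})[hemi] = hand_wmap
                if config.write_gifti:
                    smio.write_label_gii(
                        wmap, mesh.n_vertices,
                        os.path.join(out, f"{subj.subject_id}_{hemi}.label.gii"))
                for cond in face_conditions:
                    try:
                        cog = weighted_cog(wmap, mesh, cond)
                        sd = signed_distance_to_anchor(cog, rois, mesh)
                        value = sd.value * config.distance_scale
                    except EmptyWinnerError:
                        value = np.nan
                    dist_rows.append({"subject": subj.subject_id,
                                      "group": subj.group, "hemisphere": hemi,
                                      "condition": cond, "signed_distance_mm": value})
            lat = coverage_and_laterality(
                report.hand_winner_maps[subj.subject_id]["deprived"],
                report.hand_winner_maps[subj.subject_id]["intact"],
                mesh, rois.hand)
            for cond, li in lat.items():
                lat_rows.append({"subject": subj.subject_id, "group": subj.group,
                                 "condition": cond,
                                 "deprived_pct": li.deprived_pct,
                                 "intact_pct": li.intact_pct,
                                 "laterality_index": li.value,
                                 "degenerate": li.degenerate})
    except Exception as exc:
        raise _stage_guard("topography", exc)

    report.distances = pd.DataFrame(dist_rows)
    # outliers flagged per group x hemisphere x condition, never removed
    report.distances["outlier"] = False
    for _, idx in report.distances.groupby(["group", "hemisphere", "condition"]).groups.items():
        vals = report.distances.loc[idx, "signed_distance_mm"].to_numpy()
        if np.isfinite(vals).all() and len(vals) >= 3:
            report.distances.loc[idx, "outlier"] = flag_outliers(vals)
    report.laterality = pd.DataFrame(lat_rows)
    smio.write_tsv(report.distances, os.path.join(out, "distances.tsv"))
    smio.write_tsv(report.laterality, os.path.join(out, "laterality.tsv"))
    if last < 3:
        return report

    # --- jaccard ----------------------------------------------------------
    jac_rows = []
    try:
        groups_present = [g for g, n in spec.groups.items() if n > 0]
        for subj in bundle.subjects:
            for hemi in spec.hemispheres:
                for ref_group in groups_present:
                    ref_maps = {s.subject_id: report.winner_maps[s.subject_id][hemi]
                                for s in bundle.by_group(ref_group)}
                    if subj.group == ref_group and len(ref_maps) < 2:
                        continue
                    for cond in face_conditions:
                        res = cross_group_similarity(
                            subj.subject_id,
                            report.winner_maps[subj.subject_id][hemi],
                            ref_maps, cond, leave_self_out=True)
                        jac_rows.append({"target_subject": subj.subject_id,
                                         "target_group": subj.group,
                                         "reference_group": ref_group,
                                         "hemisphere": hemi, "condition": cond,
                                         **res})
    except Exception as exc:
        raise _stage_guard("jaccard", exc)
    report.jaccard = pd.DataFrame(jac_rows)
    smio.write_tsv(report.jaccard, os.path.join(out, "jaccard.tsv"))
    if last < 4:
        return report

    # --- rsa --------------------------------------------------------------
    rdm_rows, mds_rows = [], []
    try:
        for subj in bundle.subjects:
            for hemi in spec.hemispheres:
                res = report.glm_results[subj.subject_id][hemi]
                conds = list(res[0].conditions)
                # thumb has no controllable analogue for one-handers
                if subj.group == "one_handers" and "thumb" in conds:
                    keep = [i for i, c in enumerate(conds) if c != "thumb"]
                    conds = [conds[i] for i in keep]
                else:
                    keep = list(range(len(conds)))
                for roi_label, roi in (("hand", rois.hand_trimmed),
                                       ("face", rois.face_trimmed)):
                    cov = estimate_noise_cov(
                        [r.residuals[:, roi] for r in res], lam=config.rsa_lambda)
                    rdm = crossnobis_rdm(
                        [r.betas[np.ix_(keep, roi)] for r in res], cov,
                        conditions=conds, roi_label=roi_label,
                        subject_id=subj.subject_id, hemisphere=hemi)
                    for a, b, v in rdm.to_long():
                        rdm_rows.append({"subject": subj.subject_id,
                                         "group": subj.group, "hemisphere": hemi,
                                         "roi": roi_label, "cond_a": a,
                                         "cond_b": b, "distance": v})
                    coords = classical_mds(rdm, k=2)
                    for c, (x, y) in zip(rdm.conditions, coords):
                        mds_rows.append({"subject": subj.subject_id,
                                         "group": subj.group, "hemisphere": hemi,
                                         "roi": roi_label, "condition": c,
                                         "mds_x": x, "mds_y": y})
    except Exception as exc:
        raise _stage_guard("rsa", exc)
    report.rdms = pd.DataFrame(rdm_rows)
    report.mds = pd.DataFrame(mds_rows)
    smio.write_tsv(report.rdms, os.path.join(out, "rdms.tsv"))
    smio.write_tsv(report.mds, os.path.join(out, "mds.tsv"))
    if last < 5:
        return report

    # --- scores -----------------------------------------------------------
    try:
        amp_rows = bundle.participants[bundle.participants["Group"] == "amputees"]
        report.scores = score_table(amp_rows) if len(amp_rows) else pd.DataFrame()
        report.demographics = cohort_demographics(bundle.participants)
    except Exception as exc:
        raise _stage_guard("scores", exc)
    if len(report.scores):
        smio.write_tsv(report.scores, os.path.join(out, "scores.tsv"))
    smio.write_tsv(report.demographics, os.path.join(out, "demographics.tsv"))
    if last < 6:
        return report

    # --- stats ------------------------------------------------------------
    perm_rows = []
    try:
        dist = report.distances.dropna(subset=["signed_distance_mm"])
        test_groups = [g for g in ("amputees", "one_handers")
                       if spec.groups.get(g, 0) >= 2]
        if spec.groups.get("controls", 0) >= 2:
            for test_group in test_groups:
                for cond in face_conditions:
                    sub = dist[(dist.condition == cond)
                               & dist.group.isin([test_group, "controls"])]
                    wide = sub.pivot_table(index=["subject", "group"],
                                           columns="hemisphere",
                                           values="signed_distance_mm").reset_index()
                    if not {"deprived", "intact"}.issubset(wide.columns):
                        continue
                    wide = wide.dropna(subset=["deprived", "intact"])
                    counts = wide.group.value_counts()
                    if counts.get(test_group, 0) < 2 or counts.get("controls", 0) < 2:
                        continue
                    res = perm_interaction_test(
                        wide.deprived.to_numpy(), wide.intact.to_numpy(),
                        wide.group.to_numpy(), n_perm=config.n_perm,
                        seed=config.seed,
                        statistic_name=f"distance_{cond}_{test_group}_vs_controls")
                    perm_rows.append(vars(res))
                    lat = report.laterality[report.laterality.condition == cond]
                    res2 = perm_group_diff(
                        lat[lat.group == test_group].laterality_index.to_numpy(),
                        lat[lat.group == "controls"].laterality_index.to_numpy(),
                        n_perm=config.n_perm, seed=config.seed,
                        statistic_name=f"laterality_{cond}_{test_group}_vs_controls")
                    perm_rows.append(vars(res2))
    except Exception as exc:
        raise _stage_guard("stats", exc)
    report.permutation = pd.DataFrame(perm_rows)
    smio.write_tsv(report.permutation, os.path.join(out, "permutation.tsv"))

    # summary: per-group mean laterality and distances + RSA face information
    summary = (report.laterality.groupby(["group", "condition"])["laterality_index"]
               .mean().reset_index()
               .rename(columns={"laterality_index": "mean_laterality"}))
    smio.write_tsv(summary, os.path.join(out, "summary_laterality.tsv"))
    face_info = (report.rdms[(report.rdms.cond_a != "thumb")
                             & (report.rdms.cond_b != "thumb")]
                 .groupby(["group", "hemisphere", "roi"])["distance"]
                 .mean().reset_index()
                 .rename(columns={"distance": "mean_face_dissimilarity"}))
    smio.write_tsv(face_info, os.path.join(out, "summary_face_information.tsv"))
    logger.info("pipeline complete: outputs in %s", out)
    return report
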