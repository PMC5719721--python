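"""End-to-end study pipeline.

read -> register -> partition into 5-mm segment pairs -> classify -> score
-> transitions / TCFA fates -> group statistics, with per-patient exclusion
records and a reproducible run manifest.

Patients whose registered overlap is too short are skipped and recorded
(mirroring study exclusions) unless ``strict`` is set, in which case the
run aborts on the first invalid patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import (InsufficientOverlapError, PlaquekitError, ValidationError)
from .io import read_cohort, write_results
from .laps import laps_pullback
from .model import PatientStudy, Timepoint
from .morphometry import frame_morphometry
from .phenotype import Phenotype
from .registration import (PullbackPhenotypes, build_registration,
                           partition_segments)
from .stats import (add_bh_adjusted, compare_numeric, mixed_effect_group_test,
                    paired_change_p)
from .transitions import (TcfaFateResult, TransitionMatrix,
                          classify_tcfa_fates, group_phenotype_share,
                          transition_matrix)

logger = logging.getLogger("plaquekit")

# Segment-table variable families compared between groups.
_DELTA_VARS = [
    "delta_lumen_csa_mm2", "delta_eem_csa_mm2", "delta_plaque_csa_mm2",
    "delta_pav_pct", "delta_nc_lumen_arc_deg", "delta_laps",
    "delta_f_mm2", "delta_ff_mm2", "delta_nc_mm2", "delta_dc_mm2",
    "delta_f_frac", "delta_ff_frac", "delta_nc_frac", "delta_dc_frac",
]
_LEVEL_VARS = [
    "lumen_csa_mm2", "eem_csa_mm2", "plaque_csa_mm2", "pav_pct",
    "nc_lumen_arc_deg", "laps", "f_mm2", "ff_mm2", "nc_mm2", "dc_mm2",
    "f_frac", "ff_frac", "nc_frac", "dc_frac",
]


@dataclass
class StudyResult:
    frames: pd.DataFrame
    segments: pd.DataFrame
    patients: pd.DataFrame
    group_stats: pd.DataFrame
    transitions: dict[str, TransitionMatrix]
    fates: dict[str, TcfaFateResult]
    exclusions: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def result_tables(self) -> dict[str, pd.DataFrame]:
        tables = {
            "per_frame": self.frames,
            "per_segment": self.segments,
            "per_patient": self.patients,
            "group_stats": self.group_stats,
            "tcfa_fates": pd.DataFrame(
                [{"group": g, "fate": f, "count": r.counts[f]}
                 for g, r in self.fates.items() for f in r.counts]),
        }
        for g, tm in self.transitions.items():
            tables[f"transitions_{g}"] = tm.to_dataframe().reset_index(
                names="baseline_label")
        return tables

    def write(self, out_dir: str | Path) -> dict:
        return write_results(self.result_tables(), out_dir,
                             manifest_extra=self.manifest)


def _frame_rows(study: PatientStudy, cfg: AnalysisConfig,
                analyzed_span: tuple[float, float, float, float]) -> list[dict]:
    rows = []
    bl_a, bl_b, fu_a, fu_b = analyzed_span
    for tp, pb, (lo, hi) in ((Timepoint.BASELINE, study.baseline, (bl_a, bl_b)),
                             (Timepoint.FOLLOW_UP, study.follow_up, (fu_a, fu_b))):
        phen = PullbackPhenotypes.from_pullback(pb, cfg)
        for f, fp in zip(pb.frames, phen.frames):
            m = frame_morphometry(f)
            rows.append({
                "patient_id": study.patient_id,
                "group": study.group,
                "timepoint": tp.value,
                "frame_index": f.frame_index,
                "axial_position_mm": f.axial_position_mm,
                "lumen_csa_mm2": f.lumen_csa_mm2,
                "eem_csa_mm2": f.eem_csa_mm2,
                "plaque_csa_mm2": m.plaque_csa_mm2,
                "plaque_burden_frac": m.plaque_burden_frac,
                "nc_frac": m.composition_frac["NC"],
                "nc_lumen_arc_deg": f.nc_lumen_arc_deg,
                "raw_label": fp.raw_label.display,
                "confirmed_label": fp.confirmed_label.display,
                "analyzed": bool(lo - 1e-9 <= f.axial_position_mm < hi - 1e-9),
            })
    return rows


def run_study(studies: list[PatientStudy], cfg: AnalysisConfig | None = None,
              strict: bool = False, seed: int | None = None) -> StudyResult:
    """Run the full serial analysis over a cohort of patient studies."""
    cfg = cfg or AnalysisConfig()
    if not studies:
        raise ValidationError("run_study: no patients in cohort")
    seg_rows, pat_rows, frame_rows, exclusions = [], [], [], []
    for study in studies:
        try:
            regmap = build_registration(study)
            pairs = partition_segments(study, regmap, cfg)
        except InsufficientOverlapError as exc:
            logger.info("patient=%s stage=partition excluded reason=%s",
                        study.patient_id, exc.reason)
            exclusions.append({"patient_id": study.patient_id,
                               "reason": exc.reason})
            continue
        except PlaquekitError as exc:
            if strict:
                raise
            logger.warning("patient=%s stage=analysis excluded error=%s",
                           study.patient_id, exc)
            exclusions.append({"patient_id": study.patient_id,
                               "reason": str(exc)})
            continue
        logger.info("patient=%s stage=partition segments=%d",
                    study.patient_id, len(pairs))
        for p in pairs:
            seg_rows.append({"patient_id": study.patient_id,
                             "group": study.group, **p.to_record()})
        bl_laps = laps_pullback([p.baseline_laps for p in pairs])
        fu_laps = laps_pullback([p.followup_laps for p in pairs])
        pat_rows.append({
            "patient_id": study.patient_id,
            "group": study.group,
            "n_segments": len(pairs),
            "analyzed_length_mm": len(pairs) * cfg.segment_length_mm,
            "baseline_pullback_laps": bl_laps,
            "followup_pullback_laps": fu_laps,
            "delta_pullback_laps": fu_laps - bl_laps,
            "mean_delta_plaque_csa_mm2":
                float(np.mean([p.deltas["delta_plaque_csa_mm2"] for p in pairs])),
            "mean_delta_pav_pct":
                float(np.mean([p.deltas["delta_pav_pct"] for p in pairs])),
            **{k: v for k, v in study.covariates.items()},
        })
        span = (pairs[0].baseline_start_mm, pairs[-1].baseline_stop_mm,
                pairs[0].followup_start_mm, pairs[-1].followup_stop_mm)
        frame_rows.extend(_frame_rows(study, cfg, span))

    if not seg_rows:
        raise ValidationError("run_study: every patient was excluded")
    segments = pd.DataFrame(seg_rows)
    patients = pd.DataFrame(pat_rows)
    frames = pd.DataFrame(frame_rows)

    transitions = {}
    fates = {}
    for g in sorted(segments["group"].unique()):
        sub = segments[segments["group"] == g]
        transitions[g] = transition_matrix(sub)
        fates[g] = classify_tcfa_fates(sub)

    group_stats = _group_stats(segments, patients, cfg)

    manifest = {
        "software_version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": seed,
        "patients_per_group": patients.groupby("group")["patient_id"]
        .nunique().to_dict(),
        "segments_per_group": segments.groupby("group").size().to_dict(),
        "exclusions": exclusions,
    }
    return StudyResult(frames=frames, segments=segments, patients=patients,
                       group_stats=group_stats, transitions=transitions,
                       fates=fates, exclusions=exclusions, manifest=manifest)


def _group_stats(segments: pd.DataFrame, patients: pd.DataFrame,
                 cfg: AnalysisConfig) -> pd.DataFrame:
    """Group-comparison table over segment- and patient-level variables.

    Each segment-level change row carries both the plain Welch t contrast
    and the patient-random-intercept mixed-model p value (the clustering
    correction); within-group baseline-vs-follow-up p values come from
    paired t tests on the segment values.
    """
    groups = sorted(segments["group"].unique())
    rows = []
    two_groups = len(groups) == 2

    def seg_vals(g, col):
        return segments.loc[segments["group"] == g, col].to_numpy()

    for prefix in ("baseline", "followup"):
        for var in _LEVEL_VARS:
            col = f"{prefix}_{var}"
            row = {"variable": col, "level": "segment"}
            for g in groups:
                v = seg_vals(g, col)
                row[f"{g}_mean"] = float(v.mean())
                row[f"{g}_sd"] = float(v.std(ddof=1))
                row[f"{g}_n"] = int(v.size)
            if two_groups:
                cmp_res = compare_numeric(seg_vals(groups[0], col),
                                          seg_vals(groups[1], col),
                                          variable=col)
                row["test"] = cmp_res.test
                row["p_value"] = cmp_res.p_value
            rows.append(row)
    for var in _DELTA_VARS:
        row = {"variable": var, "level": "segment"}
        for g in groups:
            v = seg_vals(g, var)
            row[f"{g}_mean"] = float(v.mean())
            row[f"{g}_sd"] = float(v.std(ddof=1))
            row[f"{g}_n"] = int(v.size)
            level_var = var.replace("delta_", "")
            if f"baseline_{level_var}" in segments.columns:
                row[f"{g}_p_change"] = paired_change_p(
                    seg_vals(g, f"baseline_{level_var}"),
                    seg_vals(g, f"followup_{level_var}"))
        if two_groups:
            cmp_res = compare_numeric(seg_vals(groups[0], var),
                                      seg_vals(groups[1], var), variable=var)
            row["test"] = cmp_res.test
            row["p_value"] = cmp_res.p_value
            me = mixed_effect_group_test(
                segments.rename(columns={var: "delta"}), value_col="delta")
            row["mixed_effect_estimate"] = me.estimate
            row["mixed_effect_p"] = me.p_value
            row["mixed_effect_method"] = me.method
        rows.append(row)
    for var in ("baseline_pullback_laps", "followup_pullback_laps",
                "delta_pullback_laps"):
        row = {"variable": var, "level": "patient"}
        for g in groups:
            v = patients.loc[patients["group"] == g, var].to_numpy()
            row[f"{g}_mean"] = float(v.mean())
            row[f"{g}_sd"] = float(v.std(ddof=1))
            row[f"{g}_n"] = int(v.size)
        if two_groups:
            cmp_res = compare_numeric(
                patients.loc[patients["group"] == groups[0], var],
                patients.loc[patients["group"] == groups[1], var],
                variable=var)
            row["test"] = cmp_res.test
            row["p_value"] = cmp_res.p_value
        rows.append(row)
    table = pd.DataFrame(rows)
    if cfg.bh_correction:
        table = add_bh_adjusted(table)
    return table


def tcfa_frame_vs_segment_share(result: StudyResult,
                                group: str | None = None) -> tuple[float, float]:
    """Fraction of confirmed-TCFA frames (within the analyzed span) vs
    fraction of TCFA-labeled segments, at baseline."""
    frames = result.frames
    segs = result.segments
    if group is not None:
        frames = frames[frames["group"] == group]
        segs = segs[segs["group"] == group]
    f = frames[(frames["timepoint"] == "baseline") & frames["analyzed"]]
    frame_share = float((f["confirmed_label"] == "TCFA").mean())
    seg_share = group_phenotype_share(segs, Phenotype.TCFA,
                                      Timepoint.BASELINE).percent / 100.0
    return frame_share, seg_share


def run_study_files(cohort_manifest: str | Path,
                    config_path: str | Path | None = None,
                    out_dir: str | Path | None = None,
                    strict: bool = False) -> StudyResult:
    """File-driven entry point: read a cohort manifest, run, write tables."""
    cfg = AnalysisConfig.from_yaml(config_path) if config_path else AnalysisConfig()
    studies = read_cohort(cohort_manifest, cfg)
    result = run_study(studies, cfg, strict=strict)
    if out_dir is not None:
        result.write(out_dir)
    return result
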