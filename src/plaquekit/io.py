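"""Readers and writers for frame tables, landmark files, cohort manifests
and result tables.

Frame tables are plain CSV with the fixed header

    frame_index,axial_position_mm,lumen_csa_mm2,eem_csa_mm2,
    f_area_mm2,ff_area_mm2,nc_area_mm2,dc_area_mm2,nc_lumen_arc_deg

Areas are mm², arcs degrees, positions mm; units are a documented convention
and never guessed from the data.  When ``axial_position_mm`` is missing the
positions are synthesized as ``frame_index * frame_spacing_mm`` (uniformly
spaced gated frames).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .config import AnalysisConfig
from .errors import SchemaError, ValidationError
from .model import Frame, PatientStudy, Pullback, Timepoint

FRAME_COLUMNS = [
    "frame_index",
    "axial_position_mm",
    "lumen_csa_mm2",
    "eem_csa_mm2",
    "f_area_mm2",
    "ff_area_mm2",
    "nc_area_mm2",
    "dc_area_mm2",
    "nc_lumen_arc_deg",
]

_FLOAT_FORMAT = "%.12g"


def read_frame_table(
    path: str | Path,
    timepoint: Timepoint | str,
    vessel_id: str = "",
    distal_landmark_frame: int | None = None,
    proximal_landmark_frame: int | None = None,
    frame_spacing_mm: float = 0.5,
    composition_tolerance_frac: float = 0.05,
) -> Pullback:
    """Read one pullback from a frame-table CSV and validate it.

    Landmarks default to the first and last frame when not given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = [c for c in FRAME_COLUMNS if c != "axial_position_mm"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column '{col}'")
    if "axial_position_mm" not in df.columns:
        df["axial_position_mm"] = df["frame_index"] * frame_spacing_mm
    df = df.sort_values("frame_index").reset_index(drop=True)
    frames = [
        Frame(
            frame_index=int(r.frame_index),
            axial_position_mm=float(r.axial_position_mm),
            lumen_csa_mm2=float(r.lumen_csa_mm2),
            eem_csa_mm2=float(r.eem_csa_mm2),
            f_area_mm2=float(r.f_area_mm2),
            ff_area_mm2=float(r.ff_area_mm2),
            nc_area_mm2=float(r.nc_area_mm2),
            dc_area_mm2=float(r.dc_area_mm2),
            nc_lumen_arc_deg=float(r.nc_lumen_arc_deg),
        )
        for r in df.itertuples(index=False)
    ]
    if not frames:
        raise ValidationError(f"{path.name}: empty frame table")
    pb = Pullback(
        frames=frames,
        distal_landmark_frame=frames[0].frame_index
        if distal_landmark_frame is None else distal_landmark_frame,
        proximal_landmark_frame=frames[-1].frame_index
        if proximal_landmark_frame is None else proximal_landmark_frame,
        timepoint=Timepoint(timepoint),
        vessel_id=vessel_id,
    )
    pb.validate(composition_tolerance_frac)
    return pb


def write_frame_table(pullback: Pullback, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "frame_index": f.frame_index,
                "axial_position_mm": f.axial_position_mm,
                "lumen_csa_mm2": f.lumen_csa_mm2,
                "eem_csa_mm2": f.eem_csa_mm2,
                "f_area_mm2": f.f_area_mm2,
                "ff_area_mm2": f.ff_area_mm2,
                "nc_area_mm2": f.nc_area_mm2,
                "dc_area_mm2": f.dc_area_mm2,
                "nc_lumen_arc_deg": f.nc_lumen_arc_deg,
            }
            for f in pullback.frames
        ],
        columns=FRAME_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_landmarks(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    for col in ("baseline_frame_index", "follow_up_frame_index"):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing column '{col}'")
    return [
        (int(b), int(f))
        for b, f in zip(df["baseline_frame_index"], df["follow_up_frame_index"])
    ]


def write_landmarks(pairs: list[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["baseline_frame_index", "follow_up_frame_index"]
                 ).to_csv(path, index=False)


# -- cohort manifests ------------------------------------------------------

def write_cohort(studies: list[PatientStudy], out_dir: str | Path) -> Path:
    """Write a full cohort: per-patient frame tables + landmark files and a
    YAML manifest pointing at them.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in studies:
        bl = f"{s.patient_id}_baseline.csv"
        fu = f"{s.patient_id}_follow_up.csv"
        lm = f"{s.patient_id}_landmarks.csv"
        write_frame_table(s.baseline, out_dir / bl)
        write_frame_table(s.follow_up, out_dir / fu)
        write_landmarks(s.landmark_pairs, out_dir / lm)
        entries.append(
            {
                "patient_id": s.patient_id,
                "group": s.group,
                "baseline": bl,
                "follow_up": fu,
                "landmarks": lm,
                "covariates": {k: float(v) for k, v in s.covariates.items()},
            }
        )
    manifest = {"patients": entries}
    manifest_path = out_dir / "cohort.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_cohort(manifest_path: str | Path,
                cfg: AnalysisConfig | None = None) -> list[PatientStudy]:
    cfg = cfg or AnalysisConfig()
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    if not isinstance(doc, dict) or "patients" not in doc:
        raise SchemaError(f"{manifest_path.name}: manifest must contain 'patients'")
    base = manifest_path.parent
    studies = []
    for entry in doc["patients"]:
        pid = str(entry["patient_id"])
        study = PatientStudy(
            patient_id=pid,
            group=str(entry["group"]),
            baseline=read_frame_table(
                base / entry["baseline"], Timepoint.BASELINE, vessel_id=pid,
                frame_spacing_mm=cfg.frame_spacing_mm,
                composition_tolerance_frac=cfg.composition_tolerance_frac),
            follow_up=read_frame_table(
                base / entry["follow_up"], Timepoint.FOLLOW_UP, vessel_id=pid,
                frame_spacing_mm=cfg.frame_spacing_mm,
                composition_tolerance_frac=cfg.composition_tolerance_frac),
            landmark_pairs=read_landmarks(base / entry["landmarks"]),
            covariates=dict(entry.get("covariates") or {}),
        )
        study.validate(cfg.composition_tolerance_frac)
        studies.append(study)
    return studies


# -- result tables ---------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  manifest_extra: dict | None = None) -> dict:
    """Write one CSV per result family plus a JSON run manifest.

    Returns the manifest dict (also written as ``manifest.json``).  Floats
    are written with 12 significant digits so a re-read reproduces values to
    1e-9; integers round-trip exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    counts = {}
    for name, df in tables.items():
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format=_FLOAT_FORMAT)
        files[name] = fname
        counts[name] = int(len(df))
    manifest = {"files": files, "row_counts": counts}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
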