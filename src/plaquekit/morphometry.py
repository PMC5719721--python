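"""Per-frame and per-segment plaque morphometry.

Frame level: plaque CSA (EEM − lumen), plaque burden (plaque/EEM) and the
composition of characterized tissue (each VH component over F+FF+NC+DC —
the convention under which published composition fractions of ~0.55 fibrous
etc. cohere, since VH leaves media and unclassified pixels uncounted).

Segment level: unweighted means over the segment's frames, percent atheroma
volume

    PAV = 100 * Σ(EEM_area − Lumen_area) / Σ EEM_area,

the minimal lumen area (MLA) with its frame, and a remodeling index.  The
remodeling index here is the EEM CSA at the MLA frame over the mean EEM CSA
of the segment's two end frames — the nearest available reference sites in
a segment-based design; when the MLA frame is itself an end frame the single
other end frame serves as reference.  The definition is isolated in one
function so alternatives are drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFrameError, ValidationError
from .model import Frame

COMPONENTS = ("F", "FF", "NC", "DC")
_ATTR = {"F": "f_area_mm2", "FF": "ff_area_mm2", "NC": "nc_area_mm2",
         "DC": "dc_area_mm2"}


@dataclass
class FrameMorphometry:
    plaque_csa_mm2: float
    plaque_burden_frac: float
    composition_frac: dict[str, float]
    composition_mm2: dict[str, float]
    nc_lumen_arc_deg: float
    lumen_csa_mm2: float
    eem_csa_mm2: float


@dataclass
class SegmentMorphometry:
    n_frames: int
    mean_lumen_csa_mm2: float
    mean_eem_csa_mm2: float
    mean_plaque_csa_mm2: float
    pav_pct: float
    mla_mm2: float
    mla_frame_index: int
    remodeling_index: float
    mean_composition_mm2: dict[str, float]
    mean_composition_frac: dict[str, float]
    mean_nc_lumen_arc_deg: float


def frame_morphometry(frame: Frame) -> FrameMorphometry:
    """Geometric and compositional indices of one frame.

    Composition fractions are defined as 0 when no tissue is characterized.
    """
    if frame.eem_csa_mm2 <= 0:
        raise DegenerateFrameError(
            f"frame {frame.frame_index}: EEM CSA must be positive")
    plaque = frame.eem_csa_mm2 - frame.lumen_csa_mm2
    burden = plaque / frame.eem_csa_mm2
    comp_mm2 = {c: getattr(frame, _ATTR[c]) for c in COMPONENTS}
    total = sum(comp_mm2.values())
    if total > 0:
        comp_frac = {c: comp_mm2[c] / total for c in COMPONENTS}
    else:
        comp_frac = {c: 0.0 for c in COMPONENTS}
    return FrameMorphometry(
        plaque_csa_mm2=plaque,
        plaque_burden_frac=burden,
        composition_frac=comp_frac,
        composition_mm2=comp_mm2,
        nc_lumen_arc_deg=frame.nc_lumen_arc_deg,
        lumen_csa_mm2=frame.lumen_csa_mm2,
        eem_csa_mm2=frame.eem_csa_mm2,
    )


def pav(frames: list[Frame]) -> float:
    """Percent atheroma volume over a frame set, in [0, 100]."""
    if not frames:
        raise ValidationError("pav: empty frame list")
    eem = np.array([f.eem_csa_mm2 for f in frames], dtype=float)
    lumen = np.array([f.lumen_csa_mm2 for f in frames], dtype=float)
    if np.any(eem <= 0):
        raise DegenerateFrameError("pav: all EEM CSA must be positive")
    return float(100.0 * (eem - lumen).sum() / eem.sum())


def remodeling_index(segment_frames: list[Frame], mla_local_index: int) -> float:
    """Remodeling index of a segment given the local index of its MLA frame.

    Reference = mean EEM of the segment's two end frames; if the MLA frame
    coincides with an end frame, the single other end frame is the reference.
    """
    n = len(segment_frames)
    if n < 3:
        raise ValidationError(
            "remodeling_index: segment has < 3 frames; merge with a neighboring "
            "segment before computing a remodeling index")
    if not (0 <= mla_local_index < n):
        raise ValidationError("remodeling_index: MLA index outside segment")
    refs = [i for i in (0, n - 1) if i != mla_local_index]
    ref_eem = float(np.mean([segment_frames[i].eem_csa_mm2 for i in refs]))
    if ref_eem <= 0:
        raise DegenerateFrameError("remodeling_index: reference EEM must be positive")
    return segment_frames[mla_local_index].eem_csa_mm2 / ref_eem


def mla_local_index(segment_frames: list[Frame]) -> int:
    """Local index of the minimal-lumen frame; ties resolve to the most
    distal (first) frame."""
    lumen = np.array([f.lumen_csa_mm2 for f in segment_frames], dtype=float)
    return int(np.argmin(lumen))


def _frame_weights(segment_frames: list[Frame]) -> np.ndarray:
    """Inter-frame distance weights (trapezoidal) for length-weighted means."""
    pos = np.array([f.axial_position_mm for f in segment_frames], dtype=float)
    if len(pos) == 1:
        return np.ones(1)
    w = np.zeros(len(pos))
    w[:-1] += np.diff(pos) / 2
    w[1:] += np.diff(pos) / 2
    return w / w.sum()


def segment_morphometry(segment_frames: list[Frame],
                        length_weighted: bool = False) -> SegmentMorphometry:
    """Aggregate morphometry of one segment (>= 3 frames)."""
    if len(segment_frames) < 3:
        raise ValidationError("segment_morphometry: segment needs >= 3 frames")
    morphs = [frame_morphometry(f) for f in segment_frames]
    if length_weighted:
        w = _frame_weights(segment_frames)
    else:
        w = np.full(len(segment_frames), 1.0 / len(segment_frames))

    def wmean(values) -> float:
        return float(np.dot(w, np.asarray(values, dtype=float)))

    mla_i = mla_local_index(segment_frames)
    return SegmentMorphometry(
        n_frames=len(segment_frames),
        mean_lumen_csa_mm2=wmean([m.lumen_csa_mm2 for m in morphs]),
        mean_eem_csa_mm2=wmean([m.eem_csa_mm2 for m in morphs]),
        mean_plaque_csa_mm2=wmean([m.plaque_csa_mm2 for m in morphs]),
        pav_pct=pav(segment_frames),
        mla_mm2=segment_frames[mla_i].lumen_csa_mm2,
        mla_frame_index=segment_frames[mla_i].frame_index,
        remodeling_index=remodeling_index(segment_frames, mla_i),
        mean_composition_mm2={
            c: wmean([m.composition_mm2[c] for m in morphs]) for c in COMPONENTS},
        mean_composition_frac={
            c: wmean([m.composition_frac[c] for m in morphs]) for c in COMPONENTS},
        mean_nc_lumen_arc_deg=wmean([m.nc_lumen_arc_deg for m in morphs]),
    )
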