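"""Domain model: frames, pullbacks and patient studies.

A *frame* is one IVUS-VH cross section: lumen and external-elastic-membrane
(EEM) cross-sectional areas, the four virtual-histology tissue-component
areas — fibrous (F), fibro-fatty (FF), necrotic core (NC), dense calcium
(DC) — and the arc (degrees) over which necrotic core touches the lumen.
A *pullback* is the ordered frame sequence of one vessel at one timepoint,
bracketed by a distal and a proximal fiduciary landmark.  A *patient study*
pairs the baseline and 1-year follow-up pullbacks of one vessel together
with the landmark frame pairs used for co-registration.

Axial positions are measured in mm from the distal end of the pullback and
increase toward the ostium (the direction of catheter withdrawal); frame
indices are 0-based.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import ValidationError


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    FOLLOW_UP = "follow_up"


VALID_GROUPS = ("DM", "non_DM")


@dataclass
class Frame:
    frame_index: int
    axial_position_mm: float
    lumen_csa_mm2: float
    eem_csa_mm2: float
    f_area_mm2: float
    ff_area_mm2: float
    nc_area_mm2: float
    dc_area_mm2: float
    nc_lumen_arc_deg: float

    @property
    def plaque_csa_mm2(self) -> float:
        return self.eem_csa_mm2 - self.lumen_csa_mm2

    @property
    def characterized_mm2(self) -> float:
        return self.f_area_mm2 + self.ff_area_mm2 + self.nc_area_mm2 + self.dc_area_mm2


def validate_frame(frame: Frame, composition_tolerance_frac: float = 0.05) -> None:
    """Check every frame invariant, raising :class:`ValidationError` naming
    the frame index and the violated rule."""

    def fail(rule: str) -> None:
        raise ValidationError(f"frame {frame.frame_index}: {rule}")

    if frame.frame_index < 0:
        fail("frame_index must be >= 0")
    for name in ("lumen_csa_mm2", "eem_csa_mm2", "f_area_mm2", "ff_area_mm2",
                 "nc_area_mm2", "dc_area_mm2", "nc_lumen_arc_deg",
                 "axial_position_mm"):
        v = getattr(frame, name)
        if not math.isfinite(v):
            fail(f"{name} must be finite")
    if frame.lumen_csa_mm2 < 0:
        fail("lumen CSA must be >= 0")
    if frame.lumen_csa_mm2 > frame.eem_csa_mm2:
        fail("lumen <= EEM violated (lumen CSA exceeds EEM CSA)")
    for name in ("f_area_mm2", "ff_area_mm2", "nc_area_mm2", "dc_area_mm2"):
        if getattr(frame, name) < 0:
            fail(f"{name} must be >= 0")
    plaque = frame.plaque_csa_mm2
    if frame.characterized_mm2 > plaque * (1.0 + composition_tolerance_frac) + 1e-12:
        fail("component areas exceed plaque area beyond tolerance")
    if not (0.0 <= frame.nc_lumen_arc_deg <= 360.0):
        fail("nc_lumen_arc_deg must lie in [0, 360]")
    if frame.nc_area_mm2 == 0 and frame.nc_lumen_arc_deg != 0:
        fail("nc_lumen_arc_deg must be 0 when nc_area_mm2 is 0")


@dataclass
class Pullback:
    frames: list[Frame]
    distal_landmark_frame: int
    proximal_landmark_frame: int
    timepoint: Timepoint
    vessel_id: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.timepoint, str):
            self.timepoint = Timepoint(self.timepoint)

    def validate(self, composition_tolerance_frac: float = 0.05) -> None:
        if len(self.frames) < 2:
            raise ValidationError(f"pullback {self.vessel_id}: needs >= 2 frames")
        for f in self.frames:
            validate_frame(f, composition_tolerance_frac)
        pos = [f.axial_position_mm for f in self.frames]
        idx = [f.frame_index for f in self.frames]
        for k in range(1, len(pos)):
            if idx[k] <= idx[k - 1]:
                raise ValidationError(
                    f"pullback {self.vessel_id}: frame_index not strictly increasing "
                    f"at row {k}")
            if pos[k] <= pos[k - 1]:
                raise ValidationError(
                    f"pullback {self.vessel_id}: axial_position_mm not strictly "
                    f"increasing at frame {idx[k]}")
        known = set(idx)
        if self.distal_landmark_frame not in known:
            raise ValidationError(
                f"pullback {self.vessel_id}: distal landmark {self.distal_landmark_frame} "
                f"is not a frame index")
        if self.proximal_landmark_frame not in known:
            raise ValidationError(
                f"pullback {self.vessel_id}: proximal landmark "
                f"{self.proximal_landmark_frame} is not a frame index")
        if self.distal_landmark_frame >= self.proximal_landmark_frame:
            raise ValidationError(
                f"pullback {self.vessel_id}: distal landmark must precede proximal")

    def position_of(self, frame_index: int) -> float:
        for f in self.frames:
            if f.frame_index == frame_index:
                return f.axial_position_mm
        raise ValidationError(
            f"pullback {self.vessel_id}: no frame with index {frame_index}")

    @property
    def analyzed_length_mm(self) -> float:
        """Axial span between the distal and proximal landmarks."""
        return self.position_of(self.proximal_landmark_frame) - \
            self.position_of(self.distal_landmark_frame)


@dataclass
class PatientStudy:
    patient_id: str
    group: str
    baseline: Pullback
    follow_up: Pullback
    landmark_pairs: list[tuple[int, int]]
    covariates: dict = field(default_factory=dict)

    def validate(self, composition_tolerance_frac: float = 0.05) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"patient {self.patient_id}: group must be one of {VALID_GROUPS}, "
                f"got {self.group!r}")
        self.baseline.validate(composition_tolerance_frac)
        self.follow_up.validate(composition_tolerance_frac)
        if len(self.landmark_pairs) < 2:
            raise ValidationError(
                f"patient {self.patient_id}: needs >= 2 landmark pairs")
        pairs = list(self.landmark_pairs)
        for k in range(1, len(pairs)):
            b0, f0 = pairs[k - 1]
            b1, f1 = pairs[k]
            if b1 <= b0 or f1 <= f0:
                raise ValidationError(
                    f"patient {self.patient_id}: landmark pairs not monotone at "
                    f"({b1}, {f1})")
        for b, f in pairs:
            self.baseline.position_of(b)
            self.follow_up.position_of(f)
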