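"""Liverpool Active Plaque Score (LAPS).

A linear frame-level risk score:

    LAPS = -2.149 + 0.68 * NC/DC + 3.39 * MLA
           + 5.1 * [remodeling index > 1.05] + 3.7 * [VH-TCFA]

computed for every frame; the LAPS of a 5-mm segment is the highest frame
LAPS within it, and the LAPS of a pullback is the mean over its segments.

Frame-level conventions: the MLA term uses the frame's own lumen CSA (the
only frame-local reading of a lesion-level quantity; a config flag
substitutes the enclosing segment's MLA), the remodeling condition comes
from the enclosing segment's remodeling index, and the NC/DC ratio is kept
finite by flooring DC at a small epsilon and capping the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import AnalysisConfig, LapsCoefficients
from .errors import ValidationError
from .morphometry import FrameMorphometry, SegmentMorphometry
from .phenotype import Phenotype


@dataclass
class LapsInputs:
    nc_dc_ratio: float
    mla_mm2: float
    remodeling_positive: bool
    tcfa_indicator: int


def laps_frame(inputs: LapsInputs, coeffs: LapsCoefficients) -> float:
    """Evaluate the LAPS formula exactly as printed."""
    return (
        coeffs.intercept
        + coeffs.nc_dc * inputs.nc_dc_ratio
        + coeffs.mla * inputs.mla_mm2
        + (coeffs.remodeling if inputs.remodeling_positive else 0.0)
        + coeffs.tcfa * inputs.tcfa_indicator
    )


def nc_dc_ratio(nc_mm2: float, dc_mm2: float, cfg: AnalysisConfig) -> float:
    """NC/DC with DC floored at ``dc_epsilon_mm2`` and the ratio capped.

    NC = 0 gives 0 regardless of DC (no necrotic core, no ratio term).
    """
    if nc_mm2 <= 0:
        return 0.0
    ratio = nc_mm2 / max(dc_mm2, cfg.dc_epsilon_mm2)
    return min(ratio, cfg.nc_dc_ratio_cap)


def laps_inputs_for_frame(
    fm: FrameMorphometry,
    segment: SegmentMorphometry,
    confirmed_label: Phenotype,
    cfg: AnalysisConfig,
) -> LapsInputs:
    """Assemble LAPS inputs for one frame within its enclosing segment."""
    return LapsInputs(
        nc_dc_ratio=nc_dc_ratio(
            fm.composition_mm2["NC"], fm.composition_mm2["DC"], cfg),
        mla_mm2=segment.mla_mm2 if cfg.use_segment_mla else fm.lumen_csa_mm2,
        remodeling_positive=segment.remodeling_index > cfg.ri_threshold,
        tcfa_indicator=1 if confirmed_label is Phenotype.TCFA else 0,
    )


def laps_segment(frame_scores: list[float]) -> float:
    """Segment LAPS = highest frame LAPS in the segment."""
    if not frame_scores:
        raise ValidationError("laps_segment: empty score list")
    return max(frame_scores)


def laps_pullback(segment_scores: list[float]) -> float:
    """Pullback LAPS = mean over its analyzed segments."""
    if not segment_scores:
        raise ValidationError("laps_pullback: empty score list")
    return sum(segment_scores) / len(segment_scores)
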