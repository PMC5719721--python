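"""Analysis configuration.

Every numeric constant of the analysis — segment length, the frame-phenotype
classification thresholds, the TCFA run-confirmation length, the LAPS
coefficients and the remodeling-index cutoff — lives here rather than in
code, so the whole pipeline can be re-run under alternative conventions from
a single YAML file.

Units are fixed by convention and never auto-detected: areas in mm², axial
positions in mm, arcs in degrees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class LapsCoefficients:
    """Coefficients of the Liverpool Active Plaque Score (LAPS).

    LAPS is a linear frame-level risk score:

        intercept + nc_dc * (NC/DC) + mla * MLA
                  + remodeling * [RI > ri_threshold] + tcfa * [VH-TCFA]

    The published coefficients are the defaults.  They are configuration, not
    code, because the score is adapted from an earlier derivation cohort and
    users may need to substitute alternative coefficient sets (including a
    negative MLA coefficient, which some derivations use).
    """

    intercept: float = -2.149
    nc_dc: float = 0.68
    mla: float = 3.39
    remodeling: float = 5.1
    tcfa: float = 3.7


@dataclass
class AnalysisConfig:
    """All tunable constants of the serial IVUS-VH analysis.

    Attributes
    ----------
    segment_length_mm:
        Length of the co-registered vessel segments that frame indices are
        averaged over (5 mm).
    frame_spacing_mm:
        Fallback inter-frame spacing used to synthesize axial positions when
        a frame table carries none (pullback speed 0.5 mm/s, one gated frame
        per second assumed).
    tcfa_min_run_frames:
        Number of consecutive TCFA-candidate frames required before the TCFA
        label is confirmed (3).
    pb_lesion_threshold_pct:
        Plaque-burden threshold below which a frame carries no lesion (40%).
    nc_confluent_threshold_pct:
        Necrotic-core fraction of characterized tissue treated as confluent
        NC (10%).
    dc_threshold_pct, ff_threshold_pct:
        Dense-calcium and fibro-fatty thresholds of the classification
        cascade (10%, 15%).
    nc_arc_contact_deg:
        Minimum NC-lumen contact arc read as "no visible fibrous cap" (30°).
        Set to 1.0 for the stricter any-contact reading.
    ri_threshold:
        Remodeling-index cutoff for the positive-remodeling LAPS term (1.05).
    dc_epsilon_mm2, nc_dc_ratio_cap:
        Floor on the DC area entering the NC/DC ratio and the cap keeping the
        ratio finite when DC ≈ 0.
    composition_tolerance_frac:
        Allowed excess of F+FF+NC+DC over plaque area, as a fraction of
        plaque area (VH leaves media/unclassified pixels uncounted).
    min_overlap_mm:
        Minimum registered baseline/follow-up overlap for a patient to be
        analyzed (25 mm inclusion criterion).
    use_segment_mla:
        If True the MLA term of frame-level LAPS uses the enclosing segment's
        minimal lumen area instead of the frame's own lumen CSA.
    length_weighted_means:
        If True segment means weight frames by inter-frame distance instead
        of the default unweighted mean over uniformly gated frames.
    bh_correction:
        If True group-statistics tables add Benjamini-Hochberg adjusted
        p-values (off by default; the primary analysis applies none).
    """

    segment_length_mm: float = 5.0
    frame_spacing_mm: float = 0.5
    tcfa_min_run_frames: int = 3
    pb_lesion_threshold_pct: float = 40.0
    nc_confluent_threshold_pct: float = 10.0
    dc_threshold_pct: float = 10.0
    ff_threshold_pct: float = 15.0
    nc_arc_contact_deg: float = 30.0
    ri_threshold: float = 1.05
    laps_coeffs: LapsCoefficients = field(default_factory=LapsCoefficients)
    dc_epsilon_mm2: float = 0.01
    nc_dc_ratio_cap: float = 10.0
    composition_tolerance_frac: float = 0.05
    min_overlap_mm: float = 25.0
    use_segment_mla: bool = False
    length_weighted_means: bool = False
    bh_correction: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "segment_length_mm",
            "frame_spacing_mm",
            "tcfa_min_run_frames",
            "pb_lesion_threshold_pct",
            "nc_confluent_threshold_pct",
            "dc_threshold_pct",
            "ff_threshold_pct",
            "nc_arc_contact_deg",
            "ri_threshold",
            "dc_epsilon_mm2",
            "nc_dc_ratio_cap",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.composition_tolerance_frac < 0:
            raise ConfigError("composition_tolerance_frac must be >= 0")
        if self.segment_length_mm <= self.frame_spacing_mm:
            raise ConfigError("segment_length_mm must exceed frame_spacing_mm")
        if self.min_overlap_mm < self.segment_length_mm:
            raise ConfigError("min_overlap_mm must be >= segment_length_mm")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        coeffs = d.pop("laps_coeffs", None)
        cfg = cls(**d) if coeffs is None else cls(laps_coeffs=LapsCoefficients(**coeffs), **d)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:  # pragma: no cover - malformed user file
            raise ConfigError(f"cannot parse config YAML: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError("config YAML must map field names to values")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise ConfigError(f"unknown config field: {exc}") from exc

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
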