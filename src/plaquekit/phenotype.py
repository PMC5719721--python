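"""Six-category plaque phenotype classification.

Frames are classified into NL < PIT < FP < FcP < ThCFA < TCFA (ascending
severity) by a threshold cascade on plaque burden and the composition of
characterized tissue:

1. plaque burden < 40%                        -> NL (no lesion)
2. NC >= 10% and NC-lumen arc >= 30 deg       -> TCFA candidate
3. NC >= 10% without lumen contact            -> ThCFA
4. DC >= 10%                                  -> FcP
5. FF >= 15%                                  -> PIT
6. otherwise                                  -> FP

A scalar NC fraction cannot express spatial confluence, so total NC >= 10%
of characterized tissue stands in for "confluent necrotic core"; lumen
contact is read from the NC-lumen arc so the criterion stays tunable (30 deg
default, 1 deg for a strict any-contact reading).

The TCFA label itself requires three consecutive candidate frames.  Shorter
candidate runs demote to ThCFA (NC-rich plaque whose cap criterion is
unconfirmed — the severity-conservative choice).  Confirmation runs over the
whole pullback, so a confirmed run straddling a 5-mm segment boundary marks
every segment it touches as TCFA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .config import AnalysisConfig
from .errors import ValidationError
from .morphometry import FrameMorphometry


class Phenotype(enum.IntEnum):
    """Plaque phenotype; integer value is the severity rank (0..5)."""

    NL = 0
    PIT = 1
    FP = 2
    FCP = 3
    THCFA = 4
    TCFA = 5

    @property
    def display(self) -> str:
        return _DISPLAY[self]

    @classmethod
    def from_string(cls, s: str) -> "Phenotype":
        try:
            return _PARSE[s]
        except KeyError:
            raise ValidationError(f"unknown phenotype label {s!r}") from None


_DISPLAY = {
    Phenotype.NL: "NL",
    Phenotype.PIT: "PIT",
    Phenotype.FP: "FP",
    Phenotype.FCP: "FcP",
    Phenotype.THCFA: "ThCFA",
    Phenotype.TCFA: "TCFA",
}
_PARSE = {v: k for k, v in _DISPLAY.items()}

PHENOTYPE_ORDER = [Phenotype.NL, Phenotype.PIT, Phenotype.FP, Phenotype.FCP,
                   Phenotype.THCFA, Phenotype.TCFA]


@dataclass
class FramePhenotype:
    frame_index: int
    raw_label: Phenotype       # TCFA here means "TCFA candidate"
    confirmed_label: Phenotype


def classify_frame(m: FrameMorphometry, cfg: AnalysisConfig) -> Phenotype:
    """Raw phenotype of one frame (TCFA = candidate, pre-confirmation)."""
    if m.plaque_burden_frac * 100.0 < cfg.pb_lesion_threshold_pct:
        return Phenotype.NL
    nc = m.composition_frac["NC"] * 100.0
    if nc >= cfg.nc_confluent_threshold_pct:
        if m.nc_lumen_arc_deg >= cfg.nc_arc_contact_deg:
            return Phenotype.TCFA
        return Phenotype.THCFA
    if m.composition_frac["DC"] * 100.0 >= cfg.dc_threshold_pct:
        return Phenotype.FCP
    if m.composition_frac["FF"] * 100.0 >= cfg.ff_threshold_pct:
        return Phenotype.PIT
    return Phenotype.FP


def confirm_tcfa_runs(raw_labels: list[Phenotype],
                      cfg: AnalysisConfig) -> list[Phenotype]:
    """Apply the consecutive-frame TCFA confirmation over a pullback.

    Maximal runs of TCFA candidates of length >= ``tcfa_min_run_frames``
    keep TCFA; members of shorter runs demote to ThCFA.  Idempotent.
    """
    confirmed = list(raw_labels)
    n = len(confirmed)
    i = 0
    while i < n:
        if confirmed[i] is Phenotype.TCFA:
            j = i
            while j < n and confirmed[j] is Phenotype.TCFA:
                j += 1
            if j - i < cfg.tcfa_min_run_frames:
                for k in range(i, j):
                    confirmed[k] = Phenotype.THCFA
            i = j
        else:
            i += 1
    return confirmed


def tcfa_runs(confirmed_labels: list[Phenotype]) -> list[tuple[int, int]]:
    """Half-open index ranges [start, stop) of confirmed TCFA runs."""
    runs = []
    i, n = 0, len(confirmed_labels)
    while i < n:
        if confirmed_labels[i] is Phenotype.TCFA:
            j = i
            while j < n and confirmed_labels[j] is Phenotype.TCFA:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def label_segment(confirmed_labels: list[Phenotype],
                  straddle_tcfa: bool = False) -> Phenotype:
    """Worst (most advanced) phenotype over the segment's frames.

    ``straddle_tcfa`` forces TCFA when a confirmed TCFA run crosses the
    segment boundary and touches this segment with at least one frame.  With
    pullback-wide confirmation the touching frames already carry TCFA, so
    the flag is a guard for per-segment confirmation workflows.
    """
    if not confirmed_labels:
        raise ValidationError("label_segment: empty segment")
    if straddle_tcfa:
        return Phenotype.TCFA
    return max(confirmed_labels)
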