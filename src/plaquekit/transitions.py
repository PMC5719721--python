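"""Phenotype transition matrices and TCFA fate classification.

Between baseline and 1-year follow-up a TCFA segment either remains TCFA
(*persistent*) or changes phenotype (*healed*); a non-TCFA segment can turn
into TCFA (*new*) or stay non-TCFA (*never*).  The primary new-TCFA rate is
reported against the baseline non-TCFA denominator; the rate against all
segments is emitted alongside since published percentages do not always
state their denominator.

Percentages are reported to one decimal, rounding halves away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import Timepoint
from .phenotype import PHENOTYPE_ORDER, Phenotype

FATES = ("persistent", "healed", "new", "never")


def _label_lists(pairs) -> tuple[list[Phenotype], list[Phenotype]]:
    """Normalize input (DataFrame with baseline_label/followup_label columns
    of labels or strings, or a sequence of segment pairs) to two phenotype
    lists.  Plain lists, not pandas columns — pandas silently coerces
    IntEnum values to int64."""

    def coerce(values) -> list[Phenotype]:
        return [v if isinstance(v, Phenotype) else Phenotype.from_string(str(v))
                for v in values]

    if isinstance(pairs, pd.DataFrame):
        return (coerce(pairs["baseline_label"]), coerce(pairs["followup_label"]))
    return (coerce(p.baseline_label for p in pairs),
            coerce(p.followup_label for p in pairs))


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class TransitionMatrix:
    labels: list[str]
    counts: np.ndarray  # 6x6, [baseline, followup]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Row-normalized (per baseline phenotype); zero rows stay zero."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(row > 0, self.counts / row, 0.0)
        return p

    def to_dataframe(self, proportions: bool = False) -> pd.DataFrame:
        data = self.proportions if proportions else self.counts
        return pd.DataFrame(data, index=self.labels, columns=self.labels)


def transition_matrix(pairs) -> TransitionMatrix:
    """Counts of baseline -> follow-up phenotype transitions."""
    bl, fu = _label_lists(pairs)
    if not bl:
        raise ValidationError("transition_matrix: no segment pairs")
    n = len(PHENOTYPE_ORDER)
    counts = np.zeros((n, n), dtype=int)
    for b, f in zip(bl, fu):
        counts[int(b), int(f)] += 1
    return TransitionMatrix(labels=[p.display for p in PHENOTYPE_ORDER],
                            counts=counts)


@dataclass
class TcfaFateResult:
    fates: list[str]                 # per segment pair, order preserved
    n_pairs: int
    n_baseline_tcfa: int
    counts: dict[str, int]
    persistent_rate: float          # persistent / baseline TCFA
    healed_rate: float              # healed / baseline TCFA
    new_rate: float                 # new / baseline non-TCFA (primary)
    new_rate_all: float             # new / all segments (alternative)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fate": FATES,
                "count": [self.counts[f] for f in FATES],
            }
        )


def classify_tcfa_fates(pairs) -> TcfaFateResult:
    """Classify every segment pair into persistent/healed/new/never."""
    bl, fu = _label_lists(pairs)
    fates = []
    for b, f in zip(bl, fu):
        if b is Phenotype.TCFA:
            fates.append("persistent" if f is Phenotype.TCFA else "healed")
        else:
            fates.append("new" if f is Phenotype.TCFA else "never")
    counts = {f: fates.count(f) for f in FATES}
    n = len(fates)
    n_bl_tcfa = counts["persistent"] + counts["healed"]
    n_bl_other = n - n_bl_tcfa
    return TcfaFateResult(
        fates=fates,
        n_pairs=n,
        n_baseline_tcfa=n_bl_tcfa,
        counts=counts,
        persistent_rate=counts["persistent"] / n_bl_tcfa if n_bl_tcfa else float("nan"),
        healed_rate=counts["healed"] / n_bl_tcfa if n_bl_tcfa else float("nan"),
        new_rate=counts["new"] / n_bl_other if n_bl_other else float("nan"),
        new_rate_all=counts["new"] / n if n else float("nan"),
    )


@dataclass
class PhenotypeShare:
    count: int
    total: int
    percent: float  # to one decimal


def group_phenotype_share(pairs, label: Phenotype,
                          timepoint: Timepoint | str) -> PhenotypeShare:
    """Share of segments carrying ``label`` at one timepoint."""
    bl, fu = _label_lists(pairs)
    if not bl:
        raise ValidationError("group_phenotype_share: no segment pairs")
    values = bl if Timepoint(timepoint) is Timepoint.BASELINE else fu
    count = int(sum(1 for v in values if v is label))
    total = len(values)
    return PhenotypeShare(count=count, total=total,
                          percent=round_pct(100.0 * count / total))
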