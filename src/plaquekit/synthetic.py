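"""Synthetic serial IVUS-VH cohort generator.

Generates complete two-timepoint patient studies — frame-level pullbacks
with landmark pairs, DM/non-DM effect structure and clinical covariates —
so every pipeline stage is testable without clinical data.

Generation is top-down: segment-level targets (baseline geometry, phenotype
label, 1-year changes, TCFA fate) are drawn first, then frames are
synthesized to realize them *exactly* in the segment means, so pipeline
recovery tests have known ground truth.  Specifically, per 5-mm segment:

* mean EEM CSA and PAV are drawn from the group's baseline distributions
  (PAV is truncated away from the 40% lesion threshold so frame noise
  cannot flip the intended phenotype class);
* the plaque-area and vessel-area (EEM) changes are drawn jointly from
  the group's change distributions — strongly correlated
  (``delta_plaque_vessel_correlation``), because plaque growth drives
  outward remodeling; the three reported change SDs (plaque, vessel, PAV)
  jointly fix that correlation near 0.93-0.97 — with a shared patient
  random intercept plus segment noise, and imposed exactly on the segment
  means.  Lumen change follows linearly (EEM minus plaque) and the PAV
  change is emergent with exactly the reported group mean, since the
  reported change table is internally consistent;
* the phenotype label is realized through composition templates whose
  fractions sit safely inside the classification-cascade thresholds, with a
  confirmed multi-frame candidate run for TCFA segments (covering roughly
  half the segment, so the cohort-wide fraction of TCFA *frames* stays
  below the fraction of TCFA-labeled *segments*);
* TCFA fate draws (persistent / new) drive the follow-up composition; a
  follow-up TCFA in a segment whose geometry regressed below the lesion
  threshold is floored back above it (rapid focal progression), the one
  place where the imposed change distributions are distorted.

Vessel remodeling progresses between timepoints in a group-directional way:
diabetic lesions can develop a positively remodeled focal profile by
follow-up (``remodeling_gain_prob``) while non-diabetic lesions tend to
resolve theirs (``remodeling_loss_prob``), mirroring the diverging
remodeling behavior of progressing vs regressing plaques.

Follow-up pullbacks are stretched piecewise-linearly (±8% per landmark leg)
relative to baseline, with a mid-vessel landmark, to exercise registration.
The pullback-level LAPS change is *not* imposed directly — it emerges from
the geometry, fate and remodeling edits; the configured distribution is
used by the fast segment-delta sampler (:func:`generate_segment_deltas`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .model import Frame, PatientStudy, Pullback, Timepoint
from .phenotype import Phenotype

# Composition templates: fractions of characterized tissue (F, FF, NC, DC)
# chosen with wide margins to the cascade thresholds (NC 10%, DC 10%,
# FF 15%) so multiplicative frame noise cannot cross a class boundary.
_TEMPLATES = {
    "NL": (0.62, 0.25, 0.05, 0.08),
    "PIT": (0.68, 0.22, 0.05, 0.05),
    "FP": (0.82, 0.08, 0.05, 0.05),
    "FcP": (0.69, 0.10, 0.05, 0.16),
    "ThCFA": (0.60, 0.10, 0.20, 0.10),
    "TCFA": (0.55, 0.10, 0.22, 0.13),   # candidate-run frames only
}
_FRAC_NOISE_SD = 0.12
_PAV_LESION_FLOOR = 43.0    # baseline lesion segments stay clear of 40%
_PAV_FU_FLOOR = 41.5        # follow-up lesions: lowest mean PAV at which
                            # every in-class frame keeps burden >= 40%
_PAV_NL_CEIL = 38.0
_SPACING = 0.5


@dataclass
class Dist:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"distribution SD must be > 0, got {self.sd}")


@dataclass
class GroupParams:
    n_patients: int
    vessel_length_mm: Dist
    baseline_vessel_area_mm2: Dist
    baseline_pav_pct: Dist
    delta_plaque_area_mm2: Dist
    delta_vessel_area_mm2: Dist
    delta_plaque_vessel_correlation: float
    delta_pav_pct: Dist
    delta_pullback_laps: Dist
    delta_plaque_pav_correlation: float
    baseline_phenotype_probs: dict[str, float]
    new_tcfa_prob: float
    persistent_tcfa_prob: float
    remodeling_gain_prob: float
    remodeling_loss_prob: float
    ldl_baseline_mmol_l: Dist
    ldl_change_mmol_l: Dist
    ldl_plaque_correlation: float

    def validate(self) -> None:
        for name in ("new_tcfa_prob", "persistent_tcfa_prob",
                     "remodeling_gain_prob", "remodeling_loss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        probs = self.baseline_phenotype_probs
        if set(probs) != set(_TEMPLATES):
            raise ConfigError("baseline_phenotype_probs must cover all six "
                              "phenotypes")
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-6:
            raise ConfigError("baseline_phenotype_probs must be a probability "
                              "vector summing to 1")
        if not -1.0 <= self.ldl_plaque_correlation <= 1.0:
            raise ConfigError("ldl_plaque_correlation must lie in [-1, 1]")
        if not -1.0 <= self.delta_plaque_pav_correlation <= 1.0:
            raise ConfigError("delta_plaque_pav_correlation must lie in "
                              "[-1, 1]")
        if not -1.0 <= self.delta_plaque_vessel_correlation <= 1.0:
            raise ConfigError("delta_plaque_vessel_correlation must lie in "
                              "[-1, 1]")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")


@dataclass
class SharedParams:
    frame_spacing_mm: float = _SPACING
    min_length_mm: float = 30.0
    patient_intercept_frac: float = 0.3
    characterized_fraction: float = 0.9
    label_drift_prob: float = 0.1
    stretch_range: tuple[float, float] = (0.92, 1.08)
    focal_segment_prob: float = 0.3

    def validate(self) -> None:
        if not 0.0 <= self.patient_intercept_frac < 1.0:
            raise ConfigError("patient_intercept_frac must lie in [0, 1)")
        if not 0.0 < self.characterized_fraction <= 1.0:
            raise ConfigError("characterized_fraction must lie in (0, 1]")
        if not 0.0 <= self.label_drift_prob <= 1.0:
            raise ConfigError("label_drift_prob must lie in [0, 1]")
        lo, hi = self.stretch_range
        if not 0.5 < lo <= hi < 2.0:
            raise ConfigError("stretch_range must satisfy 0.5 < lo <= hi < 2")
        if not 0.0 <= self.focal_segment_prob <= 1.0:
            raise ConfigError("focal_segment_prob must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    groups: dict[str, GroupParams]
    shared: SharedParams = field(default_factory=SharedParams)
    seed: int = 0

    def validate(self) -> None:
        for gp in self.groups.values():
            gp.validate()
        self.shared.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        def dist(v) -> Dist:
            return Dist(float(v["mean"]), float(v["sd"]))

        groups = {}
        for name, g in d["groups"].items():
            groups[name] = GroupParams(
                n_patients=int(g["n_patients"]),
                vessel_length_mm=dist(g["vessel_length_mm"]),
                baseline_vessel_area_mm2=dist(g["baseline_vessel_area_mm2"]),
                baseline_pav_pct=dist(g["baseline_pav_pct"]),
                delta_plaque_area_mm2=dist(g["delta_plaque_area_mm2"]),
                delta_vessel_area_mm2=dist(g["delta_vessel_area_mm2"]),
                delta_plaque_vessel_correlation=float(
                    g.get("delta_plaque_vessel_correlation", 0.0)),
                delta_pav_pct=dist(g["delta_pav_pct"]),
                delta_pullback_laps=dist(g["delta_pullback_laps"]),
                delta_plaque_pav_correlation=float(
                    g.get("delta_plaque_pav_correlation", 0.0)),
                baseline_phenotype_probs={
                    k: float(v) for k, v in g["baseline_phenotype_probs"].items()},
                new_tcfa_prob=float(g["new_tcfa_prob"]),
                persistent_tcfa_prob=float(g["persistent_tcfa_prob"]),
                remodeling_gain_prob=float(g.get("remodeling_gain_prob", 0.0)),
                remodeling_loss_prob=float(g.get("remodeling_loss_prob", 0.0)),
                ldl_baseline_mmol_l=dist(g["ldl_baseline_mmol_l"]),
                ldl_change_mmol_l=dist(g["ldl_change_mmol_l"]),
                ldl_plaque_correlation=float(g["ldl_plaque_correlation"]),
            )
        shared = d.get("shared", {})
        sp = SharedParams(
            frame_spacing_mm=float(shared.get("frame_spacing_mm", _SPACING)),
            min_length_mm=float(shared.get("min_length_mm", 30.0)),
            patient_intercept_frac=float(shared.get("patient_intercept_frac", 0.3)),
            characterized_fraction=float(shared.get("characterized_fraction", 0.9)),
            label_drift_prob=float(shared.get("label_drift_prob", 0.1)),
            stretch_range=tuple(shared.get("stretch_range", (0.92, 1.08))),
            focal_segment_prob=float(shared.get("focal_segment_prob", 0.3)),
        )
        cfg = cls(groups=groups, shared=sp, seed=int(d.get("seed", 0)))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_generator_config() -> GeneratorConfig:
    """Packaged defaults (the calibrated study conditions)."""
    text = resources.files("plaquekit.data").joinpath(
        "generator_defaults.yaml").read_text()
    return GeneratorConfig.from_dict(yaml.safe_load(text))


def _corr_normal(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """n standard-normal pairs with correlation rho, shape (n, 2)."""
    z = rng.standard_normal((n, 2))
    return np.column_stack([z[:, 0],
                            rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]])


# -- fast samplers ---------------------------------------------------------

def generate_segment_deltas(group: str, n: int,
                            gcfg: GeneratorConfig | None = None,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            patient_ids=None) -> pd.DataFrame:
    """Draw per-segment change records straight from the configured change
    distributions (no frame synthesis) — the fast path for statistics-layer
    tests.

    Without ``patient_ids`` the draws are i.i.d.; with them, a shared
    patient random intercept (``patient_intercept_frac`` of each SD) is
    added.  ``delta_pullback_laps`` draws are patient-level quantities and
    are included per record for convenience.
    """
    gcfg = gcfg or default_generator_config()
    if group not in gcfg.groups:
        raise ConfigError(f"unknown group {group!r}")
    if n < 1:
        raise ValidationError("generate_segment_deltas: n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(
        gcfg.seed if seed is None else seed)
    gp = gcfg.groups[group]
    frac = gcfg.shared.patient_intercept_frac
    rho = gp.delta_plaque_pav_correlation
    dp, dv, dl = (gp.delta_plaque_area_mm2, gp.delta_pav_pct,
                  gp.delta_pullback_laps)
    out = {}
    if patient_ids is None:
        z = _corr_normal(n, rho, rng)
        out["delta_plaque_area_mm2"] = dp.mean + dp.sd * z[:, 0]
        out["delta_pav_pct"] = dv.mean + dv.sd * z[:, 1]
        out["delta_pullback_laps"] = rng.normal(dl.mean, dl.sd, size=n)
    else:
        patient_ids = np.asarray(patient_ids)
        if patient_ids.shape[0] != n:
            raise ValidationError("patient_ids length must equal n")
        uniq, inv = np.unique(patient_ids, return_inverse=True)
        zic = _corr_normal(uniq.size, rho, rng) * frac
        zres = _corr_normal(n, rho, rng) * np.sqrt(1 - frac ** 2)
        out["delta_plaque_area_mm2"] = dp.mean + dp.sd * (zic[inv, 0] +
                                                          zres[:, 0])
        out["delta_pav_pct"] = dv.mean + dv.sd * (zic[inv, 1] + zres[:, 1])
        ic = rng.normal(0.0, frac * dl.sd, size=uniq.size)
        res = rng.normal(0.0, np.sqrt(1 - frac ** 2) * dl.sd, size=n)
        out["delta_pullback_laps"] = dl.mean + ic[inv] + res
        out["patient_id"] = patient_ids
    return pd.DataFrame(out)


def generate_label_pairs(group: str, n: int,
                         gcfg: GeneratorConfig | None = None,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         baseline_tcfa: bool | None = None) -> pd.DataFrame:
    """Draw baseline/follow-up phenotype label pairs from the group's
    baseline mix and fate probabilities, without frame synthesis.

    ``baseline_tcfa`` restricts the baseline draw to TCFA segments (True)
    or non-TCFA segments (False).
    """
    gcfg = gcfg or default_generator_config()
    if group not in gcfg.groups:
        raise ConfigError(f"unknown group {group!r}")
    if n < 1:
        raise ValidationError("generate_label_pairs: n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(
        gcfg.seed if seed is None else seed)
    gp = gcfg.groups[group]
    labels = list(gp.baseline_phenotype_probs)
    probs = np.array([gp.baseline_phenotype_probs[k] for k in labels])
    if baseline_tcfa is True:
        labels, probs = ["TCFA"], np.array([1.0])
    elif baseline_tcfa is False:
        keep = [i for i, l in enumerate(labels) if l != "TCFA"]
        labels = [labels[i] for i in keep]
        probs = probs[keep]
        probs = probs / probs.sum()
    bl = rng.choice(labels, size=n, p=probs)
    fu = [ _fate_label(l, gp, gcfg.shared, rng) for l in bl ]
    return pd.DataFrame({"baseline_label": bl, "followup_label": fu})


_DRIFTABLE = ("PIT", "FP", "FcP", "ThCFA")


def _fate_label(bl_label: str, gp: GroupParams, shared: SharedParams,
                rng: np.random.Generator) -> str:
    if bl_label == "TCFA":
        if rng.random() < gp.persistent_tcfa_prob:
            return "TCFA"
        return "ThCFA"     # healed: NC-rich but cap criterion no longer met
    if rng.random() < gp.new_tcfa_prob:
        return "TCFA"
    if bl_label in _DRIFTABLE and rng.random() < shared.label_drift_prob:
        i = _DRIFTABLE.index(bl_label)
        j = int(np.clip(i + rng.choice([-1, 1]), 0, len(_DRIFTABLE) - 1))
        return _DRIFTABLE[j]
    return bl_label


# -- frame synthesis -------------------------------------------------------

def _patterns(n: int, focal: bool, rng: np.random.Generator):
    """Zero-mean relative variation patterns for EEM and plaque over a span.

    Focal spans carry a central lesion bump (EEM +7%, plaque +16% before
    centering) producing a positively remodeled MLA site; diffuse spans get
    a mild smooth ripple (remodeling index stays below the 1.05 cutoff).
    """
    k = np.arange(n)
    if focal and n >= 5:
        shape = np.exp(-0.5 * ((k - (n - 1) / 2) / (n / 6.0)) ** 2)
        eem = 0.07 * shape
        plq = 0.16 * shape
    else:
        phase = rng.uniform(0, 2 * np.pi)
        eem = 0.015 * np.sin(2 * np.pi * k / max(n, 2) + phase)
        plq = 0.015 * np.sin(2 * np.pi * k / max(n, 2) + phase + 0.7)
    return eem - eem.mean(), plq - plq.mean()


def _compose(label: str, plaque_mm2: float, in_run: bool, shared: SharedParams,
             rng: np.random.Generator):
    """Component areas + NC-lumen arc for one frame of an intended label."""
    template = _TEMPLATES["TCFA" if (label == "TCFA" and in_run) else
                          "ThCFA" if label == "TCFA" else label]
    noise = np.exp(rng.normal(0.0, _FRAC_NOISE_SD, size=4))
    frac = np.asarray(template) * noise
    frac = frac / frac.sum()
    areas = frac * shared.characterized_fraction * max(plaque_mm2, 0.0)
    if label == "TCFA" and in_run:
        arc = rng.uniform(40.0, 120.0)
    elif label in ("ThCFA", "TCFA"):
        arc = rng.uniform(0.0, 20.0)
    else:
        arc = 0.0
    if areas[2] == 0.0:
        arc = 0.0
    return areas, arc


def _tcfa_run(n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Candidate-run placement within an n-frame span, one frame of margin
    to each span edge so confirmed runs do not leak into neighbors."""
    max_len = max(3, min(7, n - 2))
    length = int(rng.integers(3, max_len + 1))
    lo, hi = 1, max(1, n - length - 1)
    start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    return start, start + length


def _span_frames(positions: np.ndarray, first_index: int, label: str,
                 mean_eem: float, mean_plaque: float, focal: bool,
                 shared: SharedParams, rng: np.random.Generator) -> list[Frame]:
    """Synthesize the frames of one segment span with exact span means."""
    n = len(positions)
    d_eem, d_plq = _patterns(n, focal, rng)
    eem = mean_eem * (1.0 + d_eem)
    plq = mean_plaque * (1.0 + d_plq)
    plq = np.minimum(plq, 0.98 * eem)
    run = _tcfa_run(n, rng) if label == "TCFA" and n >= 5 else (0, n) \
        if label == "TCFA" else (0, 0)
    frames = []
    for j in range(n):
        areas, arc = _compose(label, plq[j], run[0] <= j < run[1], shared, rng)
        frames.append(Frame(
            frame_index=first_index + j,
            axial_position_mm=float(positions[j]),
            lumen_csa_mm2=float(eem[j] - plq[j]),
            eem_csa_mm2=float(eem[j]),
            f_area_mm2=float(areas[0]),
            ff_area_mm2=float(areas[1]),
            nc_area_mm2=float(areas[2]),
            dc_area_mm2=float(areas[3]),
            nc_lumen_arc_deg=float(arc),
        ))
    return frames


def _truncnorm(dist: Dist, lo: float, hi: float,
               rng: np.random.Generator) -> float:
    for _ in range(64):
        x = rng.normal(dist.mean, dist.sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(dist.mean, lo, hi))


def _grid(x: float) -> float:
    return round(x / _SPACING) * _SPACING


def generate_patient(patient_id: str, group: str, gcfg: GeneratorConfig,
                     rng: np.random.Generator) -> PatientStudy:
    gp = gcfg.groups[group]
    shared = gcfg.shared

    length = max(gp.vessel_length_mm.mean + gp.vessel_length_mm.sd *
                 rng.standard_normal(), shared.min_length_mm)
    length = _grid(min(length, 120.0))
    n_seg = int(length // 5.0 + 1e-9)
    n_bl = int(round(length / _SPACING)) + 1
    bl_pos = np.arange(n_bl) * _SPACING

    mid_idx_bl = n_bl // 2
    mid_bl = bl_pos[mid_idx_bl]
    s1, s2 = rng.uniform(*shared.stretch_range, size=2)
    fu_mid = max(_grid(mid_bl * s1), _SPACING)
    fu_end = fu_mid + max(_grid((length - mid_bl) * s2), _SPACING)
    n_fu = int(round(fu_end / _SPACING)) + 1
    fu_pos = np.arange(n_fu) * _SPACING
    regmap_b = np.array([0.0, mid_bl, length])
    regmap_f = np.array([0.0, fu_mid, fu_end])

    def fu_of(x):
        return np.interp(x, regmap_b, regmap_f)

    # -- segment-level targets --------------------------------------------
    labels = rng.choice(list(gp.baseline_phenotype_probs),
                        size=n_seg,
                        p=list(gp.baseline_phenotype_probs.values()))
    fu_labels = [_fate_label(l, gp, shared, rng) for l in labels]
    frac = shared.patient_intercept_frac
    rho = gp.delta_plaque_vessel_correlation
    ic_p, ic_v = _corr_normal(1, rho, rng)[0] * frac
    z = _corr_normal(n_seg, rho, rng) * np.sqrt(1 - frac ** 2)
    d_plaque = gp.delta_plaque_area_mm2.mean + \
        gp.delta_plaque_area_mm2.sd * (ic_p + z[:, 0])
    d_vessel = gp.delta_vessel_area_mm2.mean + \
        gp.delta_vessel_area_mm2.sd * (ic_v + z[:, 1])
    focal = rng.random(n_seg) < shared.focal_segment_prob
    # vessel remodeling can progress between timepoints: lesions may develop
    # a positively remodeled focal profile (gain) or resolve one (loss)
    gain = rng.random(n_seg) < gp.remodeling_gain_prob
    loss = rng.random(n_seg) < gp.remodeling_loss_prob
    fu_focal = np.where(focal, ~loss, gain)

    bl_frames: list[Frame] = []
    fu_frames_by_seg: list[list[Frame]] = []
    realized_d_plaque = np.empty(n_seg)
    for i in range(n_seg):
        vessel = _truncnorm(gp.baseline_vessel_area_mm2, 8.0, 30.0, rng)
        if labels[i] == "NL":
            pav_bl = _truncnorm(Dist(30.0, 4.0), 18.0, _PAV_NL_CEIL, rng)
            focal[i] = False
        else:
            pav_bl = _truncnorm(gp.baseline_pav_pct, _PAV_LESION_FLOOR, 65.0,
                                rng)
        plaque_bl = vessel * pav_bl / 100.0
        plaque_fu = max(plaque_bl + d_plaque[i], 0.4)
        eem_fu = max(vessel + d_vessel[i], plaque_fu + 1.0)  # lumen >= 1 mm2
        pav_fu = 100.0 * plaque_fu / eem_fu
        # Label-consistency adjustment of the follow-up burden, done at
        # constant lumen (scaling plaque and EEM together) so the imposed
        # lumen change — the quantity the risk score sees — is untouched.
        if fu_labels[i] == "NL":
            target = float(np.clip(pav_fu, 15.0, _PAV_NL_CEIL))
        elif labels[i] == "NL":            # new lesion from a no-lesion base
            target = max(pav_fu, _PAV_LESION_FLOOR)
        else:
            target = float(np.clip(pav_fu, _PAV_FU_FLOOR, 70.0))
        if target != pav_fu:
            lumen_fu = eem_fu - plaque_fu
            eem_fu = lumen_fu / (1.0 - target / 100.0)
            plaque_fu = eem_fu - lumen_fu
            pav_fu = target
        realized_d_plaque[i] = plaque_fu - plaque_bl

        seg_bl_pos = bl_pos[(bl_pos >= 5.0 * i - 1e-9) &
                            (bl_pos < 5.0 * (i + 1) - 1e-9)]
        bl_frames.extend(_span_frames(
            seg_bl_pos, len(bl_frames), labels[i], vessel, plaque_bl,
            bool(focal[i]), shared, rng))

        fa, fb = fu_of(5.0 * i), fu_of(5.0 * (i + 1))
        seg_fu_pos = fu_pos[(fu_pos >= fa - 1e-9) & (fu_pos < fb - 1e-9)]
        fu_is_focal = bool(fu_focal[i]) and fu_labels[i] != "NL"
        fu_frames_by_seg.append(_span_frames(
            seg_fu_pos, 0, fu_labels[i], eem_fu, plaque_fu, fu_is_focal,
            shared, rng))

    # residual tails past the last full segment: no-lesion filler
    def _filler(positions, first_index):
        vessel = gp.baseline_vessel_area_mm2.mean
        return _span_frames(positions, first_index, "NL", vessel,
                            vessel * 0.32, False, shared, rng)

    tail_bl = bl_pos[bl_pos >= 5.0 * n_seg - 1e-9]
    if tail_bl.size:
        bl_frames.extend(_filler(tail_bl, len(bl_frames)))
    fu_frames: list[Frame] = []
    for seg in fu_frames_by_seg:
        for f in seg:
            f.frame_index = len(fu_frames)
            fu_frames.append(f)
    tail_fu = fu_pos[fu_pos >= fu_of(5.0 * n_seg) - 1e-9]
    if tail_fu.size:
        fu_frames.extend(_filler(tail_fu, len(fu_frames)))

    mid_idx_fu = int(round(fu_mid / _SPACING))
    study = PatientStudy(
        patient_id=patient_id,
        group=group,
        baseline=Pullback(bl_frames, 0, n_bl - 1, Timepoint.BASELINE,
                          vessel_id=patient_id),
        follow_up=Pullback(fu_frames, 0, n_fu - 1, Timepoint.FOLLOW_UP,
                           vessel_id=patient_id),
        landmark_pairs=[(0, 0), (mid_idx_bl, mid_idx_fu),
                        (n_bl - 1, n_fu - 1)],
        covariates={
            "ldl_baseline_mmol_l": gp.ldl_baseline_mmol_l.mean +
            gp.ldl_baseline_mmol_l.sd * rng.standard_normal(),
            "mean_delta_plaque_area_mm2": float(np.mean(realized_d_plaque)),
        },
    )
    study.validate()
    # generator ground truth for recovery tests (not serialized by io)
    study.intended_segment_labels = {
        "baseline": [str(l) for l in labels],
        "follow_up": [str(l) for l in fu_labels],
    }
    return study


def _attach_ldl_changes(studies: list[PatientStudy], gcfg: GeneratorConfig,
                        rng: np.random.Generator) -> None:
    """Draw LDLc changes correlated (per group) with each patient's mean
    plaque-area change, standardized within group."""
    for group, gp in gcfg.groups.items():
        members = [s for s in studies if s.group == group]
        if not members:
            continue
        pm = np.array([s.covariates["mean_delta_plaque_area_mm2"]
                       for s in members])
        z = (pm - pm.mean()) / pm.std() if pm.std() > 0 else np.zeros_like(pm)
        rho = gp.ldl_plaque_correlation
        eps = rng.standard_normal(len(members))
        draw = rho * z + np.sqrt(max(1 - rho ** 2, 0.0)) * eps
        for s, v in zip(members, draw):
            s.covariates["ldl_change_mmol_l"] = (
                gp.ldl_change_mmol_l.mean + gp.ldl_change_mmol_l.sd * float(v))
            s.covariates["ldl_followup_mmol_l"] = (
                s.covariates["ldl_baseline_mmol_l"] +
                s.covariates["ldl_change_mmol_l"])


def generate_cohort(gcfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> list[PatientStudy]:
    """Generate the full two-group cohort; reproducible from the seed."""
    gcfg = gcfg or default_generator_config()
    gcfg.validate()
    rng = np.random.default_rng(gcfg.seed if seed is None else seed)
    studies = []
    counter = 0
    for group in gcfg.groups:
        for _ in range(gcfg.groups[group].n_patients):
            counter += 1
            studies.append(generate_patient(f"P{counter:03d}", group, gcfg,
                                            rng))
    _attach_ldl_changes(studies, gcfg, rng)
    return studies
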