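import copy

import numpy as np
import pytest
import yaml
from hypothesis import settings

import plaquekit as pk
from plaquekit.model import Frame, PatientStudy, Pullback, Timepoint

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")

COHORT_SEED = 123


def make_frame(index=0, pos=None, lumen=8.0, eem=16.0, f=3.0, ff=1.0,
               nc=0.5, dc=0.5, arc=0.0):
    return Frame(
        frame_index=index,
        axial_position_mm=index * 0.5 if pos is None else pos,
        lumen_csa_mm2=lumen, eem_csa_mm2=eem,
        f_area_mm2=f, ff_area_mm2=ff, nc_area_mm2=nc, dc_area_mm2=dc,
        nc_lumen_arc_deg=arc,
    )


def make_uniform_pullback(n_frames, timepoint=Timepoint.BASELINE, lumen=8.0,
                          eem=16.0, spacing=0.5, vessel_id="V"):
    frames = [make_frame(i, pos=i * spacing, lumen=lumen, eem=eem)
              for i in range(n_frames)]
    return Pullback(frames, 0, n_frames - 1, timepoint, vessel_id=vessel_id)


def make_identity_study(length_mm=70.0, patient_id="P", group="DM",
                        fu_scale=1.0):
    """Minimal two-timepoint study with uniform fibrous-plaque frames and
    end-to-end landmarks; follow-up optionally stretched by fu_scale."""
    n_bl = int(round(length_mm / 0.5)) + 1
    bl = make_uniform_pullback(n_bl, Timepoint.BASELINE, vessel_id=patient_id)
    fu_len = round(length_mm * fu_scale / 0.5) * 0.5
    n_fu = int(round(fu_len / 0.5)) + 1
    fu = make_uniform_pullback(n_fu, Timepoint.FOLLOW_UP, vessel_id=patient_id)
    return PatientStudy(
        patient_id=patient_id, group=group, baseline=bl, follow_up=fu,
        landmark_pairs=[(0, 0), (n_bl - 1, n_fu - 1)],
    )


@pytest.fixture(scope="session")
def cfg():
    return pk.AnalysisConfig()


@pytest.fixture(scope="session")
def gcfg():
    return pk.default_generator_config()


@pytest.fixture(scope="session")
def small_gcfg(gcfg):
    """Scaled-down generator (5 patients, ~35 mm vessels) for fast
    integration tests."""
    from plaquekit.synthetic import Dist
    g = copy.deepcopy(gcfg)
    g.groups["DM"].n_patients = 2
    g.groups["non_DM"].n_patients = 3
    for gp in g.groups.values():
        gp.vessel_length_mm = Dist(35.0, 3.0)
    return g


@pytest.fixture(scope="session")
def default_cohort():
    return pk.generate_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return pk.run_study(default_cohort, seed=COHORT_SEED)
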