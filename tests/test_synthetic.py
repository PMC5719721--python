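"""Synthetic cohort generator: determinism, calibration and consistency
with the analysis pipeline."""

import numpy as np
import pytest

import plaquekit as pk
from plaquekit.errors import ConfigError, ValidationError
from plaquekit.synthetic import (GeneratorConfig, default_generator_config,
                                 generate_label_pairs, generate_segment_deltas)


class TestConfig:
    def test_defaults_load_and_validate(self, gcfg):
        gcfg.validate()
        assert gcfg.groups["DM"].n_patients == 17
        assert gcfg.groups["non_DM"].n_patients == 44

    def test_invalid_probability_rejected(self, gcfg):
        import copy
        bad = copy.deepcopy(gcfg)
        bad.groups["DM"].new_tcfa_prob = 1.4
        with pytest.raises(ConfigError):
            bad.validate()

    def test_phenotype_probs_must_sum_to_one(self, gcfg):
        import copy
        bad = copy.deepcopy(gcfg)
        bad.groups["DM"].baseline_phenotype_probs["TCFA"] = 0.9
        with pytest.raises(ConfigError):
            bad.validate()


class TestDeterminism:
    def test_bit_identical_cohorts(self, small_gcfg):
        a = pk.generate_cohort(small_gcfg, seed=42)
        b = pk.generate_cohort(small_gcfg, seed=42)
        for sa, sb in zip(a, b):
            assert sa.landmark_pairs == sb.landmark_pairs
            assert sa.covariates == sb.covariates
            assert sa.baseline.frames == sb.baseline.frames
            assert sa.follow_up.frames == sb.follow_up.frames


class TestCohortShape:
    def test_group_sizes(self, default_cohort):
        assert len(default_cohort) == 61
        assert sum(s.group == "DM" for s in default_cohort) == 17

    def test_dm_vessel_length_recovers_configured_mean(self, default_cohort,
                                                       gcfg):
        lengths = [s.baseline.analyzed_length_mm
                   for s in default_cohort if s.group == "DM"]
        dist = gcfg.groups["DM"].vessel_length_mm
        se = dist.sd / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - dist.mean) <= 2 * se

    def test_every_frame_satisfies_invariants(self, default_cohort):
        for s in default_cohort[::10]:
            s.validate()

    def test_landmarks_exercise_stretch(self, default_cohort):
        # at least one patient should have a genuinely non-identity mapping
        stretched = 0
        for s in default_cohort:
            (b0, f0), (b1, f1), (b2, f2) = s.landmark_pairs
            if (f1 - f0) != (b1 - b0) or (f2 - f1) != (b2 - b1):
                stretched += 1
        assert stretched > len(default_cohort) // 2


class TestSegmentDeltas:
    def test_zero_draws_rejected(self):
        with pytest.raises(ValidationError):
            generate_segment_deltas("DM", 0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigError):
            generate_segment_deltas("DM2", 5)

    def test_large_sample_mean_converges(self):
        df = generate_segment_deltas("DM", 100_000, seed=1)
        assert abs(df["delta_plaque_area_mm2"].mean() - 0.21) < 0.01
        assert abs(df["delta_pav_pct"].mean() - 0.7) < 0.03

    def test_patient_intercepts_induce_clustering(self):
        ids = np.repeat([f"p{i}" for i in range(20)], 50)
        df = generate_segment_deltas("DM", len(ids), seed=2, patient_ids=ids)
        patient_means = df.groupby("patient_id")["delta_plaque_area_mm2"].mean()
        # between-patient spread must exceed the i.i.d. expectation
        iid_sd = 0.97 * np.sqrt(1 - 0.3 ** 2) / np.sqrt(50)
        assert patient_means.std() > 1.5 * iid_sd


class TestLabelPairs:
    def test_non_tcfa_baseline_restriction(self):
        df = generate_label_pairs("DM", 300, seed=3, baseline_tcfa=False)
        assert not (df["baseline_label"] == "TCFA").any()

    def test_fate_rates_near_configuration(self, gcfg):
        n = 4000
        new = generate_label_pairs("DM", n, seed=4, baseline_tcfa=False)
        rate = (new["followup_label"] == "TCFA").mean()
        p = gcfg.groups["DM"].new_tcfa_prob
        assert abs(rate - p) <= 2 * np.sqrt(p * (1 - p) / n)
        persist = generate_label_pairs("DM", n, seed=5, baseline_tcfa=True)
        rate = (persist["followup_label"] == "TCFA").mean()
        p = gcfg.groups["DM"].persistent_tcfa_prob
        assert abs(rate - p) <= 2 * np.sqrt(p * (1 - p) / n)


class TestPipelineConsistency:
    def test_intended_labels_reproduced(self, default_cohort, default_result):
        """The phenotype classifier applied to generated frames recovers the
        generator's intended segment labels for >= 95% of segments."""
        seg = default_result.segments
        agree = total = 0
        for s in default_cohort:
            sub = seg[seg.patient_id == s.patient_id].sort_values(
                "segment_index")
            for tp, col in (("baseline", "baseline_label"),
                            ("follow_up", "followup_label")):
                intent = s.intended_segment_labels[tp]
                assert len(intent) == len(sub)
                agree += sum(a == b for a, b in zip(intent, sub[col]))
                total += len(intent)
        assert agree / total >= 0.95

    def test_pipeline_recovers_imposed_patient_deltas(self, default_cohort,
                                                      default_result):
        pat = default_result.patients.set_index("patient_id")
        for s in default_cohort[::7]:
            assert pat.loc[s.patient_id, "mean_delta_plaque_csa_mm2"] == \
                pytest.approx(s.covariates["mean_delta_plaque_area_mm2"],
                              abs=1e-9)
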