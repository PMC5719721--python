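"""Group-comparison statistics: exact small-sample checks and calibration."""

import numpy as np
import pandas as pd
import pytest

import plaquekit as pk
from plaquekit.errors import ConstantInputError, ValidationError
from plaquekit.stats import (compare_categorical, compare_numeric, correlate,
                             mixed_effect_group_test, paired_change_p)


class TestCompareNumeric:
    def test_identical_groups_mann_whitney(self):
        res = compare_numeric([1, 2, 3, 4], [1, 2, 3, 4], normality=False)
        assert res.test == "mann_whitney"
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_separated_groups_significant(self):
        res = compare_numeric([0, 0, 0, 0], [10, 10, 10, 10],
                              normality=False)
        assert res.p_value < 0.05

    def test_identical_groups_t(self):
        res = compare_numeric([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_numeric([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated(self):
        """Null rejection rate of the default (Welch) comparison at the
        study's group sizes stays near the nominal 5% level."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, size=17)
            b = rng.normal(0.0, 1.0, size=44)
            if compare_numeric(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestCompareCategorical:
    def test_homogeneous_table(self):
        assert compare_categorical([[5, 5], [5, 5]]).p_value == \
            pytest.approx(1.0)

    def test_perfect_separation(self):
        # exact hypergeometric: 2 * C(10,10)C(10,0)/C(20,10) = 2/184756
        res = compare_categorical([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / 184756, rel=1e-9)

    def test_zero_margin(self):
        assert compare_categorical([[0, 0], [3, 7]]).p_value == \
            pytest.approx(1.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            compare_categorical([[1.5, 2], [3, 4]])

    @pytest.mark.parametrize("table", [[[7, 2], [3, 9]], [[1, 0], [5, 5]]])
    def test_invariance_to_transpose_and_swaps(self, table):
        t = np.array(table)
        p = compare_categorical(t).p_value
        assert compare_categorical(t.T).p_value == pytest.approx(p)
        assert compare_categorical(t[::-1]).p_value == pytest.approx(p)
        assert compare_categorical(t[:, ::-1]).p_value == pytest.approx(p)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_generator_ldl_plaque_correlation(self, default_cohort):
        """Non-diabetic LDLc change correlates with mean plaque-area change
        at the configured strength (within 2 SE on the Fisher-z scale)."""
        sub = [s for s in default_cohort if s.group == "non_DM"]
        x = [s.covariates["ldl_change_mmol_l"] for s in sub]
        y = [s.covariates["mean_delta_plaque_area_mm2"] for s in sub]
        r, _ = correlate(x, y)
        z = np.arctanh(r)
        z_target = np.arctanh(0.47)
        assert abs(z - z_target) <= 2 / np.sqrt(len(sub) - 3)


class TestMixedEffect:
    def _df(self, a, b, patients_a, patients_b):
        return pd.DataFrame({
            "delta": np.concatenate([a, b]),
            "group": ["A"] * len(a) + ["B"] * len(b),
            "patient_id": list(patients_a) + list(patients_b),
        })

    def test_single_segment_patients_collapse_to_plain_contrast(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.5, 1.0, 20)
        df = self._df(a, b, [f"a{i}" for i in range(15)],
                      [f"b{i}" for i in range(20)])
        res = mixed_effect_group_test(df)
        assert res.estimate == pytest.approx(b.mean() - a.mean(), abs=1e-6)

    def test_null_calibration(self):
        """With no true group effect, |estimate| < 2 SE in >= 90% of
        simulated clustered cohorts."""
        rng = np.random.default_rng(7)
        ok = 0
        reps = 100
        for _ in range(reps):
            deltas = []
            patients = []
            groups = []
            for g, n_pat in (("A", 8), ("B", 12)):
                for p in range(n_pat):
                    intercept = rng.normal(0, 0.5)
                    for s in range(5):
                        deltas.append(intercept + rng.normal(0, 1.0))
                        patients.append(f"{g}{p}")
                        groups.append(g)
            df = pd.DataFrame({"delta": deltas, "group": groups,
                               "patient_id": patients})
            res = mixed_effect_group_test(df)
            if abs(res.estimate) < 2 * res.std_error:
                ok += 1
        assert ok >= 90

    def test_clustering_correction_not_anticonservative(self):
        """On strongly clustered data the mixed-model p must not undercut
        the naive segment-level t test."""
        rng = np.random.default_rng(3)
        a, b, pa, pb = [], [], [], []
        for p in range(6):
            a.extend(rng.normal(0, 1) + rng.normal(0, 0.05, 10))
            pa.extend([f"a{p}"] * 10)
        for p in range(6):
            b.extend(rng.normal(0.6, 1) + rng.normal(0, 0.05, 10))
            pb.extend([f"b{p}"] * 10)
        df = self._df(np.array(a), np.array(b), pa, pb)
        me = mixed_effect_group_test(df)
        naive = compare_numeric(a, b)
        assert me.p_value >= naive.p_value
        assert me.random_intercept_var > 0

    def test_variance_never_negative(self, default_result):
        seg = default_result.segments.rename(
            columns={"delta_plaque_csa_mm2": "delta"})
        res = mixed_effect_group_test(seg)
        assert res.random_intercept_var >= 0.0
        assert 0.0 <= res.p_value <= 1.0


class TestPairedChange:
    def test_no_change(self):
        assert paired_change_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_systematic_shift_detected(self):
        rng = np.random.default_rng(0)
        before = rng.normal(0, 1, 30)
        after = before + 1.0 + rng.normal(0, 0.1, 30)
        assert paired_change_p(before, after) < 1e-6
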