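"""Domain-type validation and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import plaquekit as pk
from plaquekit.config import AnalysisConfig
from plaquekit.errors import ConfigError, SchemaError, ValidationError
from plaquekit.io import (FRAME_COLUMNS, read_cohort, read_frame_table,
                          write_cohort, write_frame_table, write_results)
from plaquekit.model import Timepoint, validate_frame

from conftest import make_frame, make_uniform_pullback


def _csv(tmp_path, rows, columns=FRAME_COLUMNS, name="frames.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


VALID_ROWS = [
    [0, 0.0, 8.0, 16.0, 3.0, 1.0, 0.5, 0.5, 0.0],
    [1, 0.5, 8.1, 16.2, 3.0, 1.0, 0.5, 0.5, 10.0],
    [2, 1.0, 7.9, 15.8, 3.0, 1.0, 0.5, 0.5, 0.0],
]


class TestReadFrameTable:
    def test_well_formed_table(self, tmp_path):
        pb = read_frame_table(_csv(tmp_path, VALID_ROWS), Timepoint.BASELINE)
        assert len(pb.frames) == 3
        pos = [f.axial_position_mm for f in pb.frames]
        assert pos == sorted(pos)
        assert pb.distal_landmark_frame == 0
        assert pb.proximal_landmark_frame == 2

    def test_missing_column_names_it(self, tmp_path):
        cols = [c for c in FRAME_COLUMNS if c != "nc_area_mm2"]
        rows = [r[:6] + r[7:] for r in VALID_ROWS]
        with pytest.raises(SchemaError, match="nc_area_mm2"):
            read_frame_table(_csv(tmp_path, rows, cols), Timepoint.BASELINE)

    def test_lumen_exceeding_eem_rejected(self, tmp_path):
        rows = [r[:] for r in VALID_ROWS]
        rows[1][2], rows[1][3] = 9.0, 8.0
        with pytest.raises(ValidationError, match="lumen <= EEM"):
            read_frame_table(_csv(tmp_path, rows), Timepoint.BASELINE)

    def test_arc_without_necrotic_core_rejected(self, tmp_path):
        rows = [r[:] for r in VALID_ROWS]
        rows[1][6], rows[1][8] = 0.0, 45.0
        with pytest.raises(ValidationError, match="nc_lumen_arc_deg"):
            read_frame_table(_csv(tmp_path, rows), Timepoint.BASELINE)

    def test_positions_synthesized_from_spacing(self, tmp_path):
        cols = [c for c in FRAME_COLUMNS if c != "axial_position_mm"]
        rows = [r[:1] + r[2:] for r in VALID_ROWS]
        pb = read_frame_table(_csv(tmp_path, rows, cols), Timepoint.BASELINE,
                              frame_spacing_mm=0.5)
        assert [f.axial_position_mm for f in pb.frames] == [0.0, 0.5, 1.0]


class TestFrameInvariants:
    @pytest.mark.parametrize("kwargs,rule", [
        (dict(lumen=-1.0), "lumen"),
        (dict(nc=-0.1), "nc_area_mm2"),
        (dict(arc=400.0, nc=0.5), "0, 360"),
        (dict(f=9.0), "exceed plaque area"),
    ])
    def test_each_invariant_rejects(self, kwargs, rule):
        with pytest.raises(ValidationError, match=rule):
            validate_frame(make_frame(**kwargs))

    def test_non_monotone_positions_rejected(self):
        pb = make_uniform_pullback(4)
        pb.frames[2].axial_position_mm = 0.1
        with pytest.raises(ValidationError, match="axial_position_mm"):
            pb.validate()

    def test_landmark_order_enforced(self):
        pb = make_uniform_pullback(4)
        pb.distal_landmark_frame, pb.proximal_landmark_frame = 3, 0
        with pytest.raises(ValidationError, match="distal"):
            pb.validate()


class TestRoundTrips:
    def test_frame_table_round_trip(self, tmp_path):
        pb = make_uniform_pullback(5)
        pb.frames[2].nc_area_mm2 = 0.123456789123
        write_frame_table(pb, tmp_path / "pb.csv")
        back = read_frame_table(tmp_path / "pb.csv", Timepoint.BASELINE)
        for a, b in zip(pb.frames, back.frames):
            assert a.frame_index == b.frame_index
            assert a.nc_area_mm2 == pytest.approx(b.nc_area_mm2, abs=1e-9)

    def test_cohort_round_trip(self, tmp_path, small_gcfg):
        cohort = pk.generate_cohort(small_gcfg, seed=3)
        manifest = write_cohort(cohort, tmp_path / "cohort")
        back = read_cohort(manifest)
        assert [s.patient_id for s in back] == [s.patient_id for s in cohort]
        for a, b in zip(cohort, back):
            assert a.group == b.group
            assert a.landmark_pairs == b.landmark_pairs
            assert len(a.baseline.frames) == len(b.baseline.frames)
            for fa, fb in zip(a.follow_up.frames, b.follow_up.frames):
                assert fa.eem_csa_mm2 == pytest.approx(fb.eem_csa_mm2, abs=1e-9)
            for key, val in a.covariates.items():
                assert b.covariates[key] == pytest.approx(val, abs=1e-9)

    @given(st.lists(
        st.tuples(st.floats(1.0, 20.0), st.floats(0.0, 0.9),
                  st.floats(0.0, 1.0), st.floats(0.0, 360.0)),
        min_size=2, max_size=8))
    def test_random_frames_round_trip(self, tmp_path_factory, specs):
        frames = []
        for i, (eem, burden, comp, arc) in enumerate(specs):
            plaque = eem * burden
            frames.append(pk.Frame(
                frame_index=i, axial_position_mm=0.5 * i,
                lumen_csa_mm2=eem - plaque, eem_csa_mm2=eem,
                f_area_mm2=plaque * comp * 0.5, ff_area_mm2=plaque * comp * 0.2,
                nc_area_mm2=plaque * comp * 0.2, dc_area_mm2=plaque * comp * 0.1,
                nc_lumen_arc_deg=arc if plaque * comp > 0 else 0.0))
        pb = pk.Pullback(frames, 0, len(frames) - 1, Timepoint.BASELINE)
        pb.validate()
        path = tmp_path_factory.mktemp("rt") / "pb.csv"
        write_frame_table(pb, path)
        back = read_frame_table(path, Timepoint.BASELINE)
        for a, b in zip(pb.frames, back.frames):
            for attr in ("lumen_csa_mm2", "eem_csa_mm2", "nc_area_mm2",
                         "nc_lumen_arc_deg"):
                assert getattr(a, attr) == pytest.approx(getattr(b, attr),
                                                         abs=1e-9)


class TestWriteResults:
    def test_empty_table_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["a", "b"])
        manifest = write_results({"per_segment": df}, tmp_path)
        assert manifest["row_counts"]["per_segment"] == 0
        lines = (tmp_path / "per_segment.csv").read_text().strip().splitlines()
        assert lines == ["a,b"]

    def test_segment_count_in_manifest(self, tmp_path):
        df = pd.DataFrame({"segment_index": range(698),
                           "pav_pct": np.linspace(30, 60, 698)})
        manifest = write_results({"per_segment": df}, tmp_path)
        assert manifest["row_counts"]["per_segment"] == 698

    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"i": np.arange(50), "x": rng.normal(size=50)})
        write_results({"t": df}, tmp_path)
        back = pd.read_csv(tmp_path / "t.csv")
        assert (back["i"] == df["i"]).all()
        assert np.allclose(back["x"], df["x"], atol=1e-9)


class TestConfig:
    def test_yaml_round_trip_lossless(self, tmp_path):
        cfg = AnalysisConfig(nc_arc_contact_deg=1.0, min_overlap_mm=30.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert AnalysisConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    @pytest.mark.parametrize("kwargs", [
        dict(segment_length_mm=-5.0),
        dict(segment_length_mm=0.4),        # below frame spacing
        dict(composition_tolerance_frac=-0.1),
        dict(min_overlap_mm=2.0),           # below one segment
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            AnalysisConfig(**kwargs)
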