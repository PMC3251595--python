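"""Round-trip and validation behaviour of the plate I/O layer."""

import math

import pytest

from arqiv.normalization import SubjectTimeCourse, TimeCoursePoint
from arqiv.plate_io import (
    Channel,
    FormatError,
    PlateLayout,
    ScanGrid,
    ScanSession,
    ValidationError,
    WellAssignment,
    dpf_to_hpf,
    normalize_well_id,
    read_layout,
    read_regional_export,
    read_tidy,
    write_layout,
    write_regional_export,
    write_tidy,
)


class TestScanGrid:
    def test_rejects_wrong_value_count(self):
        with pytest.raises(ValidationError, match="expected 4 regional values"):
            ScanGrid("A1", "s1", Channel("YFP"), 2, [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("bad", [-3.0, float("nan"), float("inf")])
    def test_rejects_invalid_rfu_citing_region(self, bad):
        with pytest.raises(ValidationError, match=r"region \(1,0\)"):
            ScanGrid("B2", "s1", Channel("YFP"), 2, [1.0, 2.0, bad, 4.0])

    @pytest.mark.parametrize("n", [0, 8])
    def test_pattern_range(self, n):
        with pytest.raises(ValidationError, match="pattern_n"):
            ScanGrid("A1", "s1", Channel("YFP"), n, [1.0] * max(n * n, 1))

    def test_row_major_indexing(self, make_grid):
        g = make_grid([0.0, 1.0, 2.0, 3.0])
        assert g.value_at(0, 1) == 1.0
        assert g.value_at(1, 0) == 2.0

    @pytest.mark.parametrize("raw,norm", [("a01", "A1"), ("H12", "H12"), (" b3 ", "B3")])
    def test_well_id_normalization(self, raw, norm):
        assert normalize_well_id(raw) == norm

    def test_dpf_conversion_at_boundary(self):
        assert dpf_to_hpf(5) == 120.0


class TestLayout:
    def _assignments(self, n_neg=2, n_treated=2):
        out = {}
        for i in range(n_neg):
            out[f"A{i + 1}"] = WellAssignment(f"neg-{i}", "NEGATIVE_CONTROL")
        for i in range(n_treated):
            out[f"B{i + 1}"] = WellAssignment(f"fish-{i}", "TREATED", condition="drug")
        return out

    def test_valid_layout(self):
        layout = PlateLayout("P1", self._assignments())
        assert layout.wells_in_group("NEGATIVE_CONTROL") == ["A1", "A2"]
        assert not layout.warnings

    def test_duplicate_subject_rejected(self):
        a = self._assignments()
        a["C1"] = WellAssignment("fish-0", "TREATED")
        with pytest.raises(ValidationError, match="fish-0"):
            PlateLayout("P1", a)

    def test_unknown_group_lists_allowed(self):
        with pytest.raises(ValidationError, match="NEGATIVE_CONTROL"):
            WellAssignment("s", "MYSTERY_GROUP")

    def test_no_negative_controls_warns(self):
        layout = PlateLayout(
            "P1", {"A1": WellAssignment("s1", "TREATED", condition="x")}
        )
        assert any("NEGATIVE_CONTROL" in w for w in layout.warnings)

    def test_layout_yaml_round_trip(self, tmp_path):
        layout = PlateLayout("P1", self._assignments())
        path = tmp_path / "layout.yaml"
        write_layout(layout, path)
        back = read_layout(path)
        assert back.plate_id == "P1"
        assert back.assignments == layout.assignments

    def test_duplicate_well_in_file_rejected(self, tmp_path):
        path = tmp_path / "layout.yaml"
        path.write_text(
            "plate_id: P1\nwells:\n"
            "  A1: {subject: s1, group: TREATED, condition: x}\n"
            "  a01: {subject: s2, group: TREATED, condition: x}\n"
        )
        with pytest.raises(ValidationError, match="A1"):
            read_layout(path)


class TestRegionalExport:
    def _session(self, make_grid, pattern=2):
        values = list(range(1, pattern * pattern + 1))
        grids = [
            make_grid([float(v) for v in values], well="A1", subject="s1"),
            make_grid([float(v * 10) for v in values], well="A2", subject="s2"),
        ]
        return ScanSession("S1", 48.0, grids)

    def test_round_trip_preserves_row_major_order(self, tmp_path, make_grid):
        # asymmetric values so any ordering mistake is visible
        session = self._session(make_grid)
        path = tmp_path / "export.csv"
        write_regional_export([session], path)
        back = read_regional_export(path)
        assert len(back) == 1 and len(back[0].grids) == 2
        g = next(g for g in back[0].grids if g.well_id == "A1")
        assert g.values == [1.0, 2.0, 3.0, 4.0]
        assert g.subject_id == "s1"

    @pytest.mark.parametrize("pattern_n", range(1, 8))
    def test_round_trip_all_patterns(self, tmp_path, make_grid, pattern_n):
        values = [float(i) for i in range(pattern_n**2)]
        session = ScanSession("S1", 0.0, [make_grid(values)])
        path = tmp_path / "export.csv"
        write_regional_export([session], path)
        (back,) = read_regional_export(path)
        assert back.grids[0].values == values

    def test_single_value_plate(self, tmp_path, make_grid):
        grids = [
            make_grid([float(i)], well=f"{row}{col}", subject=f"s{row}{col}")
            for i, (row, col) in enumerate(
                (r, c) for r in "ABCDEFGH" for c in range(1, 13)
            )
        ]
        path = tmp_path / "export.csv"
        write_regional_export([ScanSession("S1", 0.0, grids)], path)
        (back,) = read_regional_export(path)
        assert len(back.grids) == 96
        assert all(g.pattern_n == 1 for g in back.grids)

    def test_negative_value_cites_well_and_region(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "session_id,timepoint_hpf,well,subject_id,channel,replicate,"
            "pattern_n,region_row,region_col,value_rfu\n"
            "S1,0.0,A1,s1,YFP,1,1,0,0,-3.0\n"
        )
        with pytest.raises(ValidationError, match=r"A1 region \(0,0\)"):
            read_regional_export(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("well,value_rfu\nA1,5.0\n")
        with pytest.raises(FormatError, match="region_row"):
            read_regional_export(path)

    def test_incomplete_grid_rejected(self, tmp_path):
        header = (
            "session_id,timepoint_hpf,well,subject_id,channel,replicate,"
            "pattern_n,region_row,region_col,value_rfu\n"
        )
        rows = "S1,0.0,A1,s1,YFP,1,2,0,0,5.0\nS1,0.0,A1,s1,YFP,1,2,0,1,6.0\n"
        path = tmp_path / "bad.csv"
        path.write_text(header + rows)
        with pytest.raises(ValidationError, match="incomplete"):
            read_regional_export(path)


class TestTidy:
    def _course(self, subject="s1", flags=()):
        return SubjectTimeCourse(
            subject_id=subject,
            group="TREATED",
            channel="YFP",
            condition="MTZ",
            points=[
                TimeCoursePoint("S1", 120.0, 5000.123456789, 1, "DIRECT", 100.0, 100.0, tuple(flags)),
                TimeCoursePoint("S2", 144.0, 500.987654321, 1, "DIRECT", 10.01923456, 9.87654321, tuple(flags)),
                TimeCoursePoint("S3", 192.0, 1500.5, 1, "DIRECT", 30.0, 29.5, tuple(flags)),
            ],
        )

    def test_cardinality(self, tmp_path):
        path = tmp_path / "tidy.tsv"
        write_tidy([self._course("s1"), self._course("s2")], path)
        assert sum(1 for _ in open(path)) == 1 + 6

    def test_round_trip_full_precision(self, tmp_path):
        path = tmp_path / "tidy.tsv"
        original = [self._course()]
        write_tidy(original, path)
        (back,) = read_tidy(path)
        for p0, p1 in zip(original[0].points, back.points):
            assert p1.total_signal == p0.total_signal  # exact, not approx
            assert p1.normalized_pct == p0.normalized_pct
            assert p1.corrected_pct == p0.corrected_pct

    def test_flags_carried_verbatim(self, tmp_path):
        path = tmp_path / "tidy.tsv"
        write_tidy([self._course(flags=("BELOW_DETECTION_BASELINE", "EXCLUDED"))], path)
        (back,) = read_tidy(path)
        assert back.points[0].flags == ("BELOW_DETECTION_BASELINE", "EXCLUDED")

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_tidy([], tmp_path / "tidy.tsv")
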