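"""Marks reading, grid assignment, count tables, consensus means and agreement."""

from __future__ import annotations

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from remotepop.structure_marks import (
    GridSpec,
    MarksError,
    StructureMark,
    assign_grid_cells,
    consensus_mean_count,
    pairwise_agreement,
    read_marks,
    residential_agreement,
    tabulate_counts,
)


def mark(x=0.0, y=0.0, analyst="A", category="hut", residential=True):
    return StructureMark(x=x, y=y, analyst_id=analyst, category=category, residential=residential)


class TestReadMarks:
    def test_geojson_read_through(self, geojson_marks, category_map):
        marks = read_marks(geojson_marks, category_map=category_map)
        assert len(marks) == 3
        assert sum(m.residential for m in marks) == 2
        assert {m.analyst_id for m in marks} == {"A"}

    def test_empty_collection(self, tmp_path, category_map):
        p = tmp_path / "empty.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        assert read_marks(p, category_map=category_map) == []

    def test_missing_category_names_feature(self, tmp_path, category_map):
        doc = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0, 0]},
             "properties": {"analyst_id": "A"}},
        ]}
        p = tmp_path / "bad.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(MarksError, match="feature 0.*category"):
            read_marks(p, category_map=category_map)

    def test_unknown_category_named(self, tmp_path, category_map):
        p = tmp_path / "marks.csv"
        p.write_text("x,y,analyst_id,category\n1,2,A,warehouse\n")
        with pytest.raises(MarksError, match="warehouse"):
            read_marks(p, category_map=category_map)

    def test_csv_roundtrip_matches_geojson(self, tmp_path, category_map):
        p = tmp_path / "marks.csv"
        p.write_text("x,y,analyst_id,category\n10,20,A,hut\n50,60,B,latrine\n")
        marks = read_marks(p, category_map=category_map)
        assert [(m.analyst_id, m.residential) for m in marks] == [("A", True), ("B", False)]


class TestGrid:
    grid = GridSpec(x0=0.0, y0=0.0, n_cols=5, n_rows=5, cell_size=200.0)

    @pytest.mark.parametrize(
        "xy,cell",
        [((0.0, 0.0), (0, 0)),       # lower edge belongs to its own cell
         ((200.0, 0.0), (1, 0)),     # upper edge falls into the next cell
         ((399.9, 250.0), (1, 1))],  # floor((399.9)/200)=1, floor(250/200)=1
    )
    def test_half_open_cells(self, xy, cell):
        [m] = assign_grid_cells([mark(*xy)], self.grid)
        assert m.grid_cell == cell

    def test_strict_policy_reports_coordinates(self):
        with pytest.raises(MarksError, match=r"\(1500.0, 0.0\)"):
            assign_grid_cells([mark(1500.0, 0.0)], self.grid, policy="strict")

    def test_flag_policy_leaves_cell_unset(self):
        [m] = assign_grid_cells([mark(1500.0, 0.0)], self.grid, policy="flag")
        assert m.grid_cell is None

    @given(st.lists(st.tuples(st.floats(0, 999.999), st.floats(0, 999.999)), max_size=60))
    def test_grid_partition_conserves_counts(self, points):
        marks = [mark(x, y) for x, y in points]
        assigned = assign_grid_cells(marks, self.grid)
        assert all(m.grid_cell is not None for m in assigned)
        table = tabulate_counts(assigned)
        for analyst, cells in table.by_cell.items():
            assert sum(cells.values()) == table.per_analyst[analyst].total_count


class TestTabulate:
    def test_residential_other_total_rollup(self):
        marks = (
            [mark(analyst="1", category="hut")] * 371
            + [mark(analyst="1", category="latrine", residential=False)] * 440
        )
        table = tabulate_counts(marks)
        c = table.per_analyst["1"]
        assert (c.residential_count, c.other_count, c.total_count) == (371, 440, 811)

    def test_empty_input_zero_table(self):
        table = tabulate_counts([])
        assert table.per_analyst == {}
        assert table.residential_counts() == []

    def test_two_analysts_split(self):
        marks = [mark(analyst="A")] * 3 + [mark(analyst="B")] * 2
        table = tabulate_counts(marks)
        assert table.residential_counts() == [3, 2]

    @given(st.lists(st.tuples(st.sampled_from("AB"), st.booleans()), max_size=80))
    def test_total_conservation(self, spec):
        marks = [mark(analyst=a, category="hut" if r else "latrine", residential=r) for a, r in spec]
        for c in tabulate_counts(marks).per_analyst.values():
            assert c.total_count == c.residential_count + c.other_count


class TestConsensusMean:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1501, 1380), 1441),   # 1440.5 rounds up
         ((371, 371), 371),
         ((1643, 1194), 1419),   # 1418.5 rounds away from zero, not to even
         ((3708,), 3708)],       # single-analyst site
    )
    def test_examples(self, counts, expected):
        assert consensus_mean_count(counts) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            consensus_mean_count([])

    @given(st.lists(st.integers(0, 10**6), min_size=1, max_size=6))
    def test_exact_when_sum_divisible(self, counts):
        if sum(counts) % len(counts) == 0:
            assert consensus_mean_count(counts) == sum(counts) // len(counts)


class TestAgreement:
    @pytest.mark.parametrize(
        "a,b,diff,pct",
        [(4181, 3466, 715, 17.1),
         (2, 129, 127, 98.4),
         (70, 0, 70, 100.0),
         (0, 0, 0, 0.0),
         (2500, 2604, 104, 4.0)],
    )
    def test_examples(self, a, b, diff, pct):
        r = pairwise_agreement(a, b)
        assert (r.absolute_difference, r.relative_pct) == (diff, pct)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            pairwise_agreement(-1, 5)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_symmetry_and_bounds(self, a, b):
        r, s = pairwise_agreement(a, b), pairwise_agreement(b, a)
        assert r == s
        assert 0.0 <= r.relative_pct <= 100.0
        if a == b:
            assert r.relative_pct == 0.0

    def test_comparable_area_override(self):
        marks = [mark(analyst="A")] * 10 + [mark(analyst="B")] * 6
        table = tabulate_counts(marks)
        raw = residential_agreement(table)
        adj = residential_agreement(table, comparable_area_overrides={"A": 8})
        assert raw.absolute_difference == 4
        assert adj.absolute_difference == 2
        assert adj.relative_pct == 25.0
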