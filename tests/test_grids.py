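"""Raster I/O, stack alignment and point extraction."""

import numpy as np
import pytest

from conftest import make_grid, make_stack
from monarchniche.grids import (AlignmentError, Grid, GridFormatError,
                                LayerName, LayerStack, OutOfExtentError,
                                extract_values, load_stack, read_ascii_grid,
                                read_occurrences, write_ascii_grid,
                                write_occurrences)


class TestAsciiGrid:
    def test_parse_2x2(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2\n3 4\n")
        g = read_ascii_grid(p)
        assert g.values[0].tolist() == [1, 2]  # northern row first
        assert g.values[1].tolist() == [3, 4]

    def test_xllcenter_normalized_to_corner(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 1\nnrows 1\nxllcenter 10\nyllcenter 20\n"
                     "cellsize 2\nNODATA_value -9999\n5\n")
        g = read_ascii_grid(p)
        assert g.xllcorner == 9.0
        assert g.yllcorner == 19.0

    def test_cell_count_mismatch_is_dimension_error(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n1 2\n3 4\n")
        with pytest.raises(GridFormatError, match="6 cell values"):
            read_ascii_grid(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text("ncols two\nnrows 2\n")
        with pytest.raises(GridFormatError, match="line 1"):
            read_ascii_grid(p)

    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        # values representable at the writer's 6-significant-digit precision
        values = np.round(rng.uniform(-50, 50, size=(10, 10)), 3)
        g = make_grid(values, cellsize=0.25, xll=-120.625, yll=33.5)
        p = tmp_path / "rt.asc"
        write_ascii_grid(g, p)
        assert read_ascii_grid(p) == g

    def test_round_trip_preserves_nodata_and_negative_corner(self, tmp_path):
        g = make_grid([[1.0, -9999.0], [3.0, 4.0]], xll=-118.123456789)
        p = tmp_path / "nd.asc"
        write_ascii_grid(g, p)
        back = read_ascii_grid(p)
        assert back.xllcorner == -118.123456789
        assert back.values[0, 1] == -9999.0
        assert back.valid_mask().sum() == 3


class TestStack:
    def test_load_full_monthly_stack(self, tmp_path):
        paths = {}
        for var in ("tmin", "tmax", "precipitation"):
            for month in ("Oct", "Nov", "Dec", "Jan", "Feb"):
                name = f"{var}_{month}"
                p = tmp_path / f"{name}.asc"
                write_ascii_grid(make_grid([[1.0, 2.0], [3.0, 4.0]]), p)
                paths[name] = p
        stack = load_stack(paths)
        assert len(stack) == 15

    def test_alignment_error_lists_fields(self, tmp_path):
        a = make_grid([[1.0]], cellsize=1.0)
        b = make_grid([[1.0]], cellsize=2.0)
        with pytest.raises(AlignmentError, match="cellsize"):
            LayerStack({LayerName.parse("tmin_Jan"): a,
                        LayerName.parse("tmin_Feb"): b})

    def test_valid_mask_is_intersection(self):
        stack = make_stack(tmin_Jan=[[1.0, -9999.0]],
                           tmin_Feb=[[-9999.0, 2.0]])
        assert stack.valid_mask().sum() == 0

    def test_bad_layer_name_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            LayerName.parse("humidity_Jan")


class TestCellIndexing:
    @pytest.mark.parametrize("lon,lat,row,col", [
        (0.5, 1.5, 0, 0),    # cell centers
        (1.5, 0.5, 1, 1),
        (0.0, 2.0, 0, 0),    # top-left corner belongs to cell (0, 0)
        (1.0, 1.0, 1, 1),    # interior shared corner -> east/south cell
    ])
    def test_half_open_convention(self, lon, lat, row, col):
        g = make_grid(np.arange(4.0).reshape(2, 2))
        assert g.cell_index(lon, lat) == (row, col)

    @pytest.mark.parametrize("lon,lat", [(2.0, 1.0), (1.0, 0.0), (-0.1, 1.0)])
    def test_bottom_right_boundary_out_of_extent(self, lon, lat):
        g = make_grid(np.arange(4.0).reshape(2, 2))
        with pytest.raises(OutOfExtentError):
            g.cell_index(lon, lat)


class TestExtract:
    def test_center_and_hand_indexed_values(self):
        stack = make_stack(tmin_Jan=[[10.0, 20.0], [30.0, 40.0]])
        values, valid = extract_values(stack, [(0.5, 1.5), (1.25, 0.75)])
        # (1.25, 0.75) -> row floor((2-0.75)/1)=1, col floor(1.25)=1
        assert values[:, 0].tolist() == [10.0, 40.0]
        assert valid.all()

    def test_nodata_point_flagged(self):
        stack = make_stack(tmin_Jan=[[10.0, -9999.0]])
        values, valid = extract_values(stack, [(1.5, 0.5)])
        assert not valid[0]
        assert np.isnan(values[0, 0])

    def test_out_of_extent_reports_point_index(self):
        stack = make_stack(tmin_Jan=[[10.0, 20.0]])
        with pytest.raises(OutOfExtentError, match="point 1"):
            extract_values(stack, [(0.5, 0.5), (5.0, 0.5)])

    def test_layer_order_permutes_columns(self):
        a, b = [[1.0, 2.0]], [[5.0, 6.0]]
        s1 = make_stack(tmin_Jan=a, tmax_Jan=b)
        s2 = make_stack(tmax_Jan=b, tmin_Jan=a)
        pts = [(0.5, 0.5), (1.5, 0.5)]
        v1, _ = extract_values(s1, pts)
        v2, _ = extract_values(s2, pts)
        assert np.array_equal(v1, v2[:, ::-1])


class TestOccurrenceCsv:
    def test_read_three_rows(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("grove_id,lon,lat,occupied\nG1,1.0,2.0,true\n"
                     "G2,1.5,2.5,false\nG3,2.0,3.0,1\n")
        recs = read_occurrences(p)
        assert [r.grove_id for r in recs] == ["G1", "G2", "G3"]
        assert [r.occupied for r in recs] == [True, False, True]

    def test_missing_occupied_defaults_true(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("grove_id,lon,lat\nG1,1.0,2.0\n")
        assert read_occurrences(p)[0].occupied is True

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("grove_id,lon,lat\n")
        assert read_occurrences(p) == []

    def test_bad_coordinate_reports_row(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("grove_id,lon,lat\nG1,1.0,2.0\nG2,east,2.0\n")
        with pytest.raises(GridFormatError, match="row 3"):
            read_occurrences(p)

    def test_write_read_round_trip(self, tmp_path):
        from monarchniche.grids import OccurrenceRecord
        recs = [OccurrenceRecord("G1", 1.25, 2.5, True),
                OccurrenceRecord("G2", -120.123, 34.5, False)]
        p = tmp_path / "occ.csv"
        write_occurrences(recs, p)
        assert read_occurrences(p) == recs
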