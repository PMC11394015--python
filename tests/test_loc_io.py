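import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from azstorm.loc_io import (FormatError, RoiSet,
                            crop_to_rois, filter_min_intensity, image_summary,
                            read_localizations, read_rois,
                            render_binned_image, write_localizations,
                            write_rois)
from conftest import make_table


class TestReadWrite:
    def test_generic_csv_three_records(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("x_nm,y_nm,frame,intensity\n"
                     "10.5,20.5,0,4000\n1.25,3.5,1,5000\n7.0,8.0,2,6000\n")
        t = read_localizations(p, "generic-csv")
        assert len(t) == 3
        assert t.data.loc[0, "x"] == 10.5
        assert t.data["frame"].tolist() == [0, 1, 2]

    def test_header_only_file_is_valid_and_empty(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("x,y,frame,intensity\n")
        assert len(read_localizations(p, "generic-csv")) == 0

    @pytest.mark.parametrize("dialect", ["generic-csv", "rapidstorm-txt"])
    def test_round_trip_bit_identical(self, tmp_path, rng, dialect):
        n = 200
        t = make_table(rng.uniform(0, 2e4, n), rng.uniform(0, 2e4, n),
                       rng.integers(0, 15000, n), rng.lognormal(9, 0.4, n))
        ext = "csv" if dialect == "generic-csv" else "txt"
        p = tmp_path / f"t.{ext}"
        write_localizations(t, p, dialect)
        back = read_localizations(p, dialect, source_id=t.source_id)
        pd.testing.assert_frame_equal(t.data, back.data, check_exact=True)
        # a second write is byte-identical
        p2 = tmp_path / f"t2.{ext}"
        write_localizations(back, p2, dialect)
        assert p.read_bytes() == p2.read_bytes()

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x,y,frame\n1,2,0\n")
        with pytest.raises(FormatError, match="intensity"):
            read_localizations(p, "generic-csv")

    def test_non_numeric_cell_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x,y,frame,intensity\n1,2,0,5000\n3,oops,1,6000\n")
        with pytest.raises(FormatError, match="line 3"):
            read_localizations(p, "generic-csv")

    def test_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "locs.csv"
        p.write_text("x,y,frame,intensity,uncertainty\n1,2,0,5000,9.9\n")
        t = read_localizations(p, "generic-csv")
        assert t.data.loc[0, "uncertainty"] == 9.9

    def test_frame_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            make_table([1.0], [1.0], [20000], [5000.0], n_frames=15000)


class TestFilters:
    def test_min_intensity_boundary_inclusive(self):
        t = make_table([0, 1, 2], [0, 0, 0], [0, 0, 0], [999, 1000, 1001])
        kept = filter_min_intensity(t, 1000)
        assert len(kept) == 2
        assert kept.data["intensity"].min() == 1000

    def test_min_adc_zero_is_identity(self, small_table):
        out = filter_min_intensity(small_table, 0)
        pd.testing.assert_frame_equal(out.data, small_table.data)

    def test_crop_unit_square(self):
        t = make_table([0.5, 2.0], [0.5, 2.0], [0, 0], [5e3, 5e3])
        roi = RoiSet([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])])
        assert len(crop_to_rois(t, roi)) == 1

    def test_crop_full_field_identity(self, small_table):
        roi = RoiSet([Polygon([(0, 0), (1e4, 0), (1e4, 1e4), (0, 1e4)])])
        out = crop_to_rois(small_table, roi)
        pd.testing.assert_frame_equal(out.data, small_table.data)

    def test_crop_boundary_point_is_inside(self):
        t = make_table([1.0], [0.5], [0], [5e3])
        roi = RoiSet([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])])
        assert len(crop_to_rois(t, roi)) == 1

    def test_crop_matches_ray_casting_oracle(self, rng):
        poly = [(2.0, 1.0), (8.0, 0.5), (9.0, 6.0), (4.5, 9.0), (1.0, 5.0)]
        n = 300
        x, y = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
        t = make_table(x, y, np.zeros(n, int), np.full(n, 5e3))
        kept = crop_to_rois(t, RoiSet([Polygon(poly)]))
        got = set(map(tuple, kept.data[["x", "y"]].to_numpy()))

        def ray_cast(px, py):
            inside = False
            m = len(poly)
            for i in range(m):
                (x1, y1), (x2, y2) = poly[i], poly[(i + 1) % m]
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        inside = not inside
            return inside

        expect = {(px, py) for px, py in zip(x, y) if ray_cast(px, py)}
        assert got == expect

    def test_crop_idempotent(self, rng):
        n = 100
        t = make_table(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                       np.zeros(n, int), np.full(n, 5e3))
        roi = RoiSet([Polygon([(2, 2), (8, 2), (8, 8), (2, 8)])])
        once = crop_to_rois(t, roi)
        twice = crop_to_rois(once, roi)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_too_many_polygons_rejected(self):
        square = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(ValueError, match="maximum"):
            RoiSet([square] * 7)

    def test_roi_round_trip(self, tmp_path):
        rois = RoiSet([Polygon([(0, 0), (100, 0), (100, 100)]),
                       Polygon([(200.5, 200.25), (300, 200), (250, 320)])])
        p = tmp_path / "rois.csv"
        write_rois(rois, p)
        back = read_rois(p)
        assert len(back) == 2
        for a, b in zip(rois.polygons, back.polygons):
            assert a.equals(b)


class TestRendering:
    def test_single_localization(self):
        t = make_table([5.0], [5.0], [0], [5e3])
        img = render_binned_image(t, 10.0)
        assert img.shape == (1, 1) and img[0, 0] == 1

    def test_counts_conserved(self, rng):
        n = 500
        t = make_table(rng.uniform(0, 500, n), rng.uniform(0, 500, n),
                       np.zeros(n, int), np.full(n, 5e3))
        for p in (7.0, 10.0, 33.3):
            assert render_binned_image(t, p).sum() == n

    def test_matches_histogram2d_oracle(self, rng):
        n = 1000
        x, y = rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)
        t = make_table(x, y, np.zeros(n, int), np.full(n, 5e3))
        img = render_binned_image(t, 10.0)
        edges = np.arange(0, img.shape[0] * 10.0 + 10.0, 10.0)
        oracle, _, _ = np.histogram2d(y, x, bins=(edges[:img.shape[0] + 1],
                                                  edges[:img.shape[1] + 1]))
        assert np.array_equal(img, oracle.astype(int))

    def test_empty_table_no_exception(self):
        t = make_table([], [], [], [])
        assert render_binned_image(t, 10.0).size == 0
        assert render_binned_image(t, 10.0, shape=(5, 5)).sum() == 0


class TestImageSummary:
    def test_locs_per_100_frames(self):
        t = make_table(np.zeros(150), np.zeros(150), np.zeros(150, int),
                       np.full(150, 4144.0), n_frames=15000)
        s = image_summary(t)
        assert s.locs_per_100_frames == pytest.approx(1.0)
        assert s.mean_brightness == pytest.approx(4144.0)
        assert s.n_localizations == 150

    def test_empty_table_flags_undefined_mean(self):
        t = make_table([], [], [], [])
        s = image_summary(t)
        assert s.n_localizations == 0
        assert np.isnan(s.mean_brightness)
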