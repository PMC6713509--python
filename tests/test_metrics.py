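"""Per-object measurement, per-cell aggregation and the metrics CSV."""

import numpy as np
import pytest

from mitonetquant import BinaryMask
from mitonetquant.metrics import (
    CSV_COLUMNS,
    measure_objects,
    read_metrics_csv,
    summarize_cell,
    write_metrics_csv,
)
from mitonetquant.skeleton import build_graph, skeletonize, tag_and_label

from conftest import mask


def pipeline(px, pixel_size_um=1.0):
    m = mask(px, pixel_size_um)
    graph = build_graph(tag_and_label(skeletonize(m)))
    objects = measure_objects(m, graph)
    return m, objects


def summarize(px, pixel_size_um=1.0, **kw):
    m, objects = pipeline(px, pixel_size_um)
    return summarize_cell("roi", "src", m, objects, params_fingerprint="fp", **kw)


def thick_plus(size=31, arm=3):
    m = np.zeros((size, size), dtype=bool)
    c = size // 2
    m[c - arm // 2 : c + arm // 2 + 1, 2:-2] = True
    m[2:-2, c - arm // 2 : c + arm // 2 + 1] = True
    return m


class TestMeasureObjects:
    def test_thick_plus_is_one_network(self):
        _, objects = pipeline(thick_plus())
        assert len(objects) == 1
        (obj,) = objects
        assert obj.is_network
        assert obj.junction_count == 1
        assert obj.branch_count == 4
        assert obj.area_um2 == thick_plus().sum()

    def test_two_bars_are_two_non_networks(self):
        px = np.zeros((20, 30), dtype=bool)
        px[3:6, 4:15] = True
        px[12:15, 4:15] = True
        _, objects = pipeline(px)
        assert len(objects) == 2
        for obj in objects:
            assert not obj.is_network
            assert obj.branch_count == 1
            assert obj.area_um2 == 33

    def test_area_scales_with_pixel_size(self):
        _, obj1 = pipeline(thick_plus(), pixel_size_um=1.0)
        _, obj2 = pipeline(thick_plus(), pixel_size_um=2.0)
        assert obj2[0].area_um2 == pytest.approx(4 * obj1[0].area_um2)
        assert obj2[0].skeleton_length_um == pytest.approx(2 * obj1[0].skeleton_length_um)


class TestSummarizeCell:
    def test_square_coverage_arithmetic(self):
        px = np.zeros((100, 100), dtype=bool)
        px[40:50, 40:50] = True
        row = summarize(px, pixel_size_um=1.0)
        assert row.mito_coverage_pct == pytest.approx(1.0)
        assert row.object_count == 1
        assert row.objects_per_100um2 == pytest.approx(0.01)
        assert row.cell_area_um2 == pytest.approx(10000)

    def test_empty_mask_reports_missing_means(self):
        row = summarize(np.zeros((50, 50), dtype=bool))
        assert row.mito_coverage_pct == 0
        assert row.object_count == 0
        assert row.mean_object_length_um is None
        assert row.mean_object_area_um2 is None
        assert row.mean_junctions_per_network is None

    def test_scaling_laws(self):
        px = thick_plus()
        r1 = summarize(px, pixel_size_um=0.5)
        r2 = summarize(px, pixel_size_um=1.0)
        assert r2.mean_object_length_um == pytest.approx(2 * r1.mean_object_length_um)
        assert r2.mean_object_area_um2 == pytest.approx(4 * r1.mean_object_area_um2)
        assert r2.cell_area_um2 == pytest.approx(4 * r1.cell_area_um2)
        assert r2.mito_coverage_pct == pytest.approx(r1.mito_coverage_pct)
        assert (r2.object_count, r2.network_count, r2.junction_count_total) == (
            r1.object_count,
            r1.network_count,
            r1.junction_count_total,
        )
        assert r2.objects_per_100um2 == pytest.approx(r1.objects_per_100um2 / 4)

    def test_polygon_valid_mask_limits_cell_area(self):
        px = np.zeros((40, 40), dtype=bool)
        px[10:13, 5:25] = True
        valid = np.zeros((40, 40), dtype=bool)
        valid[:20, :] = True
        m = BinaryMask(px, 1.0, valid)
        graph = build_graph(tag_and_label(skeletonize(m)))
        row = summarize_cell("p", "s", m, measure_objects(m, graph))
        assert row.cell_area_um2 == pytest.approx(800)
        assert row.mito_coverage_pct == pytest.approx(100 * 60 / 800)

    def test_additive_over_disjoint_halves(self):
        px = np.zeros((40, 60), dtype=bool)
        px[5:8, 5:25] = True  # fully in the left half
        px[20:23, 35:55] = True  # fully in the right half
        whole = summarize(px)
        left = summarize(px[:, :30])
        right = summarize(px[:, 30:])
        assert whole.object_count == left.object_count + right.object_count
        assert whole.branch_count_total == left.branch_count_total + right.branch_count_total
        assert whole.cell_area_um2 == left.cell_area_um2 + right.cell_area_um2

    def test_length_mode_switch(self):
        px = thick_plus()
        total = summarize(px, length_mode="total")
        longest = summarize(px, length_mode="longest-branch")
        assert longest.mean_object_length_um < total.mean_object_length_um

    def test_zero_area_roi_rejected(self):
        m = BinaryMask(np.zeros((10, 10), dtype=bool), 1.0, np.zeros((10, 10), dtype=bool))
        with pytest.raises(ValueError, match="zero valid area"):
            summarize_cell("z", "s", m, [])


class TestMetricsCsv:
    def rows(self, n):
        return [summarize(thick_plus()) for _ in range(n)]

    def test_header_and_row_counts(self, tmp_path):
        p = tmp_path / "m.csv"
        write_metrics_csv(self.rows(3), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 4
        assert lines[0].split(",") == CSV_COLUMNS

    def test_empty_rows_header_only(self, tmp_path):
        p = tmp_path / "e.csv"
        write_metrics_csv([], p)
        assert p.read_text().strip().splitlines() == [",".join(CSV_COLUMNS)]

    def test_round_trip_to_six_significant_digits(self, tmp_path):
        p = tmp_path / "rt.csv"
        rows = self.rows(2)
        write_metrics_csv(rows, p)
        df = read_metrics_csv(p)
        assert df.shape[0] == 2
        for col in ("mito_coverage_pct", "mean_object_length_um", "cell_area_um2"):
            got = df[col].iloc[0]
            want = getattr(rows[0], col)
            assert got == pytest.approx(want, rel=1e-5)

    def test_missing_values_written_as_empty(self, tmp_path):
        p = tmp_path / "na.csv"
        write_metrics_csv([summarize(np.zeros((30, 30), dtype=bool))], p)
        data_line = p.read_text().strip().splitlines()[1]
        fields = dict(zip(CSV_COLUMNS, data_line.split(",")))
        assert fields["mean_object_length_um"] == ""
        assert fields["object_count"] == "0"

    def test_mixed_fingerprints_rejected(self, tmp_path):
        import dataclasses

        rows = self.rows(2)
        rows[1] = dataclasses.replace(rows[1], params_fingerprint="other")
        with pytest.raises(ValueError, match="mix"):
            write_metrics_csv(rows, tmp_path / "x.csv")
        write_metrics_csv(rows, tmp_path / "x.csv", allow_mixed=True)  # override works
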