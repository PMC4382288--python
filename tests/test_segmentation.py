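"""Adaptive segmentation, filament ordering and fluorescence extraction."""

import numpy as np
import pytest

from filafluct.datatypes import FilamentSet, FilamentTrace
from filafluct import filament_stats as fs
from filafluct import segmentation as seg
from filafluct import synthetic_data as sd


def make_record(cid, y, x):
    return seg.CellRecord(cell_id=cid, centroid=(y, x), area=40,
                          mean_fluorescence=1.0)


class TestSegmentCells:
    def test_constant_image_yields_no_cells(self):
        with pytest.warns(UserWarning, match="constant"):
            labels, cells = seg.segment_cells(np.full((32, 32), 5.0))
        assert labels.max() == 0 and cells == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            seg.segment_cells(np.zeros((4, 4, 3)))

    def test_well_separated_cells_match_ground_truth(self, default_image):
        img, truth, _ = default_image
        labels, cells = seg.segment_cells(img)
        matches = seg.match_cells(labels, truth.label_image, iou_threshold=0.5)
        assert len(matches) >= 0.95 * truth.n_cells

    def test_merged_pair_split_by_adaptive_rethresholding(self):
        """Two cells joined by a dim bridge separate once the local
        threshold rises above the bridge intensity."""
        img = np.zeros((40, 60))
        img[14:26, 10:22] = 10.0   # cell A, 12x12
        img[14:26, 24:36] = 14.0   # cell B
        img[19:21, 22:24] = 6.0    # bridge above the initial threshold
        params = seg.SegmentationParams(
            init_threshold_rule=("percentile", 50.0),  # low: merges the pair
            typical_cell_area=144.0,
            max_area_factor=1.5,
        )
        labels, cells = seg.segment_cells(img, params)
        assert len(cells) == 2
        areas = sorted(c.area for c in cells)
        assert areas[0] > 100  # both cells survive nearly whole

    def test_deterministic(self, default_image):
        img, _, _ = default_image
        a, _ = seg.segment_cells(img)
        b, _ = seg.segment_cells(img)
        assert np.array_equal(a, b)


class TestOrderIntoFilaments:
    def test_collinear_cells_form_one_indexed_chain(self):
        cells = [make_record(i, 20.0, 10.0 + 13.0 * i) for i in range(10)]
        out = seg.order_into_filaments(cells)
        assert {c.filament_id for c in out} == {0}
        assert [c.position_in_filament for c in out] == list(range(10))

    def test_parallel_filaments_stay_separate(self):
        cells = [make_record(i, 10.0, 10.0 + 13.0 * i) for i in range(6)]
        cells += [make_record(100 + i, 90.0, 10.0 + 13.0 * i) for i in range(6)]
        out = seg.order_into_filaments(cells)
        top = {c.cell_id for c in out if c.filament_id == out[0].filament_id}
        assert top in ({0, 1, 2, 3, 4, 5}, {100, 101, 102, 103, 104, 105})
        assert len({c.filament_id for c in out}) == 2

    def test_isolated_cell_becomes_singleton(self):
        out = seg.order_into_filaments([make_record(0, 5.0, 5.0)])
        assert out[0].filament_id == 0
        assert out[0].position_in_filament == 0

    def test_recovers_ground_truth_order_up_to_reversal(self, default_image):
        img, truth, _ = default_image
        labels, cells = seg.segment_cells(img)
        cells = seg.order_into_filaments(cells)
        matches = seg.match_cells(labels, truth.label_image)
        by_id = {c.cell_id: c for c in cells}
        for fil in truth.filament_assignments:
            pred = [matches.get(t) for t in fil]
            if None in pred:
                continue
            assert len({by_id[p].filament_id for p in pred}) == 1
            pos = [by_id[p].position_in_filament for p in pred]
            assert pos == sorted(pos) or pos == sorted(pos, reverse=True)


class TestExtractFluorescence:
    def test_uniform_intensity_returns_that_constant(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        labels[6:9, 6:9] = 2
        img = np.where(labels > 0, 7.5, 0.0)
        means = seg.extract_fluorescence(img, labels)
        assert means == {1: pytest.approx(7.5), 2: pytest.approx(7.5)}

    def test_relabelling_invariance(self, rng):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:6, 2:6] = 1
        labels[10:15, 10:15] = 2
        img = rng.random((20, 20))
        a = seg.extract_fluorescence(img, labels)
        relabelled = np.where(labels == 1, 5, np.where(labels == 2, 3, 0))
        b = seg.extract_fluorescence(img, relabelled)
        assert a[1] == pytest.approx(b[5]) and a[2] == pytest.approx(b[3])

    def test_no_labels_warns(self):
        with pytest.warns(UserWarning, match="no labelled"):
            assert seg.extract_fluorescence(np.ones((5, 5)), np.zeros((5, 5), int)) == {}

    def test_noise_free_render_recovers_trace_linearly(self):
        img, truth, _ = sd.default_image_fixture(seed=3, noise=False)
        means = seg.extract_fluorescence(img, truth.label_image)
        extracted = np.array([means[k] for k in range(1, truth.n_cells + 1)])
        r = np.corrcoef(extracted, truth.true_fluorescence)[0, 1]
        assert r ** 2 > 0.99


class TestFilterFilaments:
    @staticmethod
    def _set(lengths):
        return FilamentSet(
            [FilamentTrace(np.arange(1.0, n + 1.0), i) for i, n in enumerate(lengths)]
        )

    def test_default_min_length_eight(self):
        out = seg.filter_filaments(self._set([5, 8, 12]))
        assert sorted(len(t) for t in out) == [8, 12]

    def test_identity_when_all_long_enough(self):
        out = seg.filter_filaments(self._set([8, 20]))
        assert len(out) == 2

    def test_alternative_min_length_seven(self):
        out = seg.filter_filaments(self._set([7, 8]), min_length=7)
        assert sorted(len(t) for t in out) == [7, 8]


class TestReversalInvarianceDownstream:
    def test_all_statistics_unchanged_under_filament_reversal(self):
        """Filament orientation is arbitrary: noise, autocorrelation and
        cluster statistics must not depend on it."""
        from filafluct import cluster_analysis as ca

        params = sd.TraceGenParams(n_filaments=40, seed=8)
        fset, _ = sd.generate_traces(params)
        rset = FilamentSet([t.reversed() for t in fset], run_id=fset.run_id)

        assert fs.population_noise(fset) == pytest.approx(
            fs.population_noise(rset), abs=1e-12)
        for t, r in zip(fset, rset):
            assert fs.autocorrelation_raw(t, 5) == pytest.approx(
                fs.autocorrelation_raw(r, 5), abs=1e-12)
        ba, _ = ca.binarize(fset)
        bb, _ = ca.binarize(rset)
        for a, b in zip(ba, bb):
            assert sorted(ca.cluster_sizes(a)) == sorted(ca.cluster_sizes(b))
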