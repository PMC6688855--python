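import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshcover.accuracy import (
    ConfusionMatrix,
    accuracy_metrics,
    confusion_matrix,
    largest_remainder,
    stratified_points,
    summarize_accuracy,
)
from marshcover.geometry import default_design
from marshcover.raster import BARREN, NONSHRUB, SHRUB, ClassRaster


def _kappa_oracle(counts):
    """Direct loop-based OA/kappa, independent of the vectorized code."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p_o = sum(counts[i, i] for i in range(counts.shape[0])) / total
    p_e = 0.0
    for i in range(counts.shape[0]):
        p_e += counts[i, :].sum() * counts[:, i].sum()
    p_e /= total**2
    if abs(1 - p_e) < 1e-12:
        return p_o, 0.0
    return p_o, (p_o - p_e) / (1 - p_e)


class TestLargestRemainder:
    def test_study_composition_allocation(self):
        # shares (0.755, 0.035, 0.210) x 100 -> quotas 75.5 / 3.5 / 21.0;
        # floors 75/3/21 leave one seat; non-shrub's remainder edges out
        # barren's in floating point, taking the seat
        alloc = largest_remainder(np.array([0.755, 0.035, 0.210]), 100)
        assert alloc.tolist() == [75, 4, 21]
        assert alloc.sum() == 100

    @settings(deadline=None, max_examples=100)
    @given(
        shares=st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=6),
        n=st.integers(min_value=1, max_value=500),
    )
    def test_allocations_sum_to_n(self, shares, n):
        alloc = largest_remainder(np.array(shares), n)
        assert alloc.sum() == n
        assert np.all(alloc >= 0)


class TestStratifiedPoints:
    def _plot_raster(self):
        design = default_design(plot_cell_counts=(4,), plot_rows=2, scaled=True)
        plot = design.plots[0]
        data = np.full((100, 100), BARREN, dtype=np.uint8)  # gsd 1 m
        data[:, :21] = SHRUB
        data[:, 21:25] = NONSHRUB
        return ClassRaster(data, gsd_m=1.0), plot

    def test_allocation_proportional_to_area(self):
        cls, plot = self._plot_raster()
        pts = stratified_points(cls, plot, n_points=100, seed=0)
        counts = pts["mapped"].value_counts()
        # areas: barren 7500, non-shrub 400, shrub 2100 of 10000
        assert counts[BARREN] == 75
        assert counts[NONSHRUB] == 4
        assert counts[SHRUB] == 21

    def test_single_class_plot(self):
        design = default_design(plot_cell_counts=(4,), plot_rows=2, scaled=True)
        cls = ClassRaster(np.full((100, 100), SHRUB, dtype=np.uint8), gsd_m=1.0)
        pts = stratified_points(cls, design.plots[0], n_points=100, seed=1)
        assert len(pts) == 100 and (pts["mapped"] == SHRUB).all()

    def test_points_unique_and_deterministic(self):
        cls, plot = self._plot_raster()
        a = stratified_points(cls, plot, n_points=100, seed=3)
        b = stratified_points(cls, plot, n_points=100, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(["row", "col"]).any()

    def test_five_plots_give_500_points_per_altitude(self):
        design = default_design()
        w, h = design.extent_m
        cls = ClassRaster(
            np.random.default_rng(0).integers(0, 3, size=(int(h), int(w))).astype(np.uint8), gsd_m=1.0
        )
        total = sum(len(stratified_points(cls, p, 100, seed=p.plot_id)) for p in design.plots)
        assert total == 500


class TestConfusionMatrix:
    def test_identical_rasters_give_diagonal(self):
        cls = ClassRaster(np.random.default_rng(2).integers(0, 3, (50, 50)).astype(np.uint8), gsd_m=1.0)
        pts = pd.DataFrame({"row": np.arange(50), "col": np.arange(50)})
        cm = confusion_matrix(pts, cls, cls)
        assert np.all(cm.counts[~np.eye(3, dtype=bool)] == 0)
        assert cm.total == 50

    def test_hand_built_disagreements(self):
        mapped = ClassRaster(np.full((1, 10), BARREN, dtype=np.uint8), gsd_m=1.0)
        ref_data = np.full((1, 10), BARREN, dtype=np.uint8)
        ref_data[0, 3] = SHRUB
        ref_data[0, 7] = NONSHRUB
        ref = ClassRaster(ref_data, gsd_m=1.0)
        pts = pd.DataFrame({"row": [0] * 10, "col": list(range(10))})
        cm = confusion_matrix(pts, mapped, ref)
        assert cm.counts.sum() - np.trace(cm.counts) == 2
        assert cm.counts[BARREN, SHRUB] == 1 and cm.counts[BARREN, NONSHRUB] == 1

    def test_column_sums_count_reference_classes(self):
        rng = np.random.default_rng(5)
        mapped = ClassRaster(rng.integers(0, 3, (40, 40)).astype(np.uint8), gsd_m=1.0)
        ref = ClassRaster(rng.integers(0, 3, (40, 40)).astype(np.uint8), gsd_m=1.0)
        pts = pd.DataFrame({"row": rng.integers(0, 40, 200), "col": rng.integers(0, 40, 200)})
        cm = confusion_matrix(pts, mapped, ref)
        ref_labels = ref.data[pts["row"], pts["col"]]
        for c in (BARREN, NONSHRUB, SHRUB):
            assert cm.counts[:, c].sum() == int(np.sum(ref_labels == c))


class TestAccuracyMetrics:
    def test_two_class_textbook_example(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0], counts[0, 1] = 45, 5
        counts[1, 0], counts[1, 1] = 10, 40
        m = accuracy_metrics(ConfusionMatrix(counts))
        assert m["overall_accuracy"] == pytest.approx(0.85)
        assert m["kappa"] == pytest.approx(0.70)

    def test_perfect_map(self):
        m = accuracy_metrics(ConfusionMatrix(np.diag([50, 30, 20])))
        assert m["overall_accuracy"] == 1.0 and m["kappa"] == 1.0
        np.testing.assert_allclose(m["omission"], 0.0)
        np.testing.assert_allclose(m["commission"], 0.0)

    def test_degenerate_single_class_kappa_zero(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 100
        m = accuracy_metrics(ConfusionMatrix(counts))
        assert m["kappa"] == 0.0

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(1000):
            counts = rng.integers(0, 50, size=(3, 3))
            if counts.sum() == 0:
                continue
            m = accuracy_metrics(ConfusionMatrix(counts))
            oa, kappa = _kappa_oracle(counts)
            assert m["overall_accuracy"] == pytest.approx(oa, abs=1e-12)
            assert m["kappa"] == pytest.approx(kappa, abs=1e-12)

    def test_random_labels_give_near_zero_kappa(self, rng):
        n = 100_000
        mapped = rng.integers(0, 3, n)
        ref = rng.integers(0, 3, n)
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (mapped, ref), 1)
        m = accuracy_metrics(ConfusionMatrix(counts))
        assert abs(m["kappa"]) < 0.05


class TestSummary:
    def test_mean_and_range(self):
        s = summarize_accuracy(
            [{"overall_accuracy": 0.90, "kappa": 0.8}, {"overall_accuracy": 0.95, "kappa": 0.7}]
        )
        oa = s[s["metric"] == "overall_accuracy"].iloc[0]
        assert oa["mean"] == pytest.approx(0.925)
        assert (oa["min"], oa["max"]) == (0.90, 0.95)

    def test_single_plot_sd_flagged(self):
        s = summarize_accuracy([{"overall_accuracy": 0.9, "kappa": 0.8}])
        assert (s["sd"] == 0).all() and s["sd_undefined"].all()

    def test_matches_naive_recomputation(self, rng):
        metrics = [{"overall_accuracy": float(v), "kappa": float(k)}
                   for v, k in rng.random((5, 2))]
        s = summarize_accuracy(metrics).set_index("metric")
        oas = [m["overall_accuracy"] for m in metrics]
        mean = sum(oas) / 5
        sd = (sum((v - mean) ** 2 for v in oas) / 4) ** 0.5
        assert s.loc["overall_accuracy", "mean"] == pytest.approx(mean)
        assert s.loc["overall_accuracy", "sd"] == pytest.approx(sd)
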