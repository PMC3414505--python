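"""Map-correlation measure, Dice index, agreement categories, reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iscval import build_report, corr_measure, dice, kappa_category


def set_based_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: Dice from explicit voxel-index sets."""
    sa = set(map(tuple, np.argwhere(np.asarray(a, bool))))
    sb = set(map(tuple, np.argwhere(np.asarray(b, bool))))
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def kappa_from_table(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: Cohen's kappa from the 2x2 agreement table."""
    a = np.asarray(a, bool).ravel()
    b = np.asarray(b, bool).ravel()
    n = a.size
    p_o = np.mean(a == b)
    p_yes = a.mean() * b.mean()
    p_no = (1 - a.mean()) * (1 - b.mean())
    p_e = p_yes + p_no
    return (p_o - p_e) / (1 - p_e)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        assert dice(a, a) == 1.0
        assert dice(a, 1 - a) == 0.0

    def test_hand_counted_example(self):
        assert dice(np.array([1, 1, 0]), np.array([1, 0, 1])) == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            dice(np.zeros(5), np.zeros(5))

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((4, 4, 4)) < 0.3
        b = rng.random((4, 4, 4)) < 0.3
        if not (a.any() or b.any()):
            a[0, 0, 0] = True
        assert dice(a, b) == dice(b, a)
        assert dice(a, b) == pytest.approx(set_based_dice(a, b), abs=1e-12)

    def test_asymptotic_kappa_equality_for_sparse_maps(self):
        # small active fraction on >= 1e4 voxels: Dice ~ Cohen's kappa
        rng = np.random.default_rng(42)
        base = rng.random(12000) < 0.03
        noise = rng.random(12000) < 0.01
        a = base | noise
        b = base ^ (rng.random(12000) < 0.005) & base
        assert abs(dice(a, b) - kappa_from_table(a, b)) < 0.02


class TestCorrMeasure:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(100)
        assert corr_measure(z, np.abs(z)) == pytest.approx(1.0)

    def test_five_voxel_pearson_oracle(self):
        z = np.array([1.0, -2.0, 0.5, 3.0, -0.2])
        r = np.array([0.1, 0.4, 0.05, 0.5, 0.15])
        az = np.abs(z)
        expected = ((az - az.mean()) * (r - r.mean())).sum() / (
            np.sqrt(((az - az.mean()) ** 2).sum() * ((r - r.mean()) ** 2).sum())
        )
        assert corr_measure(z, r) == pytest.approx(expected, abs=1e-12)

    def test_absolute_mode_handles_deactivations(self):
        rng = np.random.default_rng(1)
        z = np.concatenate([rng.normal(4, 1, 50), rng.normal(-4, 1, 50)])
        isc = np.abs(z) / 10 + rng.normal(0, 0.05, 100)
        assert corr_measure(z, isc, use_abs=True) > corr_measure(z, isc, use_abs=False) - 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(50)
        r = rng.standard_normal(50)
        c1 = corr_measure(z, r)
        c2 = corr_measure(z * 2.5, r * 0.1 + 3.0)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_mask_restricts_voxels(self):
        z = np.array([1.0, 2.0, 3.0, 100.0])
        r = np.array([1.0, 2.0, 3.0, -100.0])
        mask = np.array([True, True, True, False])
        assert corr_measure(z, r, mask=mask) == pytest.approx(1.0)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            corr_measure(np.ones(10), np.arange(10.0))


class TestKappaCategory:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.86, "Almost perfect agreement"),
            (0.73, "Substantial agreement"),
            (0.0, "Slight agreement"),
            (-0.1, "No agreement"),
            (0.2, "Fair agreement"),
            (0.4, "Moderate agreement"),
            (0.6, "Substantial agreement"),
            (0.8, "Almost perfect agreement"),
            (1.0, "Almost perfect agreement"),
        ],
    )
    def test_bins(self, value, label):
        assert kappa_category(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kappa_category(1.5)


class TestBuildReport:
    @staticmethod
    def _runs(n_tasks, qs, seed=0):
        rng = np.random.default_rng(seed)
        runs = {}
        for i in range(n_tasks):
            z = rng.standard_normal(200)
            runs[f"task{i}"] = {
                "zmap": z,
                "iscmap": np.abs(z) / 8 + rng.normal(0, 0.05, 200),
                "glm_active": {q: rng.random(200) < 0.2 for q in qs},
                "isc_active": {q: rng.random(200) < 0.2 for q in qs},
            }
        return runs

    def test_five_by_three_layout(self):
        qs = [0.05, 0.005, 0.001]
        report = build_report(self._runs(5, qs), qs)
        assert report.dice_table.shape == (6, 4)  # 5 tasks + avg, 3 q + avg
        core = report.dice_table.loc[
            [f"task{i}" for i in range(5)], qs
        ].to_numpy()
        assert np.isfinite(core).all() and core.size == 15
        np.testing.assert_allclose(
            report.dice_table.loc["Average", qs], core.mean(axis=0)
        )
        assert report.correlation.size == 6

    def test_single_task_averages_are_identity(self):
        qs = [0.05]
        report = build_report(self._runs(1, qs), qs)
        assert report.dice_table.loc["Average", 0.05] == pytest.approx(
            report.dice_table.loc["task0", 0.05]
        )
        assert report.correlation["Average"] == pytest.approx(
            report.correlation["task0"]
        )

    def test_missing_maps_leave_gaps(self):
        qs = [0.05, 0.005]
        runs = self._runs(2, qs)
        del runs["task1"]["zmap"]
        runs["task1"]["isc_active"].pop(0.005)
        report = build_report(runs, qs)
        assert np.isnan(report.correlation["task1"])
        assert np.isnan(report.dice_table.loc["task1", 0.005])
        assert np.isfinite(report.dice_table.loc["task0", 0.005])
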