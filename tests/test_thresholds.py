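"""Threshold calibration and three-way classification rules."""

import numpy as np
import pandas as pd
import pytest

from hatchtrace.admixture import AdmixtureConfig, AssignmentResult
from hatchtrace.thresholds import (ThresholdCalibration, calibrate_thresholds,
                                   classify_individuals, evaluate_error_rate)

from conftest import diverged_pools


def _calibration(sample, ranks=(2.5, 97.5)):
    sample = np.asarray(sample, dtype=float)
    lo, hi = np.percentile(sample, ranks, method="linear")
    return ThresholdCalibration(sample, ranks[0], ranks[1],
                                float(lo), float(hi))


def _result(ind, p, pop="p"):
    return AssignmentResult(individual=ind, population=pop, p_wild=p,
                            ci_low=max(p - 0.05, 0), ci_high=min(p + 0.05, 1))


def _sort_interpolate_percentile(sample, rank):
    """Independent oracle: linear interpolation between order statistics at
    positions 0..n-1 mapped to 0..100."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    pos = rank / 100 * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return x[lo] * (1 - frac) + x[hi] * frac


class TestCalibration:
    def test_degenerate_sample_collapses(self):
        cal = _calibration([0.5] * 200)
        assert cal.t_lo == cal.t_hi == 0.5

    def test_percentile_matches_sort_interpolate_oracle(self):
        rng = np.random.default_rng(0)
        sample = rng.random(1000)
        for rank in (2.5, 5.0, 50.0, 95.0, 97.5):
            cal = _calibration(sample, (rank, rank))
            assert cal.t_lo == pytest.approx(
                _sort_interpolate_percentile(sample, rank), abs=1e-12
            )

    def test_recompute_reproduces_cutoffs(self):
        rng = np.random.default_rng(1)
        cal = _calibration(rng.random(500))
        assert cal.recompute() == (cal.t_lo, cal.t_hi)

    def test_json_round_trip(self, tmp_path):
        cal = _calibration(np.linspace(0, 1, 101))
        cal.to_json(tmp_path / "cal.json")
        back = ThresholdCalibration.from_json(tmp_path / "cal.json")
        assert back.t_lo == cal.t_lo and back.t_hi == cal.t_hi
        assert np.array_equal(back.p_wild_sample, cal.p_wild_sample)

    def test_small_f1_sample_warns(self, small_centroids):
        pw, ph, wild, hatch = small_centroids
        cfg = AdmixtureConfig(burn_in=100, sweeps=200, seed=0)
        with pytest.warns(UserWarning, match="extreme order statistics"):
            calibrate_thresholds(pw, ph, 10, wild, hatch, cfg)

    def test_invalid_ranks_rejected(self, small_centroids):
        pw, ph, wild, hatch = small_centroids
        cfg = AdmixtureConfig(seed=0)
        with pytest.raises(ValueError, match="ranks"):
            calibrate_thresholds(pw, ph, 50, wild, hatch, cfg,
                                 ranks=(97.5, 2.5))


class TestClassification:
    CAL = None

    def setup_method(self):
        # cutoffs at exactly 0.06 / 0.94
        sample = np.concatenate([
            np.full(100, 0.06), np.full(100, 0.5), np.full(100, 0.94)
        ])
        self.cal = _calibration(sample)
        assert (self.cal.t_lo, self.cal.t_hi) == (0.06, 0.94)

    def test_clearly_wild(self):
        frame, _ = classify_individuals([_result("a", 0.99)], self.cal)
        assert frame.loc[0, "label"] == "wild"

    def test_boundary_value_is_introgressed(self):
        frame, _ = classify_individuals(
            [_result("a", 0.94), _result("b", 0.06)], self.cal
        )
        assert list(frame["label"]) == ["introgressed", "introgressed"]

    def test_below_lower_is_hatchery(self):
        frame, _ = classify_individuals([_result("a", 0.01)], self.cal)
        assert frame.loc[0, "label"] == "hatchery"

    def test_counts_partition_population(self):
        rng = np.random.default_rng(2)
        results = [
            _result(f"i{k}", float(rng.random()), pop=f"p{k % 3}")
            for k in range(60)
        ]
        _, summary = classify_individuals(results, self.cal)
        parts = summary[["n_wild", "n_introgressed", "n_hatchery"]].sum(axis=1)
        assert (parts == summary["n"]).all()

    def test_labels_written_back(self):
        r = _result("a", 0.5)
        classify_individuals([r], self.cal)
        assert r.label == "introgressed"


class TestErrorRates:
    def _setup(self):
        rng = np.random.default_rng(3)
        f1_sample = np.clip(rng.normal(0.5, 0.18, 400), 0.01, 0.99)
        cal = _calibration(f1_sample)
        results, truth = [], {}
        for k in range(50):
            results.append(_result(f"w{k}", float(np.clip(rng.normal(0.97, 0.01), 0, 1))))
            truth[f"w{k}"] = "wild"
            results.append(_result(f"h{k}", float(np.clip(rng.normal(0.03, 0.01), 0, 1))))
            truth[f"h{k}"] = "hatchery"
            results.append(_result(f"f{k}", float(np.clip(rng.normal(0.5, 0.18), 0.01, 0.99))))
            truth[f"f{k}"] = "F1"
        return truth, results, cal

    def test_pure_only_truth_has_nan_missed_rate(self):
        truth, results, cal = self._setup()
        pure = {k: v for k, v in truth.items() if v != "F1"}
        pure_results = [r for r in results if r.individual in pure]
        rates = evaluate_error_rate(pure, pure_results, cal)
        assert np.isnan(rates["missed_introgressed"]).all()
        assert (rates["false_introgressed"] < 0.05).all()

    def test_widening_ranks_never_decreases_introgressed_count(self):
        truth, results, cal = self._setup()
        pairs = [(10.0, 90.0), (5.0, 95.0), (2.5, 97.5), (0.5, 99.5)]
        counts = []
        for ranks in pairs:
            frame, _ = classify_individuals(results, cal, ranks=ranks)
            counts.append(int((frame["label"] == "introgressed").sum()))
        assert counts == sorted(counts)

    def test_narrower_band_misses_more_f1(self):
        truth, results, cal = self._setup()
        rates = evaluate_error_rate(
            truth, results, cal,
            ranks_list=[(2.5, 97.5), (5.0, 95.0), (10.0, 90.0)],
        )
        missed = rates["missed_introgressed"].to_numpy()
        assert missed[0] <= missed[1] <= missed[2]

    def test_unknown_truth_label_rejected(self):
        truth, results, cal = self._setup()
        truth["w0"] = "feral"
        with pytest.raises(ValueError, match="unknown truth"):
            evaluate_error_rate(truth, results, cal)
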