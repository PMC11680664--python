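import math

import numpy as np
import pytest

from forgetting.fitting import (
    DegenerateDatasetError,
    FitResult,
    FitSet,
    RetentionDataset,
    best_fit,
    fit_all,
    fit_family,
    fit_quality_correlations,
    fitsets_to_frame,
    r_squared,
)
from forgetting.models import FunctionFamily, _raw_evaluate

from conftest import exact_dataset


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = [0.9, 0.8, 0.7]
        assert r_squared(obs, [0.8, 0.8, 0.8]) == pytest.approx(0.0)

    def test_hand_computed_half(self):
        # SSE = .01, SST = .02
        assert r_squared([0.9, 0.8, 0.7], [0.9, 0.8, 0.6]) == pytest.approx(0.5)

    def test_worse_than_mean_is_negative(self):
        assert r_squared([0.9, 0.8, 0.7], [0.5, 0.9, 1.0]) < 0.0

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDatasetError):
            r_squared([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])


class TestClosedFormFits:
    def test_exact_line(self):
        ds = RetentionDataset("lin", (1, 2, 3), (0.9, 0.8, 0.7))
        fit = fit_family(ds, FunctionFamily.LINEAR)
        assert fit.a == pytest.approx(1.0, abs=1e-12)
        assert fit.b == pytest.approx(-0.1, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_exact_logarithmic(self):
        ds = RetentionDataset("log", (1.0, math.e, math.e**2), (0.9, 0.8, 0.7))
        fit = fit_family(ds, FunctionFamily.LOGARITHMIC)
        assert fit.a == pytest.approx(0.9, abs=1e-12)
        assert fit.b == pytest.approx(0.1, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "family, a, b",
    [
        ("logarithmic", 0.9, 0.05),
        ("power", 0.8, -0.2),
        ("exponential_power", 0.85, 0.002),
        ("hyperbolic_power", 1.2, 0.003),
        ("linear", 0.8, -2e-7),
    ],
)
def test_noise_free_recovery(family, a, b):
    """Data generated exactly from a family refits to r²=1 with the
    generating parameters."""
    ds = exact_dataset(family, a, b, np.logspace(0.5, 6.2, 6))
    fit = fit_family(ds, FunctionFamily(family))
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    assert fit.a == pytest.approx(a, abs=1e-6)
    assert fit.b == pytest.approx(b, abs=1e-6)


@pytest.mark.parametrize("scale", [1 / 3600, 60.0, 86400.0])
def test_r2_invariant_to_time_units(scale):
    """Rescaling delays (s → min/h/days) changes parameters, not fit
    quality: all five families are closed under t → c t."""
    ds = RetentionDataset("u", (10, 100, 1000, 50000), (0.91, 0.72, 0.60, 0.38))
    scaled = RetentionDataset("us", tuple(scale * t for t in ds.times), ds.proportions)
    for family in FunctionFamily:
        r_orig = fit_family(ds, family).r2
        r_scaled = fit_family(scaled, family).r2
        assert r_scaled == pytest.approx(r_orig, abs=1e-8)


def test_fit_all_returns_all_five_families():
    ds = RetentionDataset("x", (1, 10, 100), (0.9, 0.6, 0.4))
    fs = fit_all(ds)
    assert set(fs.fits) == set(FunctionFamily)


def test_fitset_requires_all_families():
    fit = FitResult(FunctionFamily.LINEAR, 1.0, -0.1, 1.0)
    with pytest.raises(ValueError):
        FitSet("x", {FunctionFamily.LINEAR: fit})


def test_degenerate_dataset_rejected():
    ds = RetentionDataset("flat", (1, 10, 100), (0.5, 0.5, 0.5))
    with pytest.raises(DegenerateDatasetError):
        fit_family(ds, FunctionFamily.POWER)


class TestBestFit:
    @staticmethod
    def _fitset(r2s):
        fits = {
            f: FitResult(f, 1.0, -0.1, r2s[f.value]) for f in FunctionFamily
        }
        return FitSet("x", fits)

    def test_argmax_selection(self):
        fs = self._fitset(
            {"logarithmic": 0.95, "power": 0.91, "exponential_power": 0.90,
             "hyperbolic_power": 0.89, "linear": 0.60}
        )
        family, fit, tie = best_fit(fs)
        assert family is FunctionFamily.LOGARITHMIC
        assert fit.r2 == 0.95
        assert not tie

    def test_all_tied_breaks_to_logarithmic_and_flags(self):
        fs = self._fitset({f.value: 0.9 for f in FunctionFamily})
        family, _, tie = best_fit(fs)
        assert family is FunctionFamily.LOGARITHMIC
        assert tie

    def test_exact_power_data_wins_as_power(self):
        ds = exact_dataset("power", 0.8, -0.2, [1, 10, 100, 1000])
        family, fit, _ = best_fit(fit_all(ds))
        assert family is FunctionFamily.POWER
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_exact_logarithmic_data_beats_power(self):
        ds = exact_dataset("logarithmic", 0.9, 0.05, np.logspace(0.3, 6, 7))
        fs = fit_all(ds)
        assert fs[FunctionFamily.LOGARITHMIC].r2 == pytest.approx(1.0, abs=1e-9)
        assert fs[FunctionFamily.POWER].r2 <= 1.0
        assert best_fit(fs).family is FunctionFamily.LOGARITHMIC


class TestFitQualityCorrelations:
    @staticmethod
    def _fitset(did, r2s):
        return FitSet(
            did, {f: FitResult(f, 1.0, -0.1, r2) for f, r2 in zip(FunctionFamily, r2s)}
        )

    def test_identical_vectors_correlate_perfectly(self):
        sets = [
            self._fitset(str(i), [v, v, 0.5, 0.1 * i, 0.2])
            for i, v in enumerate([0.3, 0.6, 0.9])
        ]
        corr = fit_quality_correlations(sets)
        assert corr.loc["logarithmic", "power"] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        sets = [
            self._fitset(str(i), [v, 1 - v, 0.5, 0.1 * i, 0.2])
            for i, v in enumerate([0.3, 0.6, 0.9])
        ]
        corr = fit_quality_correlations(sets)
        assert corr.loc["logarithmic", "power"] == pytest.approx(-1.0)

    def test_constant_vector_is_missing(self):
        sets = [
            self._fitset(str(i), [v, 0.5, 0.5, 0.1 * i, 0.2])
            for i, v in enumerate([0.3, 0.6, 0.9])
        ]
        corr = fit_quality_correlations(sets)
        assert np.isnan(corr.loc["logarithmic", "power"])
        assert corr.loc["power", "power"] == 1.0

    def test_needs_three_fitsets(self):
        sets = [self._fitset("a", [0.1, 0.2, 0.3, 0.4, 0.5])]
        with pytest.raises(ValueError):
            fit_quality_correlations(sets)


def test_tidy_frame_has_one_row_per_family():
    ds = RetentionDataset("x", (1, 10, 100), (0.9, 0.6, 0.4))
    frame = fitsets_to_frame([fit_all(ds)])
    assert len(frame) == 5
    assert set(frame.columns) == {"dataset_id", "family", "a", "b", "r2", "converged"}


class TestDatasetValidation:
    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            RetentionDataset("x", (1, 10), (0.9, 0.8))

    def test_nonpositive_delay(self):
        with pytest.raises(ValueError):
            RetentionDataset("x", (0, 10, 100), (0.9, 0.8, 0.7))

    def test_non_increasing_delays(self):
        with pytest.raises(ValueError):
            RetentionDataset("x", (1, 100, 10), (0.9, 0.8, 0.7))

    def test_out_of_range_proportion(self):
        with pytest.raises(ValueError):
            RetentionDataset("x", (1, 10, 100), (0.9, 1.2, 0.7))
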