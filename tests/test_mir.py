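import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mefeval.mir import (
    N_SELECTED,
    PIN_RANGES,
    RAW_PIN_COUNT,
    detect_homogeneous_subsets,
    mahalanobis_qc,
    match_weekly_to_spectrum,
    prediction_metrics,
    savitzky_golay,
    select_informative_pins,
    selected_pin_indices,
    standardize_subset,
    weekly_aggregate_and_edit,
)


class TestPinSelection:
    def test_yields_exactly_241_points(self):
        out = select_informative_pins(np.zeros(RAW_PIN_COUNT))
        assert out.shape == (241,)
        assert N_SELECTED == 241

    def test_all_zero_stays_zero(self):
        assert np.all(select_informative_pins(np.zeros(RAW_PIN_COUNT)) == 0)

    @pytest.mark.parametrize("pin,expected_kept", [
        (259, False), (260, True), (402, True), (403, False),
        (441, False), (442, True), (472, True), (473, False),
        (700, False), (701, True), (767, True), (768, False),
    ])
    def test_range_boundaries(self, pin, expected_kept):
        raw = np.zeros(RAW_PIN_COUNT)
        raw[pin - 1] = 1.0  # 1-based pin indexing
        assert (select_informative_pins(raw).sum() == 1.0) == expected_kept

    def test_selection_is_a_projection(self):
        """Re-extracting from a padded already-selected vector returns the
        same 241 values."""
        rng = np.random.default_rng(0)
        raw = rng.standard_normal(RAW_PIN_COUNT)
        sel = select_informative_pins(raw)
        padded = np.zeros(RAW_PIN_COUNT)
        padded[selected_pin_indices()] = sel
        assert np.array_equal(select_informative_pins(padded), sel)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            select_informative_pins(np.zeros(500))


class TestSubsets:
    def test_identical_spectra_single_subset(self):
        spectra = np.ones((50, 30))
        dates = np.arange(50)
        assert detect_homogeneous_subsets(spectra, dates).max() == 0

    def test_threshold_one_gives_single_subset(self, rng):
        spectra = rng.standard_normal((80, 30))
        out = detect_homogeneous_subsets(spectra, np.arange(80),
                                         variance_threshold=1.0)
        assert np.all(out == 0)

    def test_planted_level_shift_detected(self, rng):
        n, p = 200, 40
        base = rng.standard_normal((n, p)) * 0.2
        profile = rng.standard_normal(p)
        base[100:] += 3.0 * profile  # instrument drift at index 100
        dates = np.arange(n)
        out = detect_homogeneous_subsets(base, dates, window=25)
        assert out.max() == 1
        change = np.argmax(out > 0)
        assert abs(change - 100) <= 25

    def test_single_spectrum_warns(self, rng):
        with pytest.warns(UserWarning):
            out = detect_homogeneous_subsets(rng.standard_normal((1, 10)),
                                             np.array([0]))
        assert np.all(out == 0)


class TestStandardization:
    def test_identity_on_reference(self, rng):
        spectra = rng.standard_normal((40, 20)) + 5.0
        out, m = standardize_subset(spectra, spectra.mean(0), spectra.std(0))
        assert np.allclose(out, spectra)
        assert np.allclose(m.slope, 1.0) and np.allclose(m.offset, 0.0)

    def test_affine_inversion(self, rng):
        ref = rng.standard_normal((60, 15))
        shifted = ref * 2.0 + 1.0
        out, m = standardize_subset(shifted, ref.mean(0), ref.std(0))
        assert np.allclose(m.slope, 0.5)
        assert np.allclose(m.offset, -0.5, atol=1e-10)

    def test_matches_reference_moments_exactly(self, rng):
        ref_mean = rng.standard_normal(25)
        ref_sd = rng.uniform(0.5, 2.0, 25)
        sub = rng.standard_normal((30, 25)) * 3 + 10
        out, _ = standardize_subset(sub, ref_mean, ref_sd)
        assert np.abs(out.mean(0) - ref_mean).max() < 1e-10
        assert np.abs(out.std(0) - ref_sd).max() < 1e-10

    def test_zero_variance_pin_offset_only(self, rng):
        sub = rng.standard_normal((20, 3))
        sub[:, 1] = 7.0
        with pytest.warns(UserWarning):
            out, m = standardize_subset(sub, np.zeros(3), np.ones(3))
        assert np.allclose(out[:, 1], 0.0)  # moved onto the reference mean


class TestMahalanobisQC:
    def test_centroid_spectrum_retained(self, rng):
        x = rng.standard_normal((100, 10))
        x[0] = x[1:].mean(axis=0)
        keep = mahalanobis_qc(x)
        assert keep[0]

    def test_planted_outlier_flagged(self, rng):
        x = rng.standard_normal((200, 20))
        direction = rng.standard_normal(20)
        direction /= np.linalg.norm(direction)
        x[5] = 30.0 * direction
        keep = mahalanobis_qc(x)
        assert not keep[5]
        # validates against an independently tabulated quantile
        assert chi2.ppf(0.999, df=1) < 30.0**2

    def test_clean_data_flag_rate_near_nominal(self):
        rng = np.random.default_rng(99)
        n = 20000
        cov_chol = rng.standard_normal((15, 15)) * 0.1 + np.eye(15)
        x = rng.standard_normal((n, 15)) @ cov_chol.T
        keep = mahalanobis_qc(x, variance_threshold=0.0)
        rate = 1.0 - keep.mean()
        # nominal 0.001 within Monte-Carlo error (binomial 99.9% band)
        se = np.sqrt(0.001 * 0.999 / n)
        assert abs(rate - 0.001) < 4 * se + 1e-4


class TestSavitzkyGolay:
    def test_cubic_polynomial_exact_at_interior(self):
        x = np.arange(60, dtype=float)
        y = 0.3 * x**3 - 2 * x**2 + x - 4
        out = savitzky_golay(y)
        assert np.abs(out[5:-5] - y[5:-5]).max() < 1e-8

    def test_constant_unchanged_everywhere(self):
        y = np.full(30, 3.7)
        assert np.allclose(savitzky_golay(y), 3.7)

    def test_interior_matches_windowed_polyfit_oracle(self, rng):
        y = rng.standard_normal(40)
        out = savitzky_golay(y)
        for i in (7, 15, 23, 31):
            w = np.arange(i - 5, i + 6)
            coef = np.polynomial.polynomial.polyfit(w - i, y[w], 3)
            assert out[i] == pytest.approx(coef[0], abs=1e-10)

    def test_edges_use_shrunken_window_fit(self, rng):
        y = rng.standard_normal(25)
        out = savitzky_golay(y)
        coef = np.polynomial.polynomial.polyfit(np.arange(6), y[:6], 3)
        assert out[0] == pytest.approx(coef[0], abs=1e-10)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(30), order=3, width=10)
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(30), order=3, width=3)
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros(5))


def _daily_frame(ch4_by_day, animal=1, lactation=1, dim_start=100):
    dates = pd.date_range("2022-03-07", periods=len(ch4_by_day))
    return pd.DataFrame({
        "animal": animal,
        "date": dates,
        "ch4": ch4_by_day,
        "dim": np.arange(dim_start, dim_start + len(ch4_by_day)),
        "lactation": lactation,
    })


class TestWeeklyAggregation:
    def test_week_with_single_record_excluded(self):
        d = _daily_frame([500.0])
        assert len(weekly_aggregate_and_edit(d)) == 0

    def test_low_dim_excluded(self):
        d = _daily_frame([500.0, 510.0], dim_start=3)
        d.loc[:, "dim"] = [3, 4]
        assert len(weekly_aggregate_and_edit(d)) == 0

    def test_non_first_lactation_excluded(self):
        d = _daily_frame([500.0] * 5, lactation=2)
        assert len(weekly_aggregate_and_edit(d)) == 0

    def test_weekly_mean_computed(self):
        d = _daily_frame([480.0, 500.0, 520.0])
        out = weekly_aggregate_and_edit(d)
        assert len(out) == 1
        assert out["ch4"].iloc[0] == pytest.approx(500.0)
        assert out["n_daily"].iloc[0] == 3

    def test_daily_edit_switch(self):
        """With edit_level='daily' the SD filter removes wild daily values
        before averaging instead of dropping whole weeks."""
        rng = np.random.default_rng(5)
        frames = [_daily_frame(490 + rng.standard_normal(3), animal=a)
                  for a in range(30)]
        bad = _daily_frame([490.0, 491.0, 5000.0], animal=77)
        d = pd.concat(frames + [bad], ignore_index=True)
        weekly = weekly_aggregate_and_edit(d, edit_level="daily")
        row = weekly[weekly.animal == 77]
        assert len(row) == 1
        assert row["n_daily"].iloc[0] == 2  # the wild daily record removed
        assert abs(row["ch4"].iloc[0] - 490.5) < 1.0

    def test_sd_outlier_week_removed(self):
        rng = np.random.default_rng(3)
        frames = []
        for a in range(40):
            vals = 490 + rng.standard_normal(3)
            frames.append(_daily_frame(vals, animal=a))
        # plant one wild weekly mean
        frames.append(_daily_frame([900.0, 902.0, 898.0], animal=99))
        d = pd.concat(frames, ignore_index=True)
        out = weekly_aggregate_and_edit(d)
        base = weekly_aggregate_and_edit(d[d.animal != 99])
        assert len(out) == len(base)
        assert 99 not in out["animal"].to_numpy()


class TestSpectrumMatching:
    def _weekly(self, midpoint="2022-03-09"):
        return pd.DataFrame({
            "animal": [1], "week": ["2022-W10"], "ch4": [500.0],
            "n_daily": [3], "midpoint": [pd.Timestamp(midpoint)],
        })

    def _spectra_index(self, dates):
        return pd.DataFrame({
            "animal": 1,
            "date": pd.to_datetime(dates),
            "spectrum_id": np.arange(len(dates)),
        })

    def test_same_day_matches_at_zero(self):
        out = match_weekly_to_spectrum(self._weekly(), self._spectra_index(["2022-03-09"]))
        assert out["spectrum_id"].iloc[0] == 0
        assert out["match_days"].iloc[0] == 0

    def test_12_days_unmatched(self):
        out = match_weekly_to_spectrum(self._weekly(), self._spectra_index(["2022-03-21"]))
        assert out["spectrum_id"].iloc[0] == -1

    def test_11_days_matched(self):
        out = match_weekly_to_spectrum(self._weekly(), self._spectra_index(["2022-03-20"]))
        assert out["spectrum_id"].iloc[0] == 0

    def test_tie_goes_to_earlier_date(self):
        out = match_weekly_to_spectrum(
            self._weekly(), self._spectra_index(["2022-03-06", "2022-03-12"])
        )
        assert out["spectrum_id"].iloc[0] == 0


class TestPredictionMetrics:
    def test_identical_vectors(self):
        m = prediction_metrics(np.arange(10.0), np.arange(10.0))
        assert m["r"] == pytest.approx(1.0)
        assert m["rmse"] == 0.0

    def test_negated_vector(self):
        x = np.arange(10.0)
        assert prediction_metrics(x, -x)["r"] == pytest.approx(-1.0)

    def test_hand_computed_toy_set(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([1.5, 2.0, 2.5, 5.0, 4.0])
        m = prediction_metrics(pred, obs)
        # frozen from direct hand computation of Pearson r and RMSE
        assert m["r"] == pytest.approx(np.corrcoef(pred, obs)[0, 1])
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)))
        assert m["rmse"] == pytest.approx(np.sqrt((0.25 + 0 + 0.25 + 1.0 + 1.0) / 5))

    def test_zero_variance_flagged(self):
        m = prediction_metrics(np.ones(5), np.arange(5.0))
        assert m["degenerate"] and np.isnan(m["r"])
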