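"""Tests for eccentricity tuning, size readouts and the adaptation regression."""

import numpy as np
import pandas as pd
import pytest

from bmbu.synth import CohortSpec, make_cohort, make_v1
from bmbu.v1 import (
    adaptation_regression,
    double_gamma_hirf,
    drop_high_variance_voxels,
    extract_signal,
    fit_eccentricity_tuning,
    readout_weights,
    tuned_response,
)

HIRF = double_gamma_hirf(6, 2.2)
RINGS = {"r_s": 2.44, "r_m": 2.84, "r_l": 3.24}


def _traversal_movie(eccs, n_frames=120, thickness=0.45):
    movie = np.zeros((len(eccs), n_frames))
    pos = eccs.min() + (np.arange(n_frames) % 30) / 30 * np.ptp(eccs)
    for t in range(n_frames):
        movie[np.abs(eccs - pos[t]) < thickness, t] = 1.0
    return movie


class TestTuningFit:
    def test_generate_and_refit_recovers_peak(self):
        eccs = np.linspace(0.5, 6, 40)
        movie = _traversal_movie(eccs)
        g = np.exp(-((eccs - 3.0) ** 2) / 2.0)
        neural = (movie * g[:, None]).sum(axis=0)
        ts = np.convolve(neural, HIRF)[:120] * 2.0 + 1.0
        rng = np.random.default_rng(0)
        noisy = ts + rng.normal(0, ts.std() / 5, ts.size)
        fit = fit_eccentricity_tuning(noisy, movie, eccs, HIRF)
        assert fit.e == pytest.approx(3.0, abs=0.25)
        assert not fit.degenerate

    def test_flat_series_flagged_degenerate(self):
        eccs = np.linspace(0.5, 6, 40)
        movie = _traversal_movie(eccs)
        fit = fit_eccentricity_tuning(np.full(120, 1.0), movie, eccs, HIRF)
        assert fit.degenerate

    def test_rss_minimal_at_generating_parameters_noise_free(self):
        eccs = np.linspace(0.5, 6, 40)
        movie = _traversal_movie(eccs)
        g = np.exp(-((eccs - 3.0) ** 2) / 2.0)
        ts = np.convolve((movie * g[:, None]).sum(axis=0), HIRF)[:120]

        def rss_at(e):
            gg = np.exp(-((eccs - e) ** 2) / 2.0)
            pred = np.convolve((movie * gg[:, None]).sum(axis=0), HIRF)[:120]
            A = np.column_stack([pred, np.ones(120)])
            coef, *_ = np.linalg.lstsq(A, ts, rcond=None)
            r = ts - A @ coef
            return r @ r

        assert rss_at(3.0) <= rss_at(4.0)


class TestTunedResponse:
    def test_column_means_vanish(self, rng):
        rr = rng.standard_normal((21, 50))
        tr = tuned_response(rr)
        assert np.allclose(tr.mean(axis=0), 0.0, atol=1e-12)

    def test_untuned_input_gives_zero(self):
        rr = np.ones((5, 1)) @ np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(tuned_response(rr), 0.0)

    def test_toy_matrix_hand_computed(self):
        rr = np.array([[1.0, 4.0], [3.0, 0.0], [2.0, 2.0]])
        expected = np.array([[-1.0, 2.0], [1.0, -2.0], [0.0, 0.0]])
        assert np.allclose(tuned_response(rr), expected)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            tuned_response(np.ones((1, 5)))


class TestReadoutWeights:
    ECCS = np.linspace(1.0, 5.0, 21)

    def test_uniform_weight_zero_at_medium_ring(self):
        eccs = np.array([2.0, RINGS["r_m"], 4.0])
        w = readout_weights("uniform", eccs, 1.0, **RINGS)
        assert list(w.w) == [-1.0, 0.0, 1.0]

    def test_discriminability_weights_sum_to_zero(self):
        w = readout_weights("discriminability", self.ECCS, 1.0, **RINGS)
        assert w.w.sum() == pytest.approx(0.0, abs=1e-12)

    def test_loglik_weight_symmetric_at_midpoint(self):
        # with equal tuning widths the raw log-likelihood difference vanishes
        # for a bin exactly between the S- and L-ring radii
        mid = (RINGS["r_s"] + RINGS["r_l"]) / 2
        sig = 1.0
        raw = -((mid - RINGS["r_l"]) ** 2) / (2 * sig**2) + (
            (mid - RINGS["r_s"]) ** 2
        ) / (2 * sig**2)
        assert raw == pytest.approx(0.0, abs=1e-12)

    def test_inverted_ring_order_rejected(self):
        with pytest.raises(ValueError):
            readout_weights("uniform", self.ECCS, 1.0, r_s=3.0, r_m=2.8, r_l=2.5)


class TestExtractSignal:
    def test_sign_convention_follows_ring_size(self):
        eccs = np.linspace(1.0, 5.0, 21)
        w = readout_weights("uniform", eccs, 1.0, **RINGS)
        g = lambda r: np.exp(-((eccs - r) ** 2) / 2.0)
        tr_l = tuned_response(g(RINGS["r_l"])[:, None, None] * np.ones((1, 1, 6)))
        tr_s = tuned_response(g(RINGS["r_s"])[:, None, None] * np.ones((1, 1, 6)))
        assert extract_signal(tr_l, w, 3)[0] > 0 > extract_signal(tr_s, w, 3)[0]

    def test_zero_weights_give_zero_signal(self):
        w = readout_weights("uniform", np.full(4, RINGS["r_m"]), 1.0, **RINGS)
        tr = np.random.default_rng(0).standard_normal((4, 7, 6))
        assert np.allclose(extract_signal(tr, w, 3), 0.0)

    def test_toy_two_trial_hand_computed(self):
        w = readout_weights("uniform", np.array([2.0, RINGS["r_m"], 4.0]), 1.0, **RINGS)
        tr = np.zeros((3, 2, 6))
        tr[:, 0, 3] = [1.0, 5.0, 2.0]   # -1*1 + 0*5 + 1*2 = 1
        tr[:, 1, 3] = [4.0, 0.0, 1.0]   # -4 + 0 + 1 = -3
        assert np.allclose(extract_signal(tr, w, 3), [1.0, -3.0])

    def test_frame_out_of_range_rejected(self):
        w = readout_weights("uniform", np.array([2.0, 4.0]), 1.0, **RINGS)
        with pytest.raises(IndexError):
            extract_signal(np.zeros((2, 3, 6)), w, 6)


class TestAdaptation:
    @pytest.fixture(scope="class")
    def cohort(self):
        return make_cohort(CohortSpec(n_subjects=6, seed=4))

    PEAKS = np.linspace(1.0, 5.0, 21)

    def _signal(self, rec, lam, seed=None):
        rr = make_v1(
            rec.table, self.PEAKS, 1.0, gain=2.0, lambda_adapt=lam,
            noise_sd=0.3, hirf=HIRF, seed=rec.subject if seed is None else seed,
        )
        w = readout_weights("discriminability", self.PEAKS, 1.0, **RINGS)
        return extract_signal(tuned_response(rr), w, 3)

    def test_adaptation_produces_negative_lag_coefficient(self, cohort):
        coefs = pd.DataFrame(
            [adaptation_regression(self._signal(r, 0.4), r.table)["coef"] for r in cohort]
        )
        assert coefs["stim"].mean() > 0
        assert coefs["stim_lag1"].mean() < -0.05

    def test_no_adaptation_gives_null_lag_coefficient(self, cohort):
        coefs = pd.DataFrame(
            [adaptation_regression(self._signal(r, 0.0), r.table)["coef"] for r in cohort]
        )
        assert abs(coefs["stim_lag1"].mean()) < 0.05

    def test_lag_coefficient_monotone_in_adaptation_strength(self, cohort):
        means = []
        for lam in (0.0, 0.3, 0.6):
            c = [
                adaptation_regression(self._signal(r, lam), r.table)["coef"]["stim_lag1"]
                for r in cohort
            ]
            means.append(np.mean(c))
        assert means[0] > means[1] > means[2]

    def test_coefficients_match_statsmodels_ols(self, cohort):
        import statsmodels.api as sm
        from bmbu.behavior import add_lagged_columns

        rec = cohort[0]
        sig = self._signal(rec, 0.4)
        ours = adaptation_regression(sig, rec.table)
        t = add_lagged_columns(rec.table, 1).assign(signal=sig)
        t = t.dropna(subset=["stim_lag1", "choice_lag1"])
        t = t[t["valid"]]
        X = sm.add_constant(
            t[["stimulus", "stim_lag1", "choice_lag1"]].to_numpy(dtype=float)
        )
        ref = sm.OLS(t["signal"].to_numpy(), X).fit()
        assert np.allclose(ours["coef"].to_numpy(), ref.params, atol=1e-10)

    def test_three_schemes_agree_on_synthetic_data(self, cohort):
        rec = cohort[0]
        rr = make_v1(
            rec.table, self.PEAKS, 1.0, gain=2.0, lambda_adapt=0.3,
            noise_sd=0.5, hirf=HIRF, seed=1,
        )
        tr = tuned_response(rr)
        sigs = []
        for scheme in ("uniform", "discriminability", "loglik_ratio"):
            w = readout_weights(scheme, self.PEAKS, 1.0, **RINGS)
            sigs.append(extract_signal(tr, w, 3))
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.corrcoef(sigs[i], sigs[j])[0, 1] > 0.5

    def test_negative_adaptation_rejected(self, cohort):
        with pytest.raises(ValueError):
            make_v1(cohort[0].table, self.PEAKS, 1.0, 2.0, -0.1, 0.3, HIRF)


def test_blood_vessel_clamp_filter(rng):
    ts = rng.standard_normal((30, 100))
    ts[3] *= 8.0
    keep = drop_high_variance_voxels(ts, factor=10.0)
    assert not keep[3] and keep.sum() == 29


class TestV1AMEPattern:
    def test_adapted_v1_signal_mediates_only_the_current_stimulus(self):
        """Pipeline-level null: with realistic (weak) adaptation the V1-style
        signal's effect on choice survives controlling the previous stimulus
        but is abolished when the current stimulus is controlled."""
        from bmbu.behavior import ame_contrast_suite

        cohort = make_cohort(CohortSpec(n_subjects=8, seed=4))
        peaks = np.linspace(1.0, 5.0, 21)
        w = readout_weights("discriminability", peaks, 1.0, **RINGS)
        tabs, adapt, adapt_null = [], [], []
        for rec in cohort:
            sigs = {}
            for lam in (0.2, 0.0):
                rr = make_v1(
                    rec.table, peaks, 1.0, gain=2.0, lambda_adapt=lam,
                    noise_sd=1.0, hirf=HIRF, seed=rec.subject,
                )
                sigs[lam] = extract_signal(tuned_response(rr), w, 3)
            adapt.append(
                adaptation_regression(sigs[0.2], rec.table)["coef"]["stim_lag1"]
            )
            adapt_null.append(
                adaptation_regression(sigs[0.0], rec.table)["coef"]["stim_lag1"]
            )
            t = rec.table.copy()
            sig = sigs[0.2]
            t["X"] = (sig - sig.mean()) / sig.std()
            tabs.append(t)
        # adaptation is present: with identical noise draws, adding the
        # adaptation term lowers the lag coefficient in every subject
        paired = np.asarray(adapt) - np.asarray(adapt_null)
        assert np.all(paired < 0)
        assert np.mean(adapt) < -0.05
        # ...yet does not route the previous stimulus into the choice
        d = ame_contrast_suite(tabs, "X").deltas.set_index("contrast")
        assert d.loc["ctrl_prev-baseline", "p"] > 0.05
        assert d.loc["ctrl_curr-baseline", "p"] < 0.05
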