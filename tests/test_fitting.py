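"""Tests for trial exclusions, the likelihood, ML fitting and model comparison."""

import numpy as np
import pandas as pd
import pytest

from bmbu.design import build_schedule, schedule_table
from bmbu.fitting import (
    FitConfig,
    compare_models,
    fit_bmbu,
    fit_constant,
    nagelkerke_r2,
    neg_log_likelihood,
    neg_log_likelihood_constant,
)
from bmbu.observer import ObserverParams, choice_probability_mc, simulate_observer
from bmbu.trials import exclude_trials, prepare_design


def _session(params, n_runs=8, seed=0, design_seed=3):
    design = schedule_table(build_schedule(n_runs=n_runs, seed=design_seed))
    stim = design["stimulus"].to_numpy()
    runs = design["run"].to_numpy()
    sim = simulate_observer(stim, runs, params, n_reps=1, seed=seed)
    design = design.assign(choice=sim["d"][0], rt=1.0)
    return design


class TestExcludeTrials:
    def test_first_trial_of_each_run_invalid(self):
        t = pd.DataFrame(
            {"run": np.repeat([0, 1], 26), "trial": list(range(26)) * 2, "rt": 0.5}
        )
        out = exclude_trials(t)
        assert out["valid"].sum() == 50
        assert not out.groupby("run")["valid"].first().any()

    def test_rt_cutoff_is_strict_less_than(self):
        t = pd.DataFrame({"run": [0, 0, 0], "trial": [0, 1, 2], "rt": [0.5, 0.29, 0.30]})
        out = exclude_trials(t)
        assert list(out["valid"]) == [False, False, True]

    def test_empty_table_passes_through(self):
        t = pd.DataFrame({"run": [], "trial": [], "rt": []})
        out = exclude_trials(t)
        assert out.empty and "valid" in out.columns

    def test_missing_rt_column_rejected(self):
        with pytest.raises(KeyError):
            exclude_trials(pd.DataFrame({"run": [0]}))


class TestLikelihood:
    def test_constant_model_at_boundary_is_t_log2(self):
        t = pd.DataFrame(
            {"run": 0, "trial": range(10), "stimulus": 0.0, "choice": [0, 1] * 5, "rt": 1.0}
        )
        nll = neg_log_likelihood_constant(t, mu0=0.0, sigma_m=1.0)
        assert nll == pytest.approx(9 * np.log(2))  # first trial excluded

    def test_likelihood_prefers_generating_noise_level(self):
        """Mean NLL at the generating sigma_m beats a doubled one."""
        p = ObserverParams(0.0, 2.0, 0.8, 0.6)
        p2 = ObserverParams(0.0, 2.0, 1.6, 0.6)
        diffs = []
        for seed in range(30):
            t = _session(p, n_runs=2, seed=seed)
            diffs.append(neg_log_likelihood(t, p2) - neg_log_likelihood(t, p))
        assert np.mean(diffs) > 0

    def test_closed_form_matches_monte_carlo_per_trial(self):
        p = ObserverParams(0.1, 2.5, 0.9, 0.7)
        t = _session(p, n_runs=1, seed=5)
        design = prepare_design(t)
        from bmbu.observer import _choice_probability_padded

        probs = _choice_probability_padded(design["stimulus"], design["history"], p)
        for i in (1, 5, 12, 25):
            hist = design["history"][i]
            hist = list(hist[np.isfinite(hist)])
            mc = choice_probability_mc(design["stimulus"][i], hist, p, n=4 * 10**5, seed=i)
            assert probs[i] == pytest.approx(mc, abs=0.005)


class TestFitting:
    def test_same_seed_gives_identical_fit(self):
        p = ObserverParams(0.0, 2.0, 0.8, 0.6)
        t = _session(p, seed=2)
        cfg = FitConfig(n_starts=10, n_top=3, seed=4)
        a, b = fit_bmbu(t, cfg), fit_bmbu(t, cfg)
        assert np.array_equal(a.params_hat.as_array(), b.params_hat.as_array())
        assert a.loglik == b.loglik

    def test_pooled_sessions_recover_noise_and_decay(self):
        """More data pins down the measurement noise and memory decay."""
        p = ObserverParams(0.1, 2.0, 0.8, 0.7)
        parts = []
        for k in range(6):
            s = _session(p, seed=10 + k, design_seed=k)
            s["run"] = s["run"] + 8 * k
            parts.append(s)
        pooled = pd.concat(parts, ignore_index=True)
        fit = fit_bmbu(pooled, FitConfig(n_starts=40, n_top=8, seed=1))
        hat = fit.params_hat
        assert hat.sigma_m == pytest.approx(p.sigma_m, rel=0.3)
        assert hat.kappa == pytest.approx(p.kappa, rel=0.6)

    def test_updating_model_never_fits_worse_than_constant(self):
        """The constant boundary is the infinite-decay limit of the model."""
        t = _session(ObserverParams(0.0, 2.0, 1.0, 0.8), seed=7)
        fb = fit_bmbu(t, FitConfig(n_starts=30, n_top=5, seed=0))
        fc = fit_constant(t, FitConfig(seed=0))
        assert fb.loglik >= fc.loglik - 1.0

    def test_fit_translation_equivariance(self):
        p = ObserverParams(0.0, 2.0, 0.8, 0.6)
        t = _session(p, seed=3)
        shift = 1.5
        t2 = t.assign(stimulus=t["stimulus"] + shift)
        cfg = FitConfig(n_starts=25, n_top=5, seed=0)
        b1 = cfg.bounds
        cfg2 = FitConfig(
            n_starts=25, n_top=5, seed=0,
            bounds=((b1[0][0] + shift, b1[0][1] + shift),) + b1[1:],
        )
        f1, f2 = fit_bmbu(t, cfg), fit_bmbu(t2, cfg2)
        assert f2.params_hat.mu0 - f1.params_hat.mu0 == pytest.approx(shift, abs=0.05)
        assert f2.loglik == pytest.approx(f1.loglik, abs=0.05)


class TestModelComparison:
    def test_nagelkerke_arithmetic_oracle(self):
        # hand-computed from L = e^-100, L0 = e^-120, T = 200
        val = nagelkerke_r2(-100.0, -120.0, 200)
        expected = (1 - np.exp(-0.2)) / (1 - np.exp(-1.2))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.2594, abs=1e-4)

    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(-120.0, -120.0, 200) == pytest.approx(0.0)

    def test_updating_cohort_favors_updating_model(self, behavior_cohort):
        """Mean AIC difference is negative on boundary-updating cohorts."""
        deltas = []
        for rec in behavior_cohort[:4]:
            fb = fit_bmbu(rec.table, FitConfig(n_starts=30, n_top=5, seed=0))
            fc = fit_constant(rec.table, FitConfig(seed=0))
            cmp = compare_models(fb, fc, rec.table)
            deltas.append(cmp.delta_aic)
            assert 0 <= cmp.nagelkerke_bmbu <= 1
        assert np.mean(deltas) < 0

    def test_mismatched_trial_sets_rejected(self):
        t = _session(ObserverParams(0.0, 2.0, 1.0, 0.8), seed=1)
        fb = fit_bmbu(t, FitConfig(n_starts=5, n_top=2, seed=0))
        fc = fit_constant(t.iloc[:100], FitConfig(seed=0))
        with pytest.raises(ValueError):
            compare_models(fb, fc, t)
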