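import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numaniso.analysis import (
    code_contrasts,
    compare_experiments,
    compute_dv,
    fit_lmm,
    lrt_interaction,
    power_simulation,
    prepare_trials,
    screen_participants,
    FitResult,
)
from numaniso.observer import ObserverParams, design_session, simulate_trials


def make_participant(pid, n_main=300, n_control=30, n_invalid=0, n_ctl_wrong=0):
    """Hand-built trial rows for screening tests."""
    rows = []
    for i in range(n_main):
        resp = np.nan if i < n_invalid else 40.0
        rows.append(
            dict(participant=pid, experiment="1a", block=0, trial=i,
                 arrangement="radial" if i % 2 else "tangential",
                 polarity_scheme="uniform_dark", numerosity_range="small",
                 true_n=40, response=resp, is_control=False, block_mean=39.0)
        )
    for i in range(n_control):
        correct = i >= n_ctl_wrong
        rows.append(
            dict(participant=pid, experiment="1a", block=-1, trial=n_main + i,
                 arrangement="radial", polarity_scheme="uniform_dark",
                 numerosity_range="small", true_n=3,
                 response=3.0 if correct else 2.0, is_control=True,
                 block_mean=3.0)
        )
    return pd.DataFrame(rows)


class TestScreenParticipants:
    def test_clean_participant_kept(self):
        rep = screen_participants(make_participant(0))
        assert rep.kept == (0,)
        assert rep.excluded == {}

    def test_exactly_5_percent_invalid_kept(self):
        # 330 trials total; 16 invalid is 4.85% -> kept; 17 is 5.15% -> excluded
        t = pd.concat(
            [make_participant(0, n_invalid=16), make_participant(1, n_invalid=17)]
        )
        rep = screen_participants(t)
        assert 0 in rep.kept
        assert rep.excluded.get(1) == "invalid_responses"

    def test_90_percent_control_accuracy_excluded(self):
        # 3/30 wrong = exactly 10% incorrect -> excluded; 2/30 -> kept
        t = pd.concat(
            [make_participant(0, n_ctl_wrong=3), make_participant(1, n_ctl_wrong=2)]
        )
        rep = screen_participants(t)
        assert rep.excluded.get(0) == "subitizing_fail"
        assert 1 in rep.kept

    def test_incomplete_excluded(self):
        t = pd.concat([make_participant(0), make_participant(1, n_main=200)])
        rep = screen_participants(t)
        assert rep.excluded.get(1) == "incomplete"

    def test_idempotent(self):
        t = pd.concat(
            [make_participant(0), make_participant(1, n_ctl_wrong=5)]
        )
        rep1 = screen_participants(t)
        screened = t[t.participant.isin(rep1.kept)]
        rep2 = screen_participants(screened)
        assert rep2.kept == rep1.kept
        assert rep2.excluded == {}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            screen_participants(pd.DataFrame(columns=["participant", "response"]))


class TestComputeDv:
    @pytest.mark.parametrize(
        "resp,true_n,expected", [(38, 40, -2), (40, 40, 0), (45, 40, 5)]
    )
    def test_examples(self, resp, true_n, expected):
        assert compute_dv(resp, true_n) == expected

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            compute_dv(float("nan"), 40)


class TestCodeContrasts:
    @pytest.mark.parametrize(
        "level,factor,code",
        [
            ("radial", "arrangement", -0.5),
            ("tangential", "arrangement", 0.5),
            ("uniform", "polarity", 0.5),
            ("uniform_dark", "polarity", 0.5),
            ("uniform_light", "polarity", 0.5),
            ("mixed", "polarity", -0.5),
            ("small", "numerosity_range", -0.5),
            ("large", "numerosity_range", 0.5),
        ],
    )
    def test_codes(self, level, factor, code):
        assert code_contrasts(level, factor) == code

    def test_codes_sum_to_zero(self):
        assert code_contrasts("radial", "arrangement") + code_contrasts(
            "tangential", "arrangement"
        ) == 0

    def test_unknown_level(self):
        with pytest.raises(ValueError):
            code_contrasts("diagonal", "arrangement")


class TestFitLmm:
    def test_noiseless_recovery(self):
        params = ObserverParams(
            beta0=0, beta_arr=2, sd_intercept=0, sd_arr_slope=0, resid_sd=0
        )
        data = prepare_trials(simulate_trials(design_session("1a"), params, 5, seed=0))
        fit = fit_lmm(data)
        assert fit["x_arr"]["estimate"] == pytest.approx(2.0, abs=1e-8)

    def test_monte_carlo_recovery(self):
        """Mean recovered arrangement effect over replicates centers on
        the injected value (reduced scale)."""
        params = ObserverParams(
            beta0=-2, beta_arr=0.89, sd_intercept=2, sd_arr_slope=1, resid_sd=4
        )
        plan = design_session("1a")
        estimates = []
        for seed in range(12):
            data = prepare_trials(simulate_trials(plan, params, 20, seed=seed))
            estimates.append(fit_lmm(data)["x_arr"]["estimate"])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 0.89) < 3 * se

    def test_permutation_null_destroys_effect(self):
        params = ObserverParams(
            beta0=0, beta_arr=3, sd_intercept=1, sd_arr_slope=0.5, resid_sd=3
        )
        data = prepare_trials(
            simulate_trials(design_session("1a"), params, 15, seed=2)
        )
        rng = np.random.default_rng(0)
        data["x_arr"] = rng.permutation(data["x_arr"].to_numpy())
        fit = fit_lmm(data)
        assert abs(fit["x_arr"]["estimate"]) < 3 * fit["x_arr"]["se"]

    def test_df_and_estimation_recorded(self):
        params = ObserverParams()
        data = prepare_trials(simulate_trials(design_session("1a"), params, 6, seed=1))
        fit = fit_lmm(data, estimation="ml")
        assert fit.df == 5.0
        assert fit.estimation == "ml"
        assert fit.df_method == "participants-1"

    def test_numerosity_variance_component_variant(self):
        params = ObserverParams()
        data = prepare_trials(simulate_trials(design_session("1a"), params, 6, seed=1))
        fit = fit_lmm(data, random_spec="intercept+slope+numerosity")
        assert "x_arr" in fit.terms


class TestLrtInteraction:
    def _fit(self, ll, terms, estimation="ml"):
        k = len(terms)
        return FitResult(
            terms=terms, estimates=(0.0,) * k, se=(1.0,) * k, t=(0.0,) * k,
            df=10.0, p=(1.0,) * k, log_likelihood=ll, converged=True,
            estimation=estimation,
        )

    def test_identical_likelihoods(self):
        full = self._fit(-100.0, ("intercept", "x_arr", "x_arr:x_pol"))
        red = self._fit(-100.0, ("intercept", "x_arr"))
        res = lrt_interaction(full, red)
        assert res.chi_square == 0.0
        assert res.p == pytest.approx(1.0)

    def test_chi_square_tail_oracle(self):
        # ll difference 0.125 -> chi2 0.25, p = sf(0.25, 1) ~ 0.617
        full = self._fit(-99.875, ("intercept", "x_arr", "x_arr:x_pol"))
        red = self._fit(-100.0, ("intercept", "x_arr"))
        res = lrt_interaction(full, red)
        assert res.chi_square == pytest.approx(0.25)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(0.25, 1), abs=1e-12)
        assert res.p == pytest.approx(0.617, abs=0.001)

    def test_reml_rejected(self):
        full = self._fit(-99.0, ("intercept", "x_arr", "x_arr:x_pol"), "reml")
        red = self._fit(-100.0, ("intercept", "x_arr"), "reml")
        with pytest.raises(ValueError):
            lrt_interaction(full, red)

    def test_non_nested_rejected(self):
        full = self._fit(-99.0, ("intercept", "x_arr"))
        red = self._fit(-100.0, ("intercept", "x_pol"))
        with pytest.raises(ValueError):
            lrt_interaction(full, red)

    def test_detects_true_interaction(self):
        """Power-by-simulation oracle at reduced scale: a 2-item
        arrangement x polarity interaction is detected most of the time."""
        plan = design_session("4")
        hits = 0
        n_reps = 12
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            params = ObserverParams(
                beta0=0, beta_arr=1, beta_pol=1, sd_intercept=1,
                sd_arr_slope=0.5, resid_sd=3,
            )
            trials = simulate_trials(plan, params, 12, seed=seed)
            data = prepare_trials(trials)
            # inject the interaction directly on the dv scale
            data["dv"] = data["dv"] + 2.0 * data["x_arr"] * data["x_pol"] * 2.0
            full = fit_lmm(
                data, fixed_terms=("x_arr", "x_pol", "x_arr:x_pol"), estimation="ml"
            )
            red = fit_lmm(data, fixed_terms=("x_arr", "x_pol"), estimation="ml")
            if lrt_interaction(full, red).p < 0.05:
                hits += 1
        assert hits / n_reps > 0.8


class TestCompareExperiments:
    def _table(self, tag, beta0, n=8, seed=0, pid_offset=0):
        params = ObserverParams(
            beta0=beta0, beta_arr=1.0, sd_intercept=1, sd_arr_slope=0.5, resid_sd=3
        )
        t = simulate_trials(design_session(tag), params, n, seed=seed)
        t["participant"] = t["participant"] + pid_offset
        t["experiment"] = tag
        return t

    def test_identical_experiments_give_null_term(self):
        a = prepare_trials(self._table("1a", -3.0, seed=1))
        b = prepare_trials(self._table("1a", -3.0, seed=1, pid_offset=100))
        b["experiment"] = "1x"
        fits = compare_experiments([a, b], coding="simple")
        exp = fits["dv"]["x_exp"]
        assert abs(exp["estimate"]) < 3 * max(exp["se"], 1e-6)

    def test_sum_coding_recovers_grand_mean(self):
        a = prepare_trials(self._table("1a", -6.0, seed=2))
        b = prepare_trials(self._table("1b", -6.0, seed=3, pid_offset=100))
        fits = compare_experiments([a, b], coding="sum")
        grand = fits["dv"]["intercept"]
        assert grand["estimate"] == pytest.approx(-6.0, abs=1.0)

    def test_abs_dv_sign_invariance(self):
        a = prepare_trials(self._table("1a", -3.0, seed=4))
        b = prepare_trials(self._table("1b", -3.0, seed=5, pid_offset=100))
        fits1 = compare_experiments([a, b], coding="simple")
        a2, b2 = a.copy(), b.copy()
        a2["dv"] = -a2["dv"]
        b2["dv"] = -b2["dv"]
        fits2 = compare_experiments([a2, b2], coding="simple")
        assert fits1["abs_dv"].estimates == pytest.approx(
            fits2["abs_dv"].estimates, rel=1e-6
        )

    def test_overlapping_participants_rejected(self):
        a = prepare_trials(self._table("1a", -3.0, seed=6))
        b = prepare_trials(self._table("1b", -3.0, seed=7))
        with pytest.raises(ValueError):
            compare_experiments([a, b])


class TestPowerSimulation:
    def test_saturated_power(self):
        params = ObserverParams(
            beta_arr=10.0, sd_intercept=0.5, sd_arr_slope=0.2, resid_sd=1.0
        )
        res = power_simulation(
            params, 6, design_session("1a"), n_reps=10, seed=0
        )
        assert res.power == 1.0

    def test_reproducible(self):
        params = ObserverParams(beta_arr=0.5)
        r1 = power_simulation(params, 5, design_session("1a"), n_reps=5, seed=9)
        r2 = power_simulation(params, 5, design_session("1a"), n_reps=5, seed=9)
        assert r1 == r2

    def test_ci_brackets_point_estimate(self):
        params = ObserverParams(beta_arr=1.0)
        res = power_simulation(params, 6, design_session("1a"), n_reps=8, seed=2)
        assert res.ci_low <= res.power <= res.ci_high
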