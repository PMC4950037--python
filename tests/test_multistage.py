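"""Error-spending schedules, the maximum-information search and the
multi-stage trial simulator."""

import numpy as np
import pytest
from scipy import optimize, stats

from mamsrb import (
    DesignSpec,
    EffectConfiguration,
    solve_boundaries,
    solve_max_information,
    solve_stagewise_boundaries,
)
from mamsrb.model import NONE, simulate_scores
from mamsrb.multistage import (
    multistage_power,
    parse_spending,
    run_multistage_trial,
    simulate_multistage,
)
from .test_boundaries import make_spec


@pytest.fixture(scope="module")
def tailor_schedule(tailor_spec):
    return solve_max_information(tailor_spec.replace(n_stages=2))


class TestSpendingFunctions:
    @pytest.mark.parametrize("ident", ["pow:1", "pow:2", "pow:3", "obf"])
    def test_valid_spending_shape(self, ident):
        f = parse_spending(ident, 0.05)
        assert f(0.0) == 0.0
        assert f(1.0) == pytest.approx(0.05, abs=1e-12)
        assert f(1.7) == pytest.approx(0.05, abs=1e-12)
        t = np.linspace(0.05, 1.0, 30)
        vals = [f(x) for x in t]
        assert np.all(np.diff(vals) > 0)

    def test_bad_identifiers_rejected(self):
        with pytest.raises(ValueError):
            parse_spending("pocock-ish", 0.05)
        with pytest.raises(ValueError):
            parse_spending("pow:-1", 0.05)


class TestScheduleSolving:
    def test_single_look_reduces_to_fixed_design(self, tailor_spec, tailor_design):
        spec1 = tailor_spec.replace(n_stages=1)
        sched = solve_max_information(spec1)
        sol = tailor_design
        assert sched.max_info_E == pytest.approx(sol.I_star, abs=5e-3)
        assert sched.u_E[0] == pytest.approx(sol.boundaries_at_I_star.u_E, abs=5e-3)
        assert sched.u_S[0] == pytest.approx(sol.boundaries_at_I_star.u_S, abs=5e-3)
        assert sched.l_E[0] == sched.u_E[0]

    def test_single_arm_two_looks_match_classical_gst(self):
        """With one arm and no gate, the schedule must agree with a
        textbook one-sided error-spending design, computed here by direct
        bivariate-normal integration."""
        spec = make_spec(
            n_arms=1, c=-np.inf, n_stages=2, spending_upper="pow:1", spending_lower="pow:1"
        )
        info = np.array([20.0, 40.0])
        l, u = solve_stagewise_boundaries(spec, info, "efficacy")

        alpha = spec.alpha
        # oracle: stage 1 spends alpha/2 and (1-alpha)/2
        u1 = np.sqrt(info[0]) * stats.norm.ppf(1 - alpha / 2)
        l1 = np.sqrt(info[0]) * stats.norm.ppf((1 - alpha) / 2)
        cov = np.array([[info[0], info[0]], [info[0], info[1]]])
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)

        def stage2_upper(u2):
            # P(l1 < Z1 < u1, Z2 >= u2)
            p_box = mvn.cdf([u1, u2]) - mvn.cdf([l1, u2])
            p_cont = stats.norm.cdf(u1 / np.sqrt(info[0])) - stats.norm.cdf(
                l1 / np.sqrt(info[0])
            )
            return p_cont - p_box  # continue at 1 and exceed u2 at stage 2

        u2 = optimize.brentq(lambda x: stage2_upper(x) - alpha / 2, 0.0, 50.0)
        assert u[0] == pytest.approx(u1, abs=2e-3)
        assert l[0] == pytest.approx(l1, abs=2e-3)
        assert u[1] == pytest.approx(u2, abs=5e-3)
        assert l[1] == u[1]

    def test_stagewise_spend_matches_plan(self, tailor_spec):
        spec = tailor_spec.replace(n_stages=3)
        info = np.array([1, 2, 3]) / 3 * 60.0
        for endpoint in ("efficacy", "safety"):
            l, u, diag = solve_stagewise_boundaries(
                spec, info, endpoint, return_diagnostics=True
            )
            level = diag["pi_U"].sum()
            f = parse_spending(spec.spending_upper, level)
            planned = np.diff([f(t) for t in [0, 1 / 3, 2 / 3, 1.0]])
            assert np.allclose(diag["pi_U"], planned, atol=1e-6)
            assert np.all(l[:-1] < u[:-1])
            assert l[-1] == u[-1]

    def test_efficacy_total_spend_is_alpha(self, tailor_spec):
        spec = tailor_spec.replace(n_stages=2)
        info = np.array([30.0, 60.0])
        _, _, diag = solve_stagewise_boundaries(
            spec, info, "efficacy", return_diagnostics=True
        )
        assert diag["pi_U"].sum() == pytest.approx(spec.alpha, abs=1e-10)

    def test_infeasible_information_sequence_rejected(self, tailor_spec):
        with pytest.raises(ValueError):
            solve_stagewise_boundaries(tailor_spec, [40.0, 30.0], "efficacy")


class TestMaxInformationSearch:
    def test_interim_looks_cost_information(self, tailor_spec, tailor_design, tailor_schedule):
        # binding futility + early looks require more maximum information
        assert tailor_schedule.max_info_E > tailor_design.I_star

    def test_schedule_power_hits_target(self, tailor_spec, tailor_schedule):
        p = multistage_power(
            tailor_spec.replace(n_stages=2),
            tailor_schedule.info_E,
            tailor_schedule.l_E,
            tailor_schedule.u_E,
        )
        assert p == pytest.approx(0.9, abs=2e-3)

    def test_safety_information_scaled_by_variance_ratio(self):
        spec = make_spec(n_arms=2, sigma_E=1.0, sigma_S=2.0, rho=0.2, n_stages=2)
        sched = solve_max_information(spec)
        assert np.allclose(sched.info_S, sched.info_E / 4.0)
        assert sched.n_star == int(np.ceil(2 * sched.max_info_E))


class TestTrialExecution:
    def test_fwer_controlled_three_stages(self, tailor_spec):
        spec = tailor_spec.replace(n_stages=3)
        sched = solve_max_information(spec)
        se3 = 3 * np.sqrt(0.05 * 0.95 / 100_000)
        for cfg in (
            EffectConfiguration.worst_case_efficacy(spec),
            EffectConfiguration.worst_case_safety(spec),
        ):
            res = simulate_multistage(spec, cfg, sched, 100_000, seed=17)
            assert res["reject"].mean() <= 0.05 + se3
            # proper termination: every path decided by stage J
            assert res["stage"].max() <= 3

    def test_expected_information_saved_under_null(self, tailor_spec, tailor_schedule):
        spec = tailor_spec.replace(n_stages=2)
        cfg = EffectConfiguration.worst_case_efficacy(spec)
        res = simulate_multistage(spec, cfg, tailor_schedule, 50_000, seed=18)
        mean_info = tailor_schedule.info_E[res["stage"] - 1].mean()
        assert mean_info < tailor_schedule.max_info_E

    def test_unsafe_arms_stop_at_the_gate(self, tailor_spec, tailor_schedule):
        spec = tailor_spec.replace(n_stages=2)
        g = spec.gamma_surrogate
        cfg = EffectConfiguration.common(4, g, -g)
        res = simulate_multistage(spec, cfg, tailor_schedule, 5_000, seed=19)
        assert not res["reject"].any()
        assert (res["stage"] == 1).all()
        assert (res["selected"] == NONE).all()
        d = run_multistage_trial(spec, cfg, tailor_schedule, seed=20)
        assert d.outcome == "accept_no_safe_arm"

    def test_spend_conservation_by_simulation(self, tailor_spec, tailor_schedule):
        """Stagewise rejection probabilities under the efficacy worst case
        sum to alpha and split as the spending function dictates."""
        spec = tailor_spec.replace(n_stages=2)
        cfg = EffectConfiguration.worst_case_efficacy(spec)
        n = 200_000
        res = simulate_multistage(spec, cfg, tailor_schedule, n, seed=21)
        stage_rej = [
            (res["reject"] & (res["stage"] == j + 1)).mean() for j in range(2)
        ]
        planned = np.diff([0.0, 0.05 * 0.5**2, 0.05])
        for got, want in zip(stage_rej, planned):
            assert abs(got - want) < 3 * np.sqrt(want * (1 - want) / n) + 1e-4

    def test_independent_increments_of_selected_arm(self, tailor_spec):
        """Score increments computed from *cumulative patient-level data*
        are uncorrelated with the selected arm's stage-1 statistic — the
        property justifying the univariate recursion after selection."""
        from mamsrb.model import score_statistics, select_treatment, simulate_responses

        spec = tailor_spec
        cfg = EffectConfiguration.null(4)
        n1, n2, reps = 30, 60, 4_000
        z1s, incs = [], []
        rng = np.random.default_rng(22)
        for _ in range(reps):
            r = simulate_responses(spec, cfg, n2, rng)
            s1 = score_statistics(r[:, :n1], spec)
            s2 = score_statistics(r, spec)
            sel = select_treatment(s1, spec)
            if sel.selected == NONE:
                continue
            z1s.append(s1.Z_E[sel.selected])
            incs.append(s2.Z_E[sel.selected] - s1.Z_E[sel.selected])
        corr = np.corrcoef(z1s, incs)[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(len(z1s))

    def test_reproducible_given_seed(self, tailor_spec, tailor_schedule):
        spec = tailor_spec.replace(n_stages=2)
        cfg = EffectConfiguration.power_config(spec)
        a = simulate_multistage(spec, cfg, tailor_schedule, 10_000, seed=24)
        b = simulate_multistage(spec, cfg, tailor_schedule, 10_000, seed=24)
        assert np.array_equal(a["reject"], b["reject"])
        assert np.array_equal(a["stage"], b["stage"])
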