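"""Tests for the survival-time calculus and resection-protocol machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbmgrowth.gompertz_sde import FPTSample, deterministic_crossing_time
from gbmgrowth.survival_calc import (
    ResectionPlan,
    build_fpt_grid,
    eval_mean_surface,
    eval_sd_surface,
    fpt_normal_summary,
    immediate_resection_survival,
    staged_survival,
    untreated_survival,
)


class TestFPTNormalSummary:
    def test_hand_computation(self):
        s = fpt_normal_summary(FPTSample(v0=10, vc=20, times=[30.0, 36.0]))
        assert s.mu == pytest.approx(33.0)
        assert s.sigma == pytest.approx(4.2426, abs=1e-4)

    def test_identical_draws_give_zero_sd(self):
        s = fpt_normal_summary(FPTSample(v0=10, vc=20, times=[40.0] * 5))
        assert s.sigma == 0.0

    def test_censored_draws_warn(self):
        with pytest.warns(UserWarning, match="censored"):
            fpt_normal_summary(FPTSample(v0=10, vc=20, times=[30.0, 31.0], n_censored=2))

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            fpt_normal_summary(FPTSample(v0=10, vc=20, times=[30.0]))


class TestSurfaceEvaluation:
    @pytest.mark.parametrize(
        "v0, vc, expected",
        [(1, 100, 266.68), (50, 100, 137.17), (25, 100, 203.25)],
    )
    def test_mean_surface_values(self, published_surfaces, v0, vc, expected):
        with pytest.warns(UserWarning) if v0 < 10 else _no_warning():
            val = eval_mean_surface(published_surfaces.mean, v0, vc)
        assert val == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "v0, vc, expected",
        [(1, 100, 29.42), (50, 100, 25.75), (25, 100, 27.62)],
    )
    def test_sd_surface_values(self, published_surfaces, v0, vc, expected):
        with pytest.warns(UserWarning) if v0 < 10 else _no_warning():
            val = eval_sd_surface(published_surfaces.sd, v0, vc)
        assert val == pytest.approx(expected, abs=0.01)

    def test_negative_extrapolation_is_warned_not_clamped(self, published_surfaces):
        """Far outside the grid the plane goes negative; the value is kept."""
        with pytest.warns(UserWarning):
            val = eval_mean_surface(published_surfaces.mean, 1.0, 2.0)
        assert val == pytest.approx(-8.017, abs=0.01)


def _no_warning():
    import contextlib
    import warnings

    @contextlib.contextmanager
    def ctx():
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            yield

    return ctx()


class TestUntreatedSurvival:
    def test_published_table_round_numbers(self, published_surfaces):
        """Untreated survival for 1, 30 and 50 mL tumors, to the nearest day."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cases = {1: (267, 29), 30: (190, 27), 50: (137, 26)}
            for v0, (mu_ref, sd_ref) in cases.items():
                s = untreated_survival(v0, 100.0, published_surfaces)
                assert round(s.mu) == mu_ref
                assert round(s.sigma) == sd_ref

    def test_mean_decreases_with_diagnosed_volume(self, published_surfaces):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means = [untreated_survival(v, 100.0, published_surfaces).mu for v in (1, 10, 30, 50)]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_invalid_volumes_rejected(self, published_surfaces):
        with pytest.raises(ValueError):
            untreated_survival(100.0, 50.0, published_surfaces)


class TestImmediateResection:
    def test_published_values(self, published_surfaces):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s50 = immediate_resection_survival(50.0, 0.5, 100.0, published_surfaces)
            s90 = immediate_resection_survival(50.0, 0.9, 100.0, published_surfaces)
        assert (round(s50.mu), round(s50.sigma)) == (203, 28)
        assert round(s90.mu) == 256

    def test_zero_cut_is_untreated(self, published_surfaces):
        a = immediate_resection_survival(30.0, 0.0, 100.0, published_surfaces)
        b = untreated_survival(30.0, 100.0, published_surfaces)
        assert a == b


class TestStagedSurvival:
    def test_delayed_resection_published_values(self, published_surfaces):
        """1 mL tumor allowed to reach 50 mL, then cut: 330 d at 50%, 393 d at 98%."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s50 = staged_survival(
                ResectionPlan(v0=1.0, stages=[(50.0, 0.5)], vT=100.0), published_surfaces
            )
            s98 = staged_survival(
                ResectionPlan(v0=1.0, stages=[(50.0, 0.98)], vT=100.0), published_surfaces
            )
        assert (round(s50.mu), round(s50.sigma)) == (330, 29)
        assert round(s98.mu) == 393

    def test_double_resection_published_totals(self, published_surfaces):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            big = staged_survival(
                ResectionPlan(v0=1.0, stages=[(50.0, 0.8), (90.0, 0.5)], vT=100.0),
                published_surfaces,
            )
            small = staged_survival(
                ResectionPlan(v0=1.0, stages=[(2.0, 0.8), (15.0, 0.5)], vT=100.0),
                published_surfaces,
            )
        assert (round(big.mu), round(big.sigma)) == (492, 36)
        assert round(small.mu) == 271  # includes a negative first-segment mean

    def test_trivial_plan_reduces_to_untreated(self, published_surfaces):
        """A cut of 0 triggered at the diagnosed volume changes nothing."""
        plan = ResectionPlan(v0=30.0, stages=[(30.0, 0.0)], vT=100.0)
        s = staged_survival(plan, published_surfaces)
        u = untreated_survival(30.0, 100.0, published_surfaces)
        assert s == u

    def test_matches_correlated_normal_monte_carlo(self, published_surfaces):
        """Cholesky Monte-Carlo oracle for the correlated-normal sum."""
        import warnings

        rng = np.random.default_rng(42)
        A = rng.standard_normal((3, 3))
        cov = A @ A.T
        d = np.sqrt(np.diag(cov))
        R = cov / np.outer(d, d)
        plan = ResectionPlan(v0=10.0, stages=[(50.0, 0.8), (90.0, 0.5)], vT=100.0, corr=R)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = staged_survival(plan, published_surfaces)
            mus = [eval_mean_surface(published_surfaces.mean, a, b) for a, b in plan.segments()]
            sds = [eval_sd_surface(published_surfaces.sd, a, b) for a, b in plan.segments()]
        n = 100_000
        L = np.linalg.cholesky(R + 1e-12 * np.eye(3))
        z = rng.standard_normal((n, 3)) @ L.T
        draws = (np.array(mus) + z * np.array(sds)).sum(axis=1)
        se_mean = draws.std(ddof=1) / np.sqrt(n)
        assert s.mu == pytest.approx(draws.mean(), abs=3 * se_mean)
        se_sd = draws.std(ddof=1) / np.sqrt(2 * n)
        assert s.sigma == pytest.approx(draws.std(ddof=1), abs=3 * se_sd)

    def test_mean_invariant_to_correlation(self, published_surfaces):
        base = ResectionPlan(v0=10.0, stages=[(50.0, 0.5)], vT=100.0)
        rho = ResectionPlan(
            v0=10.0, stages=[(50.0, 0.5)], vT=100.0,
            corr=np.array([[1.0, 0.8], [0.8, 1.0]]),
        )
        a, b = staged_survival(base, published_surfaces), staged_survival(rho, published_surfaces)
        assert a.mu == pytest.approx(b.mu, abs=1e-12)
        assert b.sigma > a.sigma

    @given(rho1=st.floats(0.0, 0.9), rho2=st.floats(0.0, 0.9))
    def test_sd_nondecreasing_in_rho(self, published_surfaces, rho1, rho2):
        lo, hi = sorted([rho1, rho2])
        def sd(r):
            plan = ResectionPlan(
                v0=10.0, stages=[(50.0, 0.5)], vT=100.0,
                corr=np.array([[1.0, r], [r, 1.0]]),
            )
            return staged_survival(plan, published_surfaces).sigma
        assert sd(hi) >= sd(lo) - 1e-12

    def test_plan_validation(self):
        with pytest.raises(ValueError, match="cut fraction"):
            ResectionPlan(v0=1.0, stages=[(50.0, 1.0)], vT=100.0)
        with pytest.raises(ValueError, match="below the volume"):
            ResectionPlan(v0=60.0, stages=[(50.0, 0.5)], vT=100.0)
        with pytest.raises(ValueError, match="positive semidefinite"):
            ResectionPlan(
                v0=1.0, stages=[(50.0, 0.5)], vT=100.0,
                corr=np.array([[1.0, 2.0], [2.0, 1.0]]),
            )
        with pytest.raises(ValueError, match="symmetric"):
            ResectionPlan(
                v0=1.0, stages=[(50.0, 0.5)], vT=100.0,
                corr=np.array([[1.0, 0.2], [0.3, 1.0]]),
            )


class TestBuildFPTGrid:
    def test_default_grid_has_39_cells(self, mc_grid_500):
        assert len(mc_grid_500) == 39

    def test_first_cell_matches_published_table(self, mc_grid_500):
        # both the printed value and this estimate carry n=500 MC error
        # (SE ~0.23 d each), so this is a sanity band, not the tight check
        cell = next(t for t in mc_grid_500 if (t.v0, t.vc) == (10.0, 20.0))
        assert cell.mu == pytest.approx(33.69, abs=1.5)
        assert cell.sigma == pytest.approx(4.98, abs=0.7)

    def test_printed_means_stay_near_deterministic_crossing(self, params, table4):
        """Weak-noise regime: every printed grid mean is within 3 days of the
        analytic ODE crossing time."""
        for t in table4:
            exact = deterministic_crossing_time(t.v0, t.vc, params)
            assert abs(t.mu - exact) < 3.0

    def test_simulated_means_stay_near_deterministic_crossing(self, params, mc_grid_500):
        """Same weak-noise band for a fresh grid, with 3-SE Monte-Carlo slack
        on top since each cell mean is an n=500 estimate."""
        for t in mc_grid_500:
            exact = deterministic_crossing_time(t.v0, t.vc, params)
            slack = 3.0 * t.sigma / np.sqrt(500)
            assert abs(t.mu - exact) < 3.0 + slack

    def test_deterministic_limit_grid(self, zero_noise_params):
        triples = build_fpt_grid(
            zero_noise_params, v0_list=[10, 30], vc_list=[40, 60],
            n_paths=3, step=0.05, seed=1,
        )
        for t in triples:
            exact = deterministic_crossing_time(t.v0, t.vc, zero_noise_params)
            assert t.mu == pytest.approx(exact, abs=0.05 + 1e-9)
            assert t.sigma == pytest.approx(0.0, abs=1e-9)

    def test_full_pipeline_surface_recovery(self, params, published_surfaces, mc_grid_500):
        """Surfaces refitted from a fresh Monte-Carlo grid agree with the
        published untreated-survival mean at (1, 100) within 5%."""
        import warnings

        from gbmgrowth.model_fit import fit_mean_surface, fit_sd_surface
        from gbmgrowth.survival_calc import SurvivalSurfaces

        refit = SurvivalSurfaces(
            mean=fit_mean_surface(mc_grid_500), sd=fit_sd_surface(mc_grid_500)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = untreated_survival(1.0, 100.0, refit)
            ref = untreated_survival(1.0, 100.0, published_surfaces)
        assert ours.mu == pytest.approx(ref.mu, rel=0.05)
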