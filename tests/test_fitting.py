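"""Stepwise estimation: stage fits, run orchestration, aggregation."""

import numpy as np
import pytest

from triadmix.config import Config
from triadmix.data import JointDataset
from triadmix.fitting import (BivariateFit, OptimizerConfig, RunResult,
                              TriadMixtureModel, TrivariateFit, UnivariateFit,
                              aggregate_runs, fit_trivariate, fit_univariate)
from triadmix.synthetic import ScenarioSpec, simulate_scenario

FAST_OPT = OptimizerConfig(pi_starts=(1e-3,), maxfev_uni=120, maxfev_bi=80,
                           tri_refine_iters=4)


def null_dataset(rng, nvar=20_000, sigma0=1.0, n=5000.0):
    z = rng.normal(0, sigma0, (nvar, 3))
    return JointDataset(z=z, n_eff=np.full((nvar, 3), n),
                        w_indptr=np.arange(nvar + 1) * 2,
                        w_data=np.tile([0.35, 0.15], nvar))


class TestUnivariate:
    def test_null_data_pushes_signal_down_and_sigma0_to_one(self, rng):
        """Pure-null z-scores: the fitted causal signal is negligible.

        At the null the likelihood is flat in pi alone (pi and sigma^2 are
        only identified through their product), so the check is on the
        implied z-variance inflation pi * sigma^2 * N, not on pi itself.
        """
        data = null_dataset(rng)
        fit = fit_univariate(data, 0, opt_cfg=FAST_OPT)
        assert fit.pi_u * fit.sigma ** 2 * data.n_eff[0, 0] < 0.1
        assert fit.sigma0 == pytest.approx(1.0, abs=0.05)

    def test_residual_inflation_recovered(self, rng):
        data = null_dataset(rng, sigma0=1.1)
        fit = fit_univariate(data, 1, opt_cfg=FAST_OPT)
        assert 1.05 <= fit.sigma0 <= 1.15

    def test_polygenicity_recovered_within_factor_two(self):
        spec = ScenarioSpec.equilibrium(n_variants=60_000,
                                        n_traits_N=(15_000,) * 3)
        sim = simulate_scenario(spec, seed=5)
        model = TriadMixtureModel.from_simulation(sim, Config(n_random=10_000))
        data, _, _ = model._select(1)
        fit = fit_univariate(data, 0, total_het=float(sim.panel.het.sum()))
        assert abs(np.log10(fit.pi_u) - np.log10(0.002)) < 0.3


class TestBivariateNullOverlap:
    def test_independent_traits_recover_near_zero_sharing(self):
        """Two genetically disjoint traits: pi^b stays <= 10% of min pi^u."""
        import triadmix.fitting as F
        spec = ScenarioSpec(name="custom",
                            pi7_true=np.array([1e-3, 1e-3, 1e-3, 0, 0, 0, 0]),
                            pi_total=1e-3, n_variants=40_000,
                            n_traits_N=(20_000,) * 3)
        sim = simulate_scenario(spec, seed=77)
        model = TriadMixtureModel.from_simulation(
            sim, Config(n_random=8_000, n_random_bivariate=6_000))
        data, bi_data, _ = model._select(1)
        th = float(sim.panel.het.sum())
        uni = [F.fit_univariate(data, t, total_het=th) for t in (0, 1)]
        fit = F.fit_bivariate(bi_data, (0, 1), uni)
        assert fit.pi_b <= 0.1 * min(u.pi_u for u in uni)


class TestParameterAssembly:
    def test_jointly_infeasible_rho_triple_is_shrunk(self):
        """Pair-by-pair correlation estimates need not form a valid 3x3
        correlation matrix; assembly shrinks them to the PSD boundary."""
        from triadmix.fitting import _assemble_params
        uni = [UnivariateFit(trait=t, pi_u=2e-3, sigma=0.07, sigma0=1.0,
                             loglik=0.0) for t in range(3)]
        bi = [BivariateFit(pair=p, pi_b=1e-3, rho=r, rho0=0.0, loglik=0.0)
              for p, r in zip([(0, 1), (0, 2), (1, 2)], [0.9, 0.9, -0.9])]
        params = _assemble_params(uni, bi, 5e-4)
        assert np.linalg.eigvalsh(params.sigma_full()).min() >= 0
        assert abs(params.rho[0]) < 0.9


class TestTrivariateStage:
    def _stage_fits(self, pi_u, pi_b, sigma=0.07, sigma0=1.0):
        uni = [UnivariateFit(trait=t, pi_u=pi_u[t], sigma=sigma,
                             sigma0=sigma0, loglik=0.0) for t in range(3)]
        bi = [BivariateFit(pair=p, pi_b=pi_b[k], rho=0.0, rho0=0.0, loglik=0.0)
              for k, p in enumerate([(0, 1), (0, 2), (1, 2)])]
        return uni, bi

    def test_collapsed_bounds_return_the_point(self, rng):
        # pi_b's force pi123 to a single feasible value
        uni, bi = self._stage_fits([0.002, 0.002, 0.002],
                                   [0.002, 0.002, 0.002])
        data = null_dataset(rng, nvar=200)
        fit = fit_trivariate(data, uni, bi, opt_cfg=FAST_OPT)
        assert fit.pi123 == pytest.approx(0.002)
        assert fit.lo == pytest.approx(fit.hi)

    def test_estimate_stays_inside_bounds(self, rng):
        uni, bi = self._stage_fits([0.003, 0.003, 0.003],
                                   [0.001, 0.0015, 0.002])
        data = null_dataset(rng, nvar=500)
        fit = fit_trivariate(data, uni, bi, opt_cfg=FAST_OPT)
        assert fit.lo - 1e-15 <= fit.pi123 <= fit.hi + 1e-15

    def test_truth_dominates_distorted_triple_overlap(self):
        """The trivariate loglik prefers the generating pi_123 over a
        maximally distorted value (zero) in most replicates."""
        from triadmix.model import BandedData, TraitSubset, loglik
        from triadmix.fitting import _assemble_params
        wins = 0
        for seed in range(8):
            spec = ScenarioSpec.core(n_variants=30_000,
                                     n_traits_N=(8000,) * 3)
            sim = simulate_scenario(spec, seed=50 + seed)
            model = TriadMixtureModel.from_simulation(
                sim, Config(n_random=2500))
            data, _, _ = model._select(1)
            h_bar = sim.panel.het.mean()
            sig2 = spec.h2 / (0.002 * 30_000 * h_bar)
            uni, bi = TestTrivariateStage()._stage_fits(
                [0.002] * 3, [0.001] * 3, sigma=np.sqrt(sig2))
            sub = TraitSubset((0, 1, 2))
            banded = BandedData(data, sub, np.ones(3))
            ll_true = loglik(banded, _assemble_params(uni, bi, 0.001), sub)
            ll_none = loglik(banded, _assemble_params(uni, bi, 0.0), sub)
            wins += ll_true > ll_none
        assert wins >= 7


@pytest.fixture(scope="module")
def tiny_model():
    spec = ScenarioSpec.equilibrium(n_variants=12_000, pi_total=0.01,
                                    n_traits_N=(3000,) * 3)
    sim = simulate_scenario(spec, seed=9)
    return TriadMixtureModel.from_simulation(
        sim, Config(n_random=2000, n_random_trivariate=1200),
        opt_cfg=FAST_OPT)


class TestRunOrchestration:
    def test_same_seed_reproduces_identical_run(self, tiny_model):
        a = tiny_model.fit(seed=3).run.to_dict()
        b = tiny_model.fit(seed=3).run.to_dict()
        a.pop("wall_time")
        b.pop("wall_time")
        assert a == b

    def test_different_seeds_select_different_variants(self, tiny_model):
        a, _, _ = tiny_model._select(1)
        b, _, _ = tiny_model._select(2)
        assert not np.array_equal(a.panel_idx, b.panel_idx)

    def test_run_result_consistency(self, tiny_model):
        res = tiny_model.fit(seed=4)
        r = res.run
        pat = r.pattern
        np.testing.assert_allclose(pat.pi_univariate(),
                                   [u.pi_u for u in r.uni], atol=1e-12)
        np.testing.assert_allclose(pat.pi_bivariate(),
                                   [b.pi_b for b in r.bi], atol=1e-12)
        assert r.tri.lo - 1e-15 <= r.tri.pi123 <= r.tri.hi + 1e-15
        assert "pi^u" in res.summary() or "pi" in res.summary()

    def test_pruning_skip_logged(self, tiny_model, caplog):
        cfg = Config(n_random=2000, do_pruning=False)
        model = TriadMixtureModel(tiny_model.dataset, panel=tiny_model.panel,
                                  config=cfg, opt_cfg=FAST_OPT)
        data, _, _ = model._select(1)
        assert data.nvar == 2000

    def test_run_pipeline_matches_model_fit(self, tiny_model):
        from triadmix.fitting import run_pipeline
        cfg = Config(n_random=2000, n_random_trivariate=1200,
                     rand_prune_seed=3)
        run = run_pipeline(cfg, dataset=tiny_model.dataset,
                           panel=tiny_model.panel, opt_cfg=FAST_OPT)
        direct = TriadMixtureModel(tiny_model.dataset, panel=tiny_model.panel,
                                   config=cfg, opt_cfg=FAST_OPT).fit(seed=3).run
        assert run.pi123 == direct.pi123
        assert [u.pi_u for u in run.uni] == [u.pi_u for u in direct.uni]


def make_run(seed, pi7, pi_u=None, pi_b=None):
    pat = np.asarray(pi7, dtype=float)
    pi123 = pat[6]
    pi_b = [pat[3] + pi123, pat[4] + pi123, pat[5] + pi123]
    pi_u = [pat[0] + pi_b[0] + pi_b[1] - pi123,
            pat[1] + pi_b[0] + pi_b[2] - pi123,
            pat[2] + pi_b[1] + pi_b[2] - pi123]
    uni = [UnivariateFit(trait=t, pi_u=pi_u[t], sigma=0.1, sigma0=1.0,
                         loglik=0.0) for t in range(3)]
    bi = [BivariateFit(pair=p, pi_b=pi_b[k], rho=0, rho0=0, loglik=0.0)
          for k, p in enumerate([(0, 1), (0, 2), (1, 2)])]
    tri = TrivariateFit(pi123=pi123, loglik=0.0, lo=0.0, hi=min(pi_b))
    return RunResult(seed=seed, uni=uni, bi=bi, tri=tri, selected_variants=0)


class TestAggregation:
    def test_median_of_three(self):
        base = np.array([.001] * 7)
        runs = [make_run(1, base), make_run(2, base * 2), make_run(3, base * 3)]
        agg = aggregate_runs(runs)
        np.testing.assert_allclose(agg.median_pi7, base * 2)

    def test_identical_runs_zero_deviation(self):
        base = np.array([.001] * 7)
        runs = [make_run(s, base) for s in (1, 2)]
        agg = aggregate_runs(runs)
        assert agg.representative in (0, 1)

    def test_run_at_median_selected(self):
        base = np.array([.001] * 7)
        off = base.copy()
        off[6] *= 3
        runs = [make_run(1, base), make_run(2, base), make_run(3, off)]
        agg = aggregate_runs(runs)
        assert agg.representative in (0, 1)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            aggregate_runs([make_run(1, np.full(7, 1e-3))])
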