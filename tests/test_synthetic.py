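"""Generative simulator: panels, assignments, effects, z-scores."""

import io

import numpy as np
import pandas as pd
import pytest

from triadmix.ld import load_ld_text
from triadmix.synthetic import (ScenarioSpec, assign_components,
                                component_sizes, make_ld_panel, sample_effects,
                                sample_z, sample_z_matrix, scale_to_h2,
                                simulate_scenario, toy_genotype_r2)


class TestScenarioSpec:
    def test_presets_satisfy_their_constraints(self):
        core = ScenarioSpec.core()
        assert np.all(core.pi7_true[3:6] == 0)
        assert len(set(core.pi7_true[[0, 1, 2, 6]])) == 1
        ring = ScenarioSpec.ring()
        assert np.all(ring.pi7_true[[0, 1, 2, 6]] == 0)
        assert len(set(ring.pi7_true[3:6])) == 1
        eq = ScenarioSpec.equilibrium()
        assert len(set(eq.pi7_true)) == 1

    def test_per_trait_polygenicity_equals_pi_total(self):
        for name in ("core", "ring", "equilibrium"):
            spec = ScenarioSpec.preset(name)
            np.testing.assert_allclose(spec.truth.pi_univariate(),
                                       spec.pi_total)

    def test_default_n_scales_with_panel(self):
        spec = ScenarioSpec.core(n_variants=12_926_691)
        assert spec.n_traits_N[0] == pytest.approx(100_000)

    def test_invalid_pi7_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(name="custom", pi7_true=np.full(7, 0.2))


class TestPanel:
    def test_singleton_blocks(self):
        panel = make_ld_panel(50, block_size_dist=1, seed=0)
        for j in range(50):
            idx, _ = panel.neighbors(j)
            assert list(idx) == [j]

    def test_seeded_reproducibility(self):
        a = make_ld_panel(200, seed=42)
        b = make_ld_panel(200, seed=42)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        np.testing.assert_array_equal(a.nbr_r2, b.nbr_r2)

    def test_decay_profile(self):
        """Mean r2 at adjacent positions matches the decay parameter."""
        panel = make_ld_panel(30_000, block_size_dist=(4, 4), r2_decay=0.8,
                              seed=1, r2_floor=0.0)
        lag1 = []
        for j in range(0, 20_000, 7):
            idx, r2 = panel.neighbors(j)
            for k, r in zip(idx, r2):
                if k == j + 1:
                    lag1.append(r)
        mean = np.mean(lag1)
        assert mean == pytest.approx(0.8 ** 2, rel=0.05)

    def test_signed_r_consistent_with_r2(self):
        panel = make_ld_panel(500, seed=3)
        np.testing.assert_allclose(panel.nbr_r ** 2, panel.nbr_r2, atol=1e-12)


class TestAssignment:
    def test_core_component_sizes(self):
        sizes = component_sizes(ScenarioSpec.core().pi7_true, 10_000)
        np.testing.assert_array_equal(sizes, [10, 10, 10, 0, 0, 0, 10])

    def test_equilibrium_component_sizes(self):
        sizes = component_sizes(ScenarioSpec.equilibrium().pi7_true, 10_000)
        np.testing.assert_array_equal(sizes, [5, 5, 5, 5, 5, 5, 5])

    def test_biobank_scale_per_trait_count(self):
        """pi = 0.002 on a 12,926,691-variant panel -> 25,853 causal/trait."""
        sizes = component_sizes(ScenarioSpec.core().pi7_true, 12_926_691)
        member = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                           [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
        per_trait = sizes @ member
        np.testing.assert_array_equal(per_trait, [25_853, 25_853, 25_853])

    def test_labels_match_sizes(self):
        panel = make_ld_panel(5_000, seed=2)
        spec = ScenarioSpec.equilibrium(n_variants=5_000, pi_total=0.02)
        labels = assign_components(spec, panel, seed=5)
        sizes = component_sizes(spec.pi7_true, 5_000)
        for c in range(1, 8):
            assert (labels == c).sum() == sizes[c - 1]


class TestEffects:
    def _assignment(self, n, comp, count, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=np.int8)
        labels[rng.choice(n, count, replace=False)] = comp
        return labels

    def test_inactive_traits_exactly_zero(self):
        labels = self._assignment(1000, 3, 100)     # component {3}
        eff = sample_effects(labels, seed=1)
        rows = labels == 3
        assert np.all(eff.beta[rows, 0] == 0)
        assert np.all(eff.beta[rows, 1] == 0)
        assert np.any(eff.beta[rows, 2] != 0)

    def test_shared_component_correlation(self):
        labels = self._assignment(20_000, 4, 10_000)  # component {1,2}
        eff = sample_effects(labels, rho=(0.9, 0.0, 0.0), seed=2)
        rows = labels == 4
        r = np.corrcoef(eff.beta[rows, 0], eff.beta[rows, 1])[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_uncorrelated_when_rho_zero(self):
        labels = self._assignment(20_000, 4, 10_000)
        eff = sample_effects(labels, rho=(0.0, 0.0, 0.0), seed=3)
        rows = labels == 4
        r = np.corrcoef(eff.beta[rows, 0], eff.beta[rows, 1])[0, 1]
        assert abs(r) < 0.05


class TestHeritabilityScaling:
    def test_exact_postcondition(self):
        labels = np.zeros(500, dtype=np.int8)
        labels[:50] = 7
        eff = sample_effects(labels, seed=4)
        het = np.random.default_rng(0).uniform(0.1, 0.5, 500)
        scaled = scale_to_h2(eff, het, 0.4)
        for i in range(3):
            assert het @ (scaled.beta[:, i] ** 2) == pytest.approx(0.4)

    def test_doubling_target_scales_sqrt2(self):
        labels = np.zeros(100, dtype=np.int8)
        labels[:10] = 7
        eff = sample_effects(labels, seed=5)
        het = np.full(100, 0.4)
        a = scale_to_h2(eff, het, 0.2).beta
        b = scale_to_h2(eff, het, 0.4).beta
        np.testing.assert_allclose(b, a * np.sqrt(2), rtol=1e-12)

    def test_single_causal_algebra(self):
        labels = np.zeros(1, dtype=np.int8)
        labels[0] = 7
        eff = sample_effects(labels, seed=6)
        scaled = scale_to_h2(eff, np.array([0.5]), 0.4)
        np.testing.assert_allclose(scaled.beta[0] ** 2, 0.8)

    def test_trait_without_causals_rejected(self):
        labels = np.zeros(100, dtype=np.int8)
        labels[:5] = 1  # only trait 1
        eff = sample_effects(labels, seed=7)
        with pytest.raises(ValueError):
            scale_to_h2(eff, np.full(100, 0.3), 0.4)


class TestSampleZ:
    def test_null_calibration(self):
        """No causal variants: empirical var(z) = sigma0^2 = 1."""
        spec = ScenarioSpec(name="custom", pi7_true=np.zeros(7),
                            n_variants=50_000)
        panel = make_ld_panel(50_000, seed=8)
        labels = np.zeros(50_000, dtype=np.int8)
        eff = sample_effects(labels, seed=9)
        z = sample_z_matrix(eff, panel, spec, seed=10)
        np.testing.assert_allclose(z.var(axis=0), 1.0, atol=0.02)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=0.02)

    def test_bit_reproducible(self):
        sim1 = simulate_scenario(ScenarioSpec.core(n_variants=2_000), seed=3)
        sim2 = simulate_scenario(ScenarioSpec.core(n_variants=2_000), seed=3)
        np.testing.assert_array_equal(sim1.z, sim2.z)

    def test_inflation_grows_with_n(self):
        """Genome-wide z variance rises with GWAS sample size."""
        panel = make_ld_panel(20_000, seed=11)
        spec_small = ScenarioSpec.core(n_variants=20_000, n_traits_N=(500,) * 3)
        spec_big = ScenarioSpec.core(n_variants=20_000, n_traits_N=(5000,) * 3)
        labels = assign_components(spec_small, panel, seed=12)
        eff = scale_to_h2(sample_effects(labels, seed=13), panel.het, 0.4)
        z_small = sample_z_matrix(eff, panel, spec_small, seed=14)
        z_big = sample_z_matrix(eff, panel, spec_big, seed=14)
        assert z_big.var() > z_small.var() > 1.0

    def test_residual_covariance_recovered(self):
        spec = ScenarioSpec(name="custom", pi7_true=np.zeros(7),
                            n_variants=80_000, sigma0=(1.0, 1.2, 1.0),
                            rho0=(0.5, 0.0, 0.0))
        panel = make_ld_panel(80_000, seed=15)
        eff = sample_effects(np.zeros(80_000, dtype=np.int8), seed=16)
        z = sample_z_matrix(eff, panel, spec, seed=17)
        cov = np.cov(z.T)
        assert cov[0, 0] == pytest.approx(1.0, abs=0.02)
        assert cov[1, 1] == pytest.approx(1.44, abs=0.03)
        assert cov[0, 1] == pytest.approx(0.6, abs=0.02)

    def test_sumstats_tables_round_trip(self):
        sim = simulate_scenario(ScenarioSpec.core(n_variants=1_000), seed=18)
        tables = sample_z(sim.effects, sim.panel, sim.spec, seed=21)
        assert len(tables) == 3
        assert list(tables[0].columns) == ["SNP", "CHR", "BP", "A1", "A2",
                                           "Z", "N", "FRQ"]


class TestToyGenotypeR2:
    def test_identical_columns_r2_one(self):
        g = np.random.default_rng(0).integers(0, 3, (40, 1)).astype(float)
        mat = np.hstack([g, g])
        out = toy_genotype_r2(mat)
        assert out["R2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_columns_r2_zero(self):
        g = np.array([[0, 0], [0, 2], [2, 0], [2, 2.0]] * 5)
        out = toy_genotype_r2(g)
        assert out["R2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_correlation(self, rng):
        g = rng.normal(size=(50, 20))
        out = toy_genotype_r2(g, window=30)
        corr = np.corrcoef(g.T) ** 2
        for _, row in out.iterrows():
            j = int(row["SNP_A"][2:]) - 1
            k = int(row["SNP_B"][2:]) - 1
            assert row["R2"] == pytest.approx(corr[j, k], abs=1e-10)

    def test_round_trip_through_panel_loader(self, tmp_path, rng):
        g = rng.normal(size=(30, 8))
        out = toy_genotype_r2(g, r2_min=0.0)
        path = tmp_path / "toy.ld"
        out.to_csv(path, sep="\t", index=False)
        meta = pd.DataFrame({"id": [f"rs{i + 1}" for i in range(8)],
                             "chrom": 1, "pos": (np.arange(8) + 1) * 1000,
                             "a1": "A", "a2": "G",
                             "freq": np.full(8, 0.3)})
        panel = load_ld_text([path], meta)
        idx, r2 = panel.neighbors(0)
        assert len(idx) == 8  # all pairs reported at r2_min=0
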