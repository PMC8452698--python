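import numpy as np
import pytest
from scipy import integrate, stats

import gwasrep as g

Z_GW = stats.norm.isf(5e-8 / 2)  # two-sided genome-wide z threshold, ~5.45


class TestSimulatePair:
    def test_identical_config_gives_byte_identical_tables(self, tmp_path):
        cfg = g.SimConfig(n_snvs=2000, p_allele_swap=0.4, p_missing_rsid=0.1, seed=5)
        for i in (1, 2):
            pair, truth = g.simulate_pair(cfg)
            g.write_simulation(pair, truth, str(tmp_path / f"run{i}"))
        for name in ("discovery.tsv", "replication.tsv", "ground_truth.tsv", "manifest.yaml"):
            assert (tmp_path / "run1" / name).read_bytes() == (tmp_path / "run2" / name).read_bytes()

    def test_all_null_model_has_no_effects_and_rare_significance(self):
        cfg = g.SimConfig(n_snvs=50_000, frac_null=1.0, seed=11)
        pair, truth = g.simulate_pair(cfg)
        assert (truth["beta_true"] == 0.0).all()
        # expected significant count is 5e-8 * n ~ 0.0025; allow a tiny slack
        assert (pair.discovery["p_value"] < 5e-8).sum() <= 2

    @pytest.mark.parametrize("trait_type", ["quantitative", "binary"])
    def test_z_scores_are_calibrated(self, trait_type):
        cfg = g.SimConfig(
            n_snvs=10_000, frac_null=0.0, tau=0.2, n_discovery=50_000,
            n_replication=50_000, trait_type=trait_type, seed=2,
        )
        pair, truth = g.simulate_pair(cfg)
        for table, se_col in ((pair.discovery, "se_discovery"), (pair.replication, "se_replication")):
            z = (table["effect"].to_numpy() - truth["beta_true"].to_numpy()) / truth[se_col].to_numpy()
            assert abs(z.mean()) < 3.0 / np.sqrt(len(z))
            assert abs(z.std() - 1.0) < 0.03

    def test_swap_mask_negation_restores_unswapped_run(self):
        base = dict(n_snvs=5000, seed=9)
        plain, _ = g.simulate_pair(g.SimConfig(**base, p_allele_swap=0.0))
        swapped_pair, truth = g.simulate_pair(g.SimConfig(**base, p_allele_swap=0.5))
        mask = truth["swapped"].to_numpy()
        frac = mask.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(mask))
        restored = swapped_pair.replication.copy()
        restored.loc[mask, "effect"] = -restored.loc[mask, "effect"]
        restored.loc[mask, "eaf"] = 1.0 - restored.loc[mask, "eaf"]
        restored.loc[mask, ["effect_allele", "other_allele"]] = restored.loc[
            mask, ["other_allele", "effect_allele"]
        ].to_numpy()
        # effect negation and allele exchange invert bit-for-bit; the allele
        # frequency complement 1 - (1 - f) re-rounds in the last ulp
        assert restored.drop(columns="eaf").equals(plain.replication.drop(columns="eaf"))
        np.testing.assert_allclose(restored["eaf"], plain.replication["eaf"], rtol=0, atol=1e-15)

    def test_toggling_missing_rsid_stage_leaves_other_draws_alone(self):
        base = dict(n_snvs=3000, seed=4)
        full, _ = g.simulate_pair(g.SimConfig(**base))
        thinned, truth = g.simulate_pair(g.SimConfig(**base, p_missing_rsid=0.2))
        kept = ~truth["missing_in_replication"].to_numpy()
        assert thinned.replication.reset_index(drop=True).equals(
            full.replication[kept].reset_index(drop=True)
        )
        assert thinned.discovery.equals(full.discovery)

    def test_degenerate_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            g.SimConfig(maf_range=(0.0, 0.2))
        # zero-width range is allowed
        g.SimConfig(maf_range=(0.3, 0.3))

    def test_info_scores_present_only_in_replication(self):
        pair, _ = g.simulate_pair(g.SimConfig(n_snvs=500, seed=1))
        assert pair.discovery["info"].isna().all()
        assert pair.replication["info"].between(0, 1).all()


class TestExpectedShrinkage:
    def test_certain_selection_recovers_true_effect(self):
        se = 0.01
        # selection probability is 1 - sf(4.55) ~ 1 - 2.7e-6, so the
        # conditional mean sits within ~1e-4 of the true effect
        assert g.expected_shrinkage(10 * se, se, Z_GW) == pytest.approx(10 * se, rel=1e-4)

    def test_null_effect_absolute_mean_matches_numerical_integration(self):
        se = 0.013
        closed = g.expected_shrinkage(0.0, se, Z_GW, absolute=True)
        num, _ = integrate.quad(
            lambda z: abs(z) * stats.norm.pdf(z), Z_GW, 40, limit=200
        )
        expected = 2 * num / (2 * stats.norm.sf(Z_GW)) * se
        assert closed == pytest.approx(expected, rel=1e-9)
        # signed conditional mean is zero by symmetry
        assert g.expected_shrinkage(0.0, se, Z_GW) == pytest.approx(0.0, abs=1e-15)

    def test_monte_carlo_agrees_within_three_ses(self):
        mu, se = 0.02, 0.011
        rng = np.random.default_rng(8)
        x = rng.normal(mu, se, 1_000_000)
        sel = np.abs(x / se) > Z_GW
        mc = x[sel].mean()
        mc_se = x[sel].std(ddof=1) / np.sqrt(sel.sum())
        assert abs(mc - g.expected_shrinkage(mu, se, Z_GW)) < 3 * mc_se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            g.expected_shrinkage(0.1, 0.0, 5.0)
        with pytest.raises(ValueError):
            g.expected_shrinkage(0.1, 0.01, -1.0)


def test_winners_curse_emerges_across_seeds():
    """Selected discovery ORs exceed replication ORs of the same SNVs when the
    replication cohort is much larger (selection bias, not noise)."""
    diffs = []
    for seed in range(20):
        cfg = g.SimConfig(
            n_snvs=5000, frac_null=0.9, tau=0.05, n_discovery=20_000,
            n_replication=100_000, seed=seed,
        )
        pair, _ = g.simulate_pair(cfg)
        harm = g.harmonize_pair(pair).table
        sel = harm[harm["p_discovery"] < 5e-8]
        diffs.append(sel["or_discovery_norm"].mean() - sel["or_replication_norm"].mean())
    diffs = np.asarray(diffs)
    assert (diffs > 0).sum() >= 19
    assert diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs))) > 3


def test_replication_rate_monotone_in_replication_sample_size():
    grid = (30_000, 60_000, 120_000)
    mean_rates = []
    for n_rep in grid:
        rates = []
        for seed in range(5):
            cfg = g.SimConfig(
                n_snvs=5000, frac_null=0.9, tau=0.05, n_discovery=20_000,
                n_replication=n_rep, seed=100 + seed,
            )
            pair, _ = g.simulate_pair(cfg)
            calls = g.call_replication(g.harmonize_pair(pair).table)
            rates.append(g.rate(calls, "sim").rate)
        mean_rates.append(np.mean(rates))
    assert mean_rates[0] <= mean_rates[1] <= mean_rates[2]
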