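"""Generators: known-truth genotypes, phenotypes, ethogram sessions."""

import numpy as np
import pytest

from sowreact import ethogram as eth
from sowreact import grm as grm_mod
from sowreact import mixed_models as mm
from sowreact import synthetic_data as sim

from conftest import quick_fit


class TestGenotypes:
    def test_realized_maf_matches_drawing_distribution(self):
        cfg = sim.SimulationConfig(n_individuals=400, n_markers=5000,
                                   maf_range=(0.05, 0.5), seed=1)
        g = sim.simulate_genotypes(cfg)
        p = g.allele_freqs()
        maf = np.minimum(p, 1 - p)
        assert maf.mean() == pytest.approx(0.275, abs=0.02)

    def test_seed_determinism(self):
        cfg = sim.SimulationConfig(n_individuals=50, n_markers=200, seed=9)
        a = sim.simulate_genotypes(cfg)
        b = sim.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.marker_map.equals(b.marker_map)

    def test_no_missingness_by_default(self):
        g = sim.simulate_genotypes(sim.SimulationConfig(
            n_individuals=50, n_markers=100, seed=2))
        assert not np.isnan(g.dosages).any()

    def test_positions_distinct_within_chromosome(self):
        g = sim.simulate_genotypes(sim.SimulationConfig(
            n_individuals=10, n_markers=3000, n_chromosomes=3, seed=3))
        for _, grp in g.marker_map.groupby("chrom"):
            assert grp["pos_bp"].is_unique

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_markers=5, n_chromosomes=10)


class TestPhenotypes:
    def test_realized_h2_near_target(self):
        cfg = sim.SimulationConfig(n_individuals=2000, n_markers=1500,
                                   h2={"t": 0.30}, group_effect_sd=0.0,
                                   seed=4)
        g = sim.simulate_genotypes(cfg)
        pheno, truth = sim.simulate_phenotypes(g, cfg)
        y = pheno["value"].to_numpy()
        a = truth["additive_values"]["t"].to_numpy()
        slope = np.cov(y, a)[0, 1] / np.var(a)
        realized = slope ** 2 * np.var(a) / np.var(y)
        assert realized == pytest.approx(0.30, abs=0.05)

    def test_near_unit_rg_in_true_breeding_values(self):
        cfg = sim.SimulationConfig(
            n_individuals=500, n_markers=1000,
            h2={"t1": 0.15, "t2": 0.15},
            rg=np.array([[1.0, 0.99], [0.99, 1.0]]), seed=5)
        g = sim.simulate_genotypes(cfg)
        _, truth = sim.simulate_phenotypes(g, cfg)
        av = truth["additive_values"]
        r = np.corrcoef(av["t1"], av["t2"])[0, 1]
        assert r >= 0.97

    def test_negative_rg_respected(self):
        cfg = sim.SimulationConfig(
            n_individuals=500, n_markers=1000,
            h2={"t1": 0.2, "t2": 0.2},
            rg=np.array([[1.0, -0.6], [-0.6, 1.0]]), seed=6)
        g = sim.simulate_genotypes(cfg)
        _, truth = sim.simulate_phenotypes(g, cfg)
        av = truth["additive_values"]
        assert np.corrcoef(av["t1"], av["t2"])[0, 1] == pytest.approx(
            -0.6, abs=0.1)

    def test_no_qtl_equals_infinitesimal_model(self):
        cfg0 = sim.SimulationConfig(n_individuals=100, n_markers=300, seed=7)
        cfg1 = sim.SimulationConfig(n_individuals=100, n_markers=300, seed=7,
                                    planted_qtl={"trait1": []})
        g = sim.simulate_genotypes(cfg0)
        p0, _ = sim.simulate_phenotypes(g, cfg0)
        p1, _ = sim.simulate_phenotypes(g, cfg1)
        np.testing.assert_array_equal(p0["value"], p1["value"])

    def test_repeated_records_share_pe(self):
        cfg = sim.SimulationConfig(
            n_individuals=200, n_markers=400, h2={"t": 0.1},
            pe_fraction={"t": 0.3}, records_per_individual={"t": 3},
            group_effect_sd=0.0, seed=8)
        g = sim.simulate_genotypes(cfg)
        pheno, truth = sim.simulate_phenotypes(g, cfg)
        assert len(pheno) == 600
        wide = pheno.pivot(index="sow_id", columns="rec", values="value")
        # between-individual correlation of repeated records reflects
        # a + pe (= 0.4 of total variance here)
        c = wide.corr().to_numpy()
        assert np.mean(c[np.triu_indices(3, 1)]) == pytest.approx(0.4,
                                                                  abs=0.12)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(h2={"t": 0.8}, pe_fraction={"t": 0.3})


class TestEthogramSessions:
    def latent(self, n, seed=10, h2=0.15):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, np.sqrt(h2), n)
        return a + rng.normal(0, np.sqrt(1 - h2), n), a

    def test_mean_vs_increases_across_reactivity_deciles(self):
        cfg = sim.SimulationConfig(seed=11)
        x, _ = self.latent(3000)
        sessions = sim.simulate_ethogram_sessions(x, cfg)
        scores, _ = eth.score_sessions(eth.sessions_from_frame(sessions),
                                       outlier_sd=None)
        ids = scores["sow_id"].str.slice(3).astype(int).to_numpy() - 1
        dec = np.digitize(x[ids], np.quantile(x, np.linspace(0.1, 0.9, 9)))
        means = [scores["vs"][dec == k].mean() for k in range(10)]
        assert np.all(np.diff(means) > 0)

    def test_constant_latent_leaves_no_systematic_signal(self):
        cfg = sim.SimulationConfig(seed=12)
        sessions = sim.simulate_ethogram_sessions(np.zeros(2000), cfg)
        scores, _ = eth.score_sessions(eth.sessions_from_frame(sessions),
                                       outlier_sd=None)
        # with a flat latent input the scores are exchangeable noise:
        # no correlation with any ordering of the sows
        idx = scores["sow_id"].str.slice(3).astype(int).to_numpy()
        r = np.corrcoef(scores["vs"], idx)[0, 1]
        assert abs(r) < 0.06

    def test_intervention_mix_matches_design(self):
        cfg = sim.SimulationConfig(seed=13)
        x, _ = self.latent(4000)
        sessions = sim.simulate_ethogram_sessions(x, cfg)
        frac = sessions["intervention_moment"].value_counts(normalize=True)
        assert frac["none"] == pytest.approx(0.442, abs=0.03)
        assert frac["before_first_site"] == pytest.approx(0.099, abs=0.02)
        # interventions imply a 4th vocalization stage
        has4 = sessions["voc_stage_4"].ne("").to_numpy()
        assert (has4 == (sessions["intervention_moment"] != "none")
                .to_numpy()).all()

    def test_scored_sessions_carry_additive_signal(self):
        x, a = self.latent(2000, seed=14)
        cfg = sim.SimulationConfig(seed=14)
        sessions = sim.simulate_ethogram_sessions(x, cfg)
        scores, _ = eth.score_sessions(eth.sessions_from_frame(sessions),
                                       outlier_sd=None)
        ids = scores["sow_id"].str.slice(3).astype(int).to_numpy() - 1
        assert np.corrcoef(scores["rs"], a[ids])[0, 1] > 0.15


class TestFullPipelineIntegration:
    def test_session_derived_trait_recovers_h2_and_rg(self):
        """simulate -> score -> QC -> GRM -> Gibbs recovers the latent
        heritability and the near-unit RS-VS genetic correlation."""
        from sowreact import genotype_qc as qc

        cfg = sim.SimulationConfig(n_individuals=500, n_markers=2000,
                                   h2={"react": 0.15}, seed=20)
        g = sim.simulate_genotypes(cfg)
        _, truth = sim.simulate_phenotypes(g, cfg)
        a = truth["additive_values"]["react"].to_numpy()
        rng = np.random.default_rng(21)
        latent = a + rng.normal(0, np.sqrt(1 - 0.15), len(a))
        sessions = sim.simulate_ethogram_sessions(latent, cfg)
        scores, _ = eth.score_sessions(eth.sessions_from_frame(sessions))

        g_qc, _ = qc.run_qc(g, phenotype_ids=scores["sow_id"])
        G = grm_mod.stabilize(grm_mod.vanraden_g(g_qc), 0.01)

        spec = mm.ModelSpec(response="rs",
                            fixed_effects=["intervention_moment"],
                            covariates=["touches"])
        X, rec, _ = mm.build_design(scores, spec, G.individual_ids)
        cfgg = mm.GibbsConfig(iterations=3000, burn_in=1000, thin=2, seed=3)
        fit = mm.gibbs_single_trait(scores["rs"].to_numpy(), X, rec, G, cfgg)
        # the observation layer attenuates the latent h2 = 0.15 somewhat
        assert fit.samples["h2"].mean() == pytest.approx(0.15, abs=0.08)

        X2, rec2, _ = mm.build_design(scores, spec, G.individual_ids)
        fit2 = mm.gibbs_two_trait(
            scores["rs"].to_numpy(), scores["vs"].to_numpy(),
            X, X2, rec, rec2, G, cfgg)
        assert fit2.samples["rg"].mean() == pytest.approx(1.0, abs=0.10)
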