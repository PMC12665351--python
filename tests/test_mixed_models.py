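"""Design building, stepwise selection and the Gibbs samplers."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from sowreact import grm as grm_mod
from sowreact import mixed_models as mm
from sowreact import synthetic_data as sim
from sowreact.errors import DesignError, GrmError

from conftest import make_study, quick_fit


class TestHeritabilityFormulas:
    def test_single_record_form(self):
        assert mm.heritability(0.75, 3.62) == pytest.approx(0.17, abs=0.005)

    def test_repeated_record_form_differs_from_single(self):
        # collapsing repeated records and ignoring pe is NOT the same h2
        h_rep = mm.heritability(0.06, 0.32, sigma_pe2=0.13)
        h_single = mm.heritability(0.06, 0.32)
        assert h_rep == pytest.approx(0.12, abs=0.005)
        assert h_single > h_rep

    def test_vectorized_over_draws(self):
        h = mm.heritability(np.array([1.0, 2.0]), np.array([3.0, 2.0]))
        np.testing.assert_allclose(h, [0.25, 0.5])


class TestModelConfig:
    def test_default_trait_models_cover_all_traits(self):
        assert set(mm.DEFAULT_TRAIT_MODELS) == {
            "RS", "VS", "ST", "LB", "TB", "SB", "PW", "PD",
            "VT", "RR", "PS"}
        # only the repeated-record physiological traits carry pe
        assert all(mm.DEFAULT_TRAIT_MODELS[t].use_pe is (t in
                   {"VT", "RR", "PS"}) for t in mm.DEFAULT_TRAIT_MODELS)
        assert "IM" in mm.DEFAULT_TRAIT_MODELS["RS"].fixed_effects
        assert "TT" in mm.DEFAULT_TRAIT_MODELS["VS"].covariates

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "models.yaml"
        cfg.write_text(
            "rs:\n  fixed_effects: [cg, im]\n  covariates: [touches]\n"
            "vt:\n  fixed_effects: [parity]\n  repeated: true\n")
        specs = mm.load_model_config(cfg)
        assert specs["rs"].fixed_effects == ["cg", "im"]
        assert not specs["rs"].use_pe
        assert specs["vt"].use_pe


class TestBuildDesign:
    def grm3(self):
        M = np.eye(3) * 1.0
        return grm_mod.GRM(M, ["a", "b", "c"], np.array([0.5]), 0.5)

    def test_repeatability_dimensions(self):
        recs = pd.DataFrame({"sow_id": ["a", "a", "b"],
                             "value": [1.0, 2.0, 3.0]})
        spec = mm.ModelSpec(response="value",
                            random_terms=("additive", "permanent_environment"))
        X, rec2ind, names = mm.build_design(recs, spec, ["a", "b", "c"])
        assert X.shape == (3, 1) and names == ["intercept"]
        assert rec2ind.tolist() == [0, 0, 1]

    def test_single_level_factor_dropped_with_warning(self):
        recs = pd.DataFrame({"sow_id": ["a", "b"], "value": [1.0, 2.0],
                             "batch": ["x", "x"]})
        spec = mm.ModelSpec(response="value", fixed_effects=["batch"])
        with pytest.warns(UserWarning, match="single level"):
            X, _, names = mm.build_design(recs, spec, ["a", "b"])
        assert names == ["intercept"]

    def test_confounded_factors_named_in_error(self):
        recs = pd.DataFrame({
            "sow_id": list("abcd"), "value": [1.0, 2, 3, 4],
            "f1": ["x", "x", "y", "y"], "f2": ["u", "u", "v", "v"]})
        spec = mm.ModelSpec(response="value", fixed_effects=["f1", "f2"])
        with pytest.raises(DesignError, match="f[12]"):
            mm.build_design(recs, spec, list("abcd"))

    def test_unknown_individual_is_hard_error(self):
        recs = pd.DataFrame({"sow_id": ["zz"], "value": [1.0]})
        with pytest.raises(DesignError, match="zz"):
            mm.build_design(recs, mm.ModelSpec(response="value"),
                            ["a", "b"])


class TestStepwiseSelect:
    def frame(self, seed, beta_a=1.0, beta_b=0.0, n=300):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        x = rng.normal(size=n)
        y = beta_a * a + beta_b * b + rng.normal(size=n)
        return pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str),
                             "x": x, "sow_id": [f"s{i}" for i in range(n)]})

    def test_selects_true_effect_only(self):
        spec = mm.stepwise_select(self.frame(0), "y", ["A", "B"],
                                  categorical={"A", "B"})
        assert spec.fixed_effects == ["A"] and spec.covariates == []

    def test_pure_noise_gives_intercept_only(self):
        spec = mm.stepwise_select(self.frame(1, beta_a=0.0), "y",
                                  ["A", "B", "x"], categorical={"A", "B"})
        assert spec.fixed_effects == [] and spec.covariates == []

    def test_agrees_with_exhaustive_search(self):
        import statsmodels.formula.api as smf
        df = self.frame(2, beta_a=0.6, beta_b=0.25)
        cands, cats = ["A", "B", "x"], {"A", "B"}
        spec = mm.stepwise_select(df, "y", cands, categorical=cats)

        def aic_of(sub):
            rhs = " + ".join(sorted(
                f"C({t})" if t in cats else t for t in sub)) or "1"
            return smf.ols(f"y ~ {rhs}", data=df).fit().aic
        best = min((frozenset(s) for r in range(4)
                    for s in itertools.combinations(cands, r)), key=aic_of)
        assert set(spec.fixed_effects) | set(spec.covariates) <= best

    def test_no_candidates_warns(self):
        with pytest.warns(UserWarning):
            spec = mm.stepwise_select(self.frame(3), "y", [])
        assert spec.fixed_effects == []


class TestGibbsSingleTrait:
    def test_determinism_under_fixed_seed(self):
        _, recs, _, G = make_study(n=120, m=300, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = quick_fit(recs, G, iterations=700, burn_in=200, thin=5,
                           seed=7)
            f2 = quick_fit(recs, G, iterations=700, burn_in=200, thin=5,
                           seed=7)
        pd.testing.assert_frame_equal(f1.samples, f2.samples)
        np.testing.assert_array_equal(f1.a_draws, f2.a_draws)

    def test_retained_draw_arithmetic(self):
        cfg = mm.GibbsConfig(iterations=1101, burn_in=100, thin=10, seed=0)
        assert cfg.n_retained == (1101 - 100) // 10
        _, recs, _, G = make_study(n=80, m=200, seed=12)
        spec = mm.ModelSpec(response="t", fixed_effects=["group"])
        X, r, _ = mm.build_design(recs, spec, G.individual_ids)
        fit = mm.gibbs_single_trait(recs["value"].to_numpy(), X, r, G, cfg)
        assert len(fit.samples) == cfg.n_retained

    def test_null_signal_gives_small_h2(self):
        _, recs, _, G = make_study(n=500, m=800, h2=0.0, seed=13)
        fit = quick_fit(recs, G, iterations=2000, burn_in=600, thin=2)
        assert fit.samples["h2"].mean() < 0.10

    def test_h2_draws_in_unit_interval(self):
        _, recs, _, G = make_study(n=120, m=300, seed=14)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = quick_fit(recs, G, iterations=800, burn_in=200, thin=2)
        h2 = fit.samples["h2"]
        assert ((h2 > 0) & (h2 < 1)).all()

    def test_unstabilized_singular_g_directs_to_stabilize(self, rng):
        # n > m makes the raw method-1 G singular
        cfg = sim.SimulationConfig(n_individuals=30, n_markers=5,
                                   n_chromosomes=1, seed=4)
        g = sim.simulate_genotypes(cfg)
        G = grm_mod.vanraden_g(g)  # no stabilization
        recs = pd.DataFrame({"sow_id": g.individual_ids,
                             "value": rng.normal(size=30)})
        X, r, _ = mm.build_design(recs, mm.ModelSpec(response="value"),
                                  G.individual_ids)
        with pytest.raises(GrmError, match="stabilize"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mm.gibbs_single_trait(
                    recs["value"].to_numpy(), X, r, G,
                    mm.GibbsConfig(iterations=300, burn_in=100, thin=1))


class TestGibbsRepeatability:
    def test_recovery_with_repeated_records(self):
        cfg = sim.SimulationConfig(
            n_individuals=500, n_markers=1200, h2={"t": 0.12},
            pe_fraction={"t": 0.25}, records_per_individual={"t": 3},
            seed=21)
        g = sim.simulate_genotypes(cfg)
        pheno, _ = sim.simulate_phenotypes(g, cfg)
        recs = pheno[pheno.trait == "t"].reset_index(drop=True)
        G = grm_mod.stabilize(grm_mod.vanraden_g(g), 0.01)
        fit = quick_fit(recs, G, iterations=3000, burn_in=1000, thin=2,
                        repeated=True)
        s = fit.samples
        tot = s[["sigma_a2", "sigma_pe2", "sigma_e2"]].sum(axis=1)
        assert s["h2"].mean() == pytest.approx(0.12, abs=0.08)
        assert (s["sigma_pe2"] / tot).mean() == pytest.approx(0.25, abs=0.08)
        # repeatability = (sa2 + spe2) / total, per draw
        np.testing.assert_allclose(
            s["repeatability"],
            (s["sigma_a2"] + s["sigma_pe2"]) / tot, rtol=1e-10)

    def test_zero_pe_concentrates_at_boundary(self):
        cfg = sim.SimulationConfig(
            n_individuals=300, n_markers=800, h2={"t": 0.2},
            records_per_individual={"t": 3}, seed=22)
        g = sim.simulate_genotypes(cfg)
        pheno, _ = sim.simulate_phenotypes(g, cfg)
        recs = pheno[pheno.trait == "t"].reset_index(drop=True)
        G = grm_mod.stabilize(grm_mod.vanraden_g(g), 0.01)
        fit = quick_fit(recs, G, iterations=2500, burn_in=800, thin=2,
                        repeated=True)
        assert fit.samples["sigma_pe2"].mean() < 0.10

    def test_single_record_data_warns_weak_identification(self):
        _, recs, _, G = make_study(n=100, m=250, seed=23)
        with pytest.warns(UserWarning, match="weakly identified"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                quick_fit(recs, G, iterations=400, burn_in=100, thin=2,
                          repeated=True)


class TestGibbsTwoTrait:
    def fit_pair(self, recs1, recs2, G, seed=1, iterations=2500,
                 burn_in=800):
        spec = mm.ModelSpec(response="t", fixed_effects=["group"])
        X1, r1, _ = mm.build_design(recs1, spec, G.individual_ids)
        X2, r2, _ = mm.build_design(recs2, spec, G.individual_ids)
        cfg = mm.GibbsConfig(iterations=iterations, burn_in=burn_in,
                             thin=2, seed=seed)
        return mm.gibbs_two_trait(
            recs1["value"].to_numpy(), recs2["value"].to_numpy(),
            X1, X2, r1, r2, G, cfg)

    def test_duplicated_trait_gives_rg_near_one(self):
        _, recs, _, G = make_study(n=300, m=800, h2=0.3, seed=31)
        fit = self.fit_pair(recs, recs.copy(), G)
        assert fit.samples["rg"].mean() > 0.95

    def test_independent_traits_give_rg_near_zero(self):
        cfg = sim.SimulationConfig(n_individuals=400, n_markers=1000,
                                   h2={"t1": 0.3, "t2": 0.3}, seed=32)
        g = sim.simulate_genotypes(cfg)
        pheno, _ = sim.simulate_phenotypes(g, cfg)
        G = grm_mod.stabilize(grm_mod.vanraden_g(g), 0.01)
        r1 = pheno[pheno.trait == "t1"].reset_index(drop=True)
        r2 = pheno[pheno.trait == "t2"].reset_index(drop=True)
        spec = mm.ModelSpec(response="t", fixed_effects=["group"])
        X1, i1, _ = mm.build_design(r1, spec, G.individual_ids)
        X2, i2, _ = mm.build_design(r2, spec, G.individual_ids)
        fit = mm.gibbs_two_trait(
            r1["value"].to_numpy(), r2["value"].to_numpy(),
            X1, X2, i1, i2, G,
            mm.GibbsConfig(iterations=2500, burn_in=800, thin=2, seed=2))
        assert abs(fit.samples["rg"].mean()) < 0.30

    def test_rg_draws_bounded(self):
        _, recs, _, G = make_study(n=200, m=500, seed=33)
        rng = np.random.default_rng(5)
        recs2 = recs.copy()
        recs2["value"] = 0.5 * recs["value"] + rng.normal(size=len(recs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = self.fit_pair(recs, recs2, G, iterations=900, burn_in=300)
        assert fit.samples["rg"].between(-1, 1).all()
        assert fit.samples["h2_1"].between(0, 1).all()


class TestSummarizeFit:
    def test_constant_chain_has_zero_psd(self):
        fit = mm.ModelFit(
            kind="single",
            samples=pd.DataFrame({"sigma_a2": np.full(200, 0.75),
                                  "sigma_e2": np.full(200, 3.62),
                                  "h2": np.full(200, 0.17)}),
            individual_ids=["a"], a_draws=None,
            config=mm.GibbsConfig(iterations=300, burn_in=100, thin=1))
        table = mm.summarize_fit(fit).set_index("parameter")
        assert table.loc["h2", "psd"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["sigma_a2", "mean"] == pytest.approx(0.75)

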