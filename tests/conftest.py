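import numpy as np
import pytest

from sowreact import grm as grm_mod
from sowreact import mixed_models as mm
from sowreact import synthetic_data as sim


def make_study(n=400, m=1200, h2=0.30, seed=0, **kwargs):
    """Simulate one study and return (genotypes, records, truth, G*)."""
    cfg = sim.SimulationConfig(n_individuals=n, n_markers=m,
                               h2={"t": h2}, seed=seed, **kwargs)
    g = sim.simulate_genotypes(cfg)
    pheno, truth = sim.simulate_phenotypes(g, cfg)
    recs = pheno[pheno.trait == "t"].reset_index(drop=True)
    G = grm_mod.stabilize(grm_mod.vanraden_g(g), 0.01)
    return g, recs, truth, G


def quick_fit(recs, G, iterations=2500, burn_in=800, thin=2, seed=1,
              repeated=False):
    spec = mm.ModelSpec(
        response="t", fixed_effects=["group"],
        random_terms=("additive", "permanent_environment") if repeated
        else ("additive",))
    X, rec2ind, _ = mm.build_design(recs, spec, G.individual_ids)
    cfg = mm.GibbsConfig(iterations=iterations, burn_in=burn_in, thin=thin,
                         seed=seed)
    fitter = mm.gibbs_repeatability if repeated else mm.gibbs_single_trait
    return fitter(recs["value"].to_numpy(), X, rec2ind, G, cfg)


@pytest.fixture(scope="session")
def study500():
    """Midsize HWE study shared by read-only tests."""
    return make_study(n=500, m=2000, h2=0.30, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
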