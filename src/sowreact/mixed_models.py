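"""Genomic animal models fitted by Gibbs sampling.

Three model shapes are supported, all with the genomic relationship
matrix G as the covariance kernel of the additive effect:

* single-record:   y = Xb + Za + e,          a ~ N(0, G sa2), e ~ N(0, I se2)
* repeatability:   y = Xb + Za + Wpe + e,    pe ~ N(0, I spe2)
* two-trait:       the bivariate version with a 2x2 genetic (co)variance
  matrix (and, when both traits have repeated records on aligned record
  structures, 2x2 permanent-environment and residual matrices).

Heritability is computed per posterior draw as sa2/(sa2+se2) for
single-record traits and sa2/(sa2+spe2+se2) for repeated-record traits;
the genetic correlation is cov12/sqrt(sa2_1*sa2_2) per draw.

Sampling strategy
-----------------
The additive effects are updated as a block.  Writing G = U D U' and
solving the generalized eigenproblem of (U' Z'Z U, D^-1) once per fit
yields coordinates gamma with an iid N(0, sa2) prior in which the
conditional posterior is diagonal for every value of the variance ratio,
so each sweep costs O(n^2) instead of a fresh O(n^3) factorization.
Fixed effects are drawn jointly from their multivariate-normal full
conditional; variances from scaled inverse chi-square (inverse Wishart
in the bivariate case) full conditionals.  Priors default to flat
(bounded improper) on variances and flat on location effects, with a
weakly-informative scaled inverse chi-square alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import invwishart

from .errors import DesignError, GrmError
from .grm import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "GibbsConfig", "ModelFit", "VariancePrior",
    "DEFAULT_TRAIT_MODELS", "load_model_config",
    "heritability", "genetic_correlation", "build_design",
    "gibbs_single_trait", "gibbs_repeatability", "gibbs_two_trait",
    "summarize_fit", "stepwise_select",
]


# ---------------------------------------------------------------------------
# formulas shared with the worked summaries

def heritability(sigma_a2, sigma_e2, sigma_pe2=0.0):
    """h2 = sa2 / (sa2 + [spe2 +] se2); vectorized over draws."""
    return np.asarray(sigma_a2) / (
        np.asarray(sigma_a2) + np.asarray(sigma_pe2) + np.asarray(sigma_e2))


def genetic_correlation(cov12, sigma_a2_1, sigma_a2_2):
    """rg = cov12 / sqrt(sa2_1 * sa2_2); vectorized over draws."""
    return np.asarray(cov12) / np.sqrt(
        np.asarray(sigma_a2_1) * np.asarray(sigma_a2_2))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class VariancePrior:
    """Scaled inverse chi-square prior (df=-2, scale=0 is flat)."""

    df: float = -2.0
    scale: float = 0.0


@dataclass
class ModelSpec:
    """What to fit for one trait: response, systematic effects, randoms."""

    response: str
    fixed_effects: list = field(default_factory=list)  # categorical factors
    covariates: list = field(default_factory=list)     # continuous
    random_terms: tuple = ("additive",)
    id_col: str = "sow_id"

    def __post_init__(self):
        if "additive" not in self.random_terms:
            raise DesignError("the additive genetic term is always present")

    @property
    def use_pe(self) -> bool:
        return "permanent_environment" in self.random_terms


#: Final per-trait systematic effects of the source study's models.
#: Abbreviations: CG contemporary group, IPT/FPT/SPT initial / first- /
#: second-site position type, IM intervention moment, HD hair density,
#: Par parity, FCG/WCG farrowing/weaning contemporary group, Wk week,
#: loc barn location, TT touches, WS-T weather-station temperature,
#: DP dew point, DIL days in lactation, RRR/PSR recorder ids.
DEFAULT_TRAIT_MODELS: dict[str, "ModelSpec"] = {}


def _register_defaults():
    single = ("additive",)
    repeated = ("additive", "permanent_environment")
    layouts = {
        "RS": (["CG", "IPT", "FPT", "SPT", "IM", "HD"], ["TT"], single),
        "VS": (["CG", "IPT", "FPT", "SPT", "IM", "HD"], ["TT"], single),
        "ST": (["CG", "FPT", "Par", "HD"], ["WS_T", "TT"], single),
        "LB": (["Par", "FCG"], [], single),
        "TB": (["Par", "FCG"], [], single),
        "SB": (["Par", "FCG"], [], single),
        "PW": (["Par", "WCG"], [], single),
        "PD": (["Par", "WCG"], [], single),
        "VT": (["Par", "Wk", "loc"], ["DP"], repeated),
        "RR": (["RRR", "WkDT", "Par", "loc"], ["DIL", "WS_T"], repeated),
        "PS": (["PSR", "WkD", "Par", "loc"], ["DIL", "WS_T"], repeated),
    }
    for trait, (fixed, covs, rand) in layouts.items():
        DEFAULT_TRAIT_MODELS[trait] = ModelSpec(
            response=trait, fixed_effects=fixed, covariates=covs,
            random_terms=rand)


_register_defaults()


def load_model_config(path) -> dict[str, "ModelSpec"]:
    """Read per-trait model specs from a YAML file.

    Layout: a mapping of trait name to ``fixed_effects`` (list),
    ``covariates`` (list), ``repeated`` (bool) and optionally
    ``id_col``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = {}
    for trait, entry in raw.items():
        entry = entry or {}
        specs[trait] = ModelSpec(
            response=trait,
            fixed_effects=list(entry.get("fixed_effects", [])),
            covariates=list(entry.get("covariates", [])),
            random_terms=("additive", "permanent_environment")
            if entry.get("repeated", False) else ("additive",),
            id_col=entry.get("id_col", "sow_id"),
        )
    return specs


@dataclass
class GibbsConfig:
    """Chain settings; defaults follow a long single-chain convention
    (500k iterations, 150k burn-in, thinning 80)."""

    iterations: int = 500_000
    burn_in: int = 150_000
    thin: int = 80
    seed: int = 0
    prior: str = "flat"  # or "weak"

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_retained < 100:
            warnings.warn(
                f"only {self.n_retained} retained draws; summaries may be "
                "unstable", stacklevel=2)

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ModelFit:
    """Posterior draws and summaries from one Gibbs run."""

    kind: str                      # single / repeatability / two_trait
    samples: pd.DataFrame          # one row per retained draw
    individual_ids: list
    a_draws: np.ndarray | None     # n x ndraws (single) or dict for 2-trait
    config: GibbsConfig
    meta: dict = field(default_factory=dict)

    @property
    def gebv(self) -> pd.DataFrame:
        """Posterior mean and SD of each individual's breeding value."""
        if self.a_draws is None:
            raise ValueError("additive-effect draws were not stored")
        draws = self.a_draws if isinstance(self.a_draws, np.ndarray) \
            else self.a_draws[sorted(self.a_draws)[0]]
        return pd.DataFrame({
            "individual_id": self.individual_ids,
            "gebv": draws.mean(axis=1),
            "psd": draws.std(axis=1, ddof=1),
        })


# ---------------------------------------------------------------------------
# design matrices

def build_design(records: pd.DataFrame, spec: ModelSpec, grm_ids
                 ) -> tuple[np.ndarray, np.ndarray, list]:
    """Build X and the record->individual map for one trait.

    X carries an intercept, reference-level-dropped dummies for each
    categorical fixed effect and the covariates as given; the returned
    integer array plays the role of the Z (and W) incidence matrices,
    mapping each record to its individual's position in ``grm_ids``.
    Records must be complete and every individual must appear in the
    GRM.
    """
    idx = {str(i): k for k, i in enumerate(grm_ids)}
    ids = records[spec.id_col].astype(str)
    missing = sorted(set(ids) - set(idx))
    if missing:
        raise DesignError(
            f"records reference individuals absent from G: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    rec2ind = ids.map(idx).to_numpy(dtype=int)

    cols = [np.ones(len(records))]
    names = ["intercept"]
    for f in spec.fixed_effects:
        col = records[f]
        if col.isna().any():
            raise DesignError(f"factor {f!r} has missing levels")
        levels = pd.unique(col)
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped from X",
                          stacklevel=2)
            continue
        dummies = pd.get_dummies(col.astype(str), prefix=f, drop_first=True)
        cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies)
        names.extend(dummies.columns)
    for cvt in spec.covariates:
        col = records[cvt]
        if col.isna().any():
            raise DesignError(f"covariate {cvt!r} has missing values")
        cols.append(col.to_numpy(dtype=float))
        names.append(cvt)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR
        _, r, piv = sla.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise DesignError(
            f"X is rank deficient after reference-level dropping; aliased "
            f"columns: {bad}")
    return X, rec2ind, names


# ---------------------------------------------------------------------------
# sampler internals

def _prior(config: GibbsConfig, var_y: float, n_components: int
           ) -> VariancePrior:
    if config.prior == "flat":
        return VariancePrior(-2.0, 0.0)
    if config.prior == "weak":
        return VariancePrior(4.0, var_y / max(n_components, 1))
    raise ValueError(f"unknown prior {config.prior!r}")


def _draw_variance(ss: float, q: int, prior: VariancePrior,
                   rng: np.random.Generator) -> float:
    df = q + prior.df
    if df <= 0:
        raise ValueError("too few levels for a proper variance update")
    return (ss + prior.df * prior.scale if prior.df > 0 else ss) \
        / rng.chisquare(df)


class _Rotation:
    """Per-fit cache: G = U D U' and the generalized eigenbasis that
    simultaneously diagonalizes the information (U'Z'Z U) and the prior
    (D^-1), so the additive-effect full conditional is elementwise."""

    def __init__(self, grm: GRM, rec2ind: np.ndarray):
        n = grm.n
        self.n = n
        self.counts = np.bincount(rec2ind, minlength=n).astype(float)
        # refitting the same kernel (other traits, other chains) reuses
        # the decompositions, which dominate the setup cost
        cache = getattr(grm, "_rotation_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(grm, "_rotation_cache", cache)
        key = self.counts.tobytes()
        if key in cache:
            self.kappa, self.T, self.Tt = cache[key]
            return
        if "eig" in cache:
            d, U = cache["eig"]
        else:
            d, U = np.linalg.eigh(grm.matrix)
            if d.min() <= 1e-10:
                raise GrmError(
                    "G is not positive definite; apply grm.stabilize first "
                    f"(smallest eigenvalue {d.min():.3g})")
            cache["eig"] = (d, U)
        A = (U.T * self.counts) @ U
        kappa, V = sla.eigh(A, np.diag(1.0 / d))
        self.kappa = np.clip(kappa, 0.0, None)
        self.T = U @ V         # a = T gamma, gamma ~ N(0, sa2 I)
        self.Tt = self.T.T
        cache[key] = (self.kappa, self.T, self.Tt)


def _collapse(rec2ind, weights, n):
    return np.bincount(rec2ind, weights=weights, minlength=n)


def _gibbs_core(y, X, rec2ind, grm: GRM, config: GibbsConfig, use_pe: bool
                ) -> ModelFit:
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    N, n = len(y), grm.n
    rot = _Rotation(grm, rec2ind)
    T, Tt, kappa, c = rot.T, rot.Tt, rot.kappa, rot.counts

    if use_pe and (c >= 2).mean() < 0.05:
        warnings.warn("almost all individuals have a single record; "
                      "sigma_pe2 and sigma_e2 are weakly identified",
                      stacklevel=2)

    Lx = np.linalg.cholesky(X.T @ X)
    vy = float(np.var(y))
    ncomp = 3 if use_pe else 2
    prior = _prior(config, vy, ncomp)

    beta = sla.cho_solve((Lx, True), X.T @ y)
    gamma = np.zeros(n)
    a = np.zeros(n)
    pe = np.zeros(n)
    sig_a, sig_e = 0.2 * vy, 0.6 * vy
    sig_pe = 0.2 * vy if use_pe else 0.0

    keep = config.n_retained
    out = {k: np.empty(keep) for k in
           (["sigma_a2", "sigma_e2", "h2"]
            + (["sigma_pe2", "repeatability"] if use_pe else []))}
    gam_draws = np.empty((keep, n))
    k = 0
    p = X.shape[1]
    for it in range(1, config.iterations + 1):
        # fixed effects | rest  (flat prior)
        r = y - a[rec2ind] - (pe[rec2ind] if use_pe else 0.0)
        mean_b = sla.cho_solve((Lx, True), X.T @ r)
        beta = mean_b + np.sqrt(sig_e) * sla.solve_triangular(
            Lx.T, rng.standard_normal(p), lower=False)
        xb = X @ beta

        # additive effects in the diagonalizing basis
        y0 = y - xb - (pe[rec2ind] if use_pe else 0.0)
        u = Tt @ _collapse(rec2ind, y0, n)
        pv = 1.0 / (kappa / sig_e + 1.0 / sig_a)
        gamma = pv * u / sig_e + np.sqrt(pv) * rng.standard_normal(n)
        a = T @ gamma

        if use_pe:
            s = _collapse(rec2ind, y - xb - a[rec2ind], n)
            pvp = 1.0 / (c / sig_e + 1.0 / sig_pe)
            pe = pvp * s / sig_e + np.sqrt(pvp) * rng.standard_normal(n)
            sig_pe = _draw_variance(pe @ pe, n, prior, rng)

        e = y - xb - a[rec2ind] - (pe[rec2ind] if use_pe else 0.0)
        sig_e = _draw_variance(e @ e, N, prior, rng)
        sig_a = _draw_variance(gamma @ gamma, n, prior, rng)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["sigma_a2"][k] = sig_a
            out["sigma_e2"][k] = sig_e
            tot = sig_a + sig_pe + sig_e
            out["h2"][k] = sig_a / tot
            if use_pe:
                out["sigma_pe2"][k] = sig_pe
                out["repeatability"][k] = (sig_a + sig_pe) / tot
            gam_draws[k] = gamma
            k += 1

    a_draws = T @ gam_draws[:k].T
    return ModelFit(
        kind="repeatability" if use_pe else "single",
        samples=pd.DataFrame({key: v[:k] for key, v in out.items()}),
        individual_ids=list(grm.individual_ids),
        a_draws=a_draws,
        config=config,
        meta={"n_records": N, "n_individuals": n, "epsilon": grm.epsilon,
              "X": X, "rec2ind": np.asarray(rec2ind, int), "y": y,
              "use_pe": use_pe, "var_y": vy},
    )


def gibbs_single_trait(y, X, rec2ind, grm: GRM, config: GibbsConfig
                       ) -> ModelFit:
    """Fit the single-record animal model y = Xb + Za + e by Gibbs
    sampling; returns retained draws of the variance components, per-draw
    h2, and the additive-effect draws (GEBVs)."""
    return _gibbs_core(y, X, rec2ind, grm, config, use_pe=False)


def gibbs_repeatability(y, X, rec2ind, grm: GRM, config: GibbsConfig
                        ) -> ModelFit:
    """Fit the repeatability model y = Xb + Za + Wpe + e; h2 uses the
    three-component denominator and the repeatability
    (sa2+spe2)/(sa2+spe2+se2) is reported per draw."""
    return _gibbs_core(y, X, rec2ind, grm, config, use_pe=True)


def _draw_invwishart(S, q, dim, rng):
    if q < dim:
        raise ValueError("degenerate (co)variance update: fewer effective "
                         "observations than traits")
    return invwishart.rvs(df=q, scale=S + 1e-10 * np.eye(dim),
                          random_state=rng)


def gibbs_two_trait(y1, y2, X1, X2, rec1, rec2, grm: GRM,
                    config: GibbsConfig, use_pe: tuple = (False, False)
                    ) -> ModelFit:
    """Bivariate animal model for a trait pair.

    Each trait keeps its own design; the genetic effects share the G
    kernel with a 2x2 (co)variance matrix sampled from its inverse
    Wishart full conditional.  The residual covariance is estimated only
    when the two traits are recorded on the same record structure
    (identical record->individual maps); otherwise it is fixed at 0 and
    the residual variances are updated separately.  Permanent-environment
    effects are included per trait; their covariance is estimated when
    both traits have one.

    Per retained draw the fit reports the genetic correlation
    rg = cov12/sqrt(sa2_1*sa2_2) and the phenotypic correlation from the
    summed component (co)variances.
    """
    rng = np.random.default_rng(config.seed)
    y = [np.asarray(y1, float), np.asarray(y2, float)]
    X = [np.asarray(X1, float), np.asarray(X2, float)]
    rec = [np.asarray(rec1, int), np.asarray(rec2, int)]
    n = grm.n
    aligned = len(rec[0]) == len(rec[1]) and np.array_equal(rec[0], rec[1])
    if not aligned:
        logger.info("record structures differ; residual covariance fixed at 0")
    rots = [_Rotation(grm, rec[0])]
    rots.append(rots[0] if aligned else _Rotation(grm, rec[1]))
    Lx = [np.linalg.cholesky(Xt.T @ Xt) for Xt in X]
    N = [len(yt) for yt in y]
    vy = [float(np.var(yt)) for yt in y]

    both_pe = use_pe[0] and use_pe[1]
    gam = np.zeros((n, 2))
    av = np.zeros((n, 2))
    pe = np.zeros((n, 2))
    beta = [sla.cho_solve((Lx[t], True), X[t].T @ y[t]) for t in (0, 1)]
    G0 = np.diag([0.2 * v for v in vy])
    R0 = np.diag([0.6 * v for v in vy])
    P0 = np.diag([0.2 * v if use_pe[t] else 0.0 for t, v in enumerate(vy)])
    prior = [_prior(config, vy[t], 2 + use_pe[t]) for t in (0, 1)]

    keep = config.n_retained
    cols = ["sigma_a2_1", "sigma_a2_2", "cov_a_12",
            "sigma_e2_1", "sigma_e2_2", "cov_e_12",
            "h2_1", "h2_2", "rg", "rp"]
    if use_pe[0]:
        cols.append("sigma_pe2_1")
    if use_pe[1]:
        cols.append("sigma_pe2_2")
    out = {kk: np.empty(keep) for kk in cols}
    gdraws = [np.empty((keep, n)), np.empty((keep, n))]
    k = 0
    for it in range(1, config.iterations + 1):
        for t in (0, 1):
            o = 1 - t
            rot = rots[t]
            if aligned:
                e_o = y[o] - X[o] @ beta[o] - av[rec[o], o] \
                    - (pe[rec[o], o] if use_pe[o] else 0.0)
                adj = (R0[t, o] / R0[o, o]) * e_o
                r_c = R0[t, t] - R0[t, o] ** 2 / R0[o, o]
            else:
                adj, r_c = 0.0, R0[t, t]
            ystar = y[t] - adj

            r = ystar - av[rec[t], t] - (pe[rec[t], t] if use_pe[t] else 0.0)
            mean_b = sla.cho_solve((Lx[t], True), X[t].T @ r)
            beta[t] = mean_b + np.sqrt(r_c) * sla.solve_triangular(
                Lx[t].T, rng.standard_normal(X[t].shape[1]), lower=False)
            xb = X[t] @ beta[t]

            g_c = G0[t, t] - G0[t, o] ** 2 / G0[o, o]
            mg = (G0[t, o] / G0[o, o]) * gam[:, o]
            y0 = ystar - xb - (pe[rec[t], t] if use_pe[t] else 0.0)
            u = rot.Tt @ _collapse(rec[t], y0, n)
            pv = 1.0 / (rot.kappa / r_c + 1.0 / g_c)
            gam[:, t] = pv * (u / r_c + mg / g_c) \
                + np.sqrt(pv) * rng.standard_normal(n)
            av[:, t] = rot.T @ gam[:, t]

            if use_pe[t]:
                if both_pe:
                    p_c = P0[t, t] - P0[t, o] ** 2 / P0[o, o]
                    mp = (P0[t, o] / P0[o, o]) * pe[:, o]
                else:
                    p_c, mp = P0[t, t], 0.0
                s = _collapse(rec[t], ystar - xb - av[rec[t], t], n)
                pvp = 1.0 / (rot.counts / r_c + 1.0 / p_c)
                pe[:, t] = pvp * (s / r_c + mp / p_c) \
                    + np.sqrt(pvp) * rng.standard_normal(n)

        # (co)variance matrices from inverse Wishart full conditionals
        G0 = _draw_invwishart(gam.T @ gam, n, 2, rng)
        if both_pe:
            P0 = _draw_invwishart(pe.T @ pe, n, 2, rng)
        else:
            for t in (0, 1):
                if use_pe[t]:
                    P0[t, t] = _draw_variance(pe[:, t] @ pe[:, t], n,
                                              prior[t], rng)
        E = [y[t] - X[t] @ beta[t] - av[rec[t], t]
             - (pe[rec[t], t] if use_pe[t] else 0.0) for t in (0, 1)]
        if aligned:
            Em = np.column_stack(E)
            R0 = _draw_invwishart(Em.T @ Em, N[0], 2, rng)
        else:
            for t in (0, 1):
                R0[t, t] = _draw_variance(E[t] @ E[t], N[t], prior[t], rng)
            R0[0, 1] = R0[1, 0] = 0.0

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            tots = [G0[t, t] + P0[t, t] + R0[t, t] for t in (0, 1)]
            out["sigma_a2_1"][k] = G0[0, 0]
            out["sigma_a2_2"][k] = G0[1, 1]
            out["cov_a_12"][k] = G0[0, 1]
            out["sigma_e2_1"][k] = R0[0, 0]
            out["sigma_e2_2"][k] = R0[1, 1]
            out["cov_e_12"][k] = R0[0, 1]
            if use_pe[0]:
                out["sigma_pe2_1"][k] = P0[0, 0]
            if use_pe[1]:
                out["sigma_pe2_2"][k] = P0[1, 1]
            out["h2_1"][k] = G0[0, 0] / tots[0]
            out["h2_2"][k] = G0[1, 1] / tots[1]
            out["rg"][k] = G0[0, 1] / np.sqrt(G0[0, 0] * G0[1, 1])
            out["rp"][k] = (G0[0, 1] + P0[0, 1] + R0[0, 1]) \
                / np.sqrt(tots[0] * tots[1])
            gdraws[0][k] = gam[:, 0]
            gdraws[1][k] = gam[:, 1]
            k += 1

    a_draws = {f"trait{t + 1}": rots[t].T @ gdraws[t][:k].T for t in (0, 1)}
    return ModelFit(
        kind="two_trait",
        samples=pd.DataFrame({kk: v[:k] for kk, v in out.items()}),
        individual_ids=list(grm.individual_ids),
        a_draws=a_draws,
        config=config,
        meta={"aligned_records": aligned, "use_pe": use_pe,
              "epsilon": grm.epsilon,
              "X": {"trait1": X[0], "trait2": X[1]},
              "rec2ind": {"trait1": rec[0], "trait2": rec[1]},
              "y": {"trait1": y[0], "trait2": y[1]}},
    )


def summarize_fit(fit: ModelFit, check_convergence: bool = True
                  ) -> pd.DataFrame:
    """Posterior mean and posterior SD per component.

    Derived quantities (h2, rg, rp) were computed per draw inside the
    sampler, so their summaries are proper posterior summaries, not
    plug-ins of component means.  For two-trait fits a Geweke check on
    the genetic-correlation chain flags failure to converge (FTC).
    """
    s = fit.samples
    if len(s) < 100:
        warnings.warn(f"summary from only {len(s)} retained draws",
                      stacklevel=2)
    rows = [{"parameter": col,
             "mean": float(s[col].mean()),
             "psd": float(s[col].std(ddof=0))} for col in s.columns]
    table = pd.DataFrame(rows)
    if check_convergence and fit.kind == "two_trait":
        from .diagnostics import geweke
        try:
            _, p = geweke(s["rg"].to_numpy())
            table.attrs["ftc"] = bool(p < 0.05)
            table.attrs["geweke_p_rg"] = float(p)
        except Exception:  # degenerate chain
            table.attrs["ftc"] = True
    return table


# ---------------------------------------------------------------------------
# stepwise systematic-effect selection

def stepwise_select(records: pd.DataFrame, response: str, candidates,
                    categorical=None, alpha: float = 0.05,
                    id_col: str = "sow_id") -> ModelSpec:
    """Bidirectional AIC search over candidate systematic effects,
    followed by removal of terms whose partial-F p-value is >= alpha.

    Mirrors the classical workflow of fitting the full ordinary
    least-squares model, refining it by stepwise AIC with both forward
    and backward moves, and keeping only effects significant at alpha.
    Deterministic: ties are broken by term name.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    candidates = list(candidates)
    categorical = set(categorical or ())
    if not candidates:
        warnings.warn("no candidate effects; returning intercept-only spec",
                      stacklevel=2)
        return ModelSpec(response=response, id_col=id_col)

    def term(name):
        return f"C({name})" if name in categorical else name

    def fit(terms):
        rhs = " + ".join(sorted(term(t) for t in terms)) or "1"
        return smf.ols(f"{response} ~ {rhs}", data=records).fit()

    current = set(candidates)
    best_aic = fit(current).aic
    while True:
        moves = []
        for t in sorted(current):
            moves.append((fit(current - {t}).aic, "drop", t))
        for t in sorted(set(candidates) - current):
            moves.append((fit(current | {t}).aic, "add", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        aic, action, t = moves[0]
        if aic < best_aic - 1e-9:
            best_aic = aic
            current = current - {t} if action == "drop" else current | {t}
        else:
            break

    # significance pruning (partial F, type-II ANOVA)
    while current:
        res = fit(current)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl = anova_lm(res, typ=2)
        pvals = {t: float(tbl.loc[term(t), "PR(>F)"]) for t in current
                 if term(t) in tbl.index}
        worst = max(sorted(pvals), key=lambda t: (pvals[t], t), default=None)
        if worst is not None and pvals[worst] >= alpha:
            current.discard(worst)
        else:
            break

    return ModelSpec(
        response=response,
        fixed_effects=sorted(t for t in current if t in categorical),
        covariates=sorted(t for t in current if t not in categorical),
        id_col=id_col,
    )
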