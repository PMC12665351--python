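"""Synthetic genotypes, phenotypes and ethogram sessions with known truth.

The generator emulates the statistical structure the pipeline assumes:

* biallelic HWE genotypes with marker allele frequencies drawn from a
  MAF range, placed with distinct bp positions on a small number of
  chromosomes;
* polygenic trait architectures — per-marker effects drawn so the
  additive values have the requested variance, with optional planted
  QTL of specified variance fractions, multi-trait genetic correlations
  (including near-unity and moderate negative), permanent-environment
  variance and repeated records, and categorical group (management)
  effects;
* an observational ethogram layer in which a latent reactivity value per
  sow drives ordered-threshold posture states at three time points,
  stage vocalization subsets whose scores increase with reactivity, a
  log-normal shave time, and touch/intervention covariates with roughly
  44% of sows needing no intervention.

Every generator is a pure function of (config, seed); the returned truth
record stores each realized component for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ethogram import STAGE_SCORE_TO_SUBSET
from .genotype_qc import GenotypeMatrix
from .grm import centered_dosages

__all__ = [
    "SimulationConfig", "simulate_genotypes", "simulate_phenotypes",
    "simulate_ethogram_sessions", "sessions_to_frame",
]

TRUTH_SCHEMA_VERSION = 1


@dataclass
class SimulationConfig:
    """Ground-truth layout of one simulated study."""

    n_individuals: int = 500
    n_markers: int = 2000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 100_000_000
    maf_range: tuple = (0.01, 0.5)
    missing_rate: float = 0.0
    # trait -> narrow-sense heritability (phenotypic variance is 1)
    h2: dict = field(default_factory=lambda: {"trait1": 0.15})
    # genetic correlation matrix aligned with sorted(h2) trait order
    rg: np.ndarray | None = None
    # trait -> permanent-environment variance fraction (repeated traits)
    pe_fraction: dict = field(default_factory=dict)
    # trait -> records per individual (default 1)
    records_per_individual: dict = field(default_factory=dict)
    # trait -> list of (marker_index, variance_fraction)
    planted_qtl: dict = field(default_factory=dict)
    n_groups: int = 10
    group_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        for t, h in self.h2.items():
            pe = self.pe_fraction.get(t, 0.0)
            if not (0 <= h < 1 and 0 <= pe < 1 and h + pe < 1):
                raise ValueError(
                    f"trait {t}: infeasible variance fractions h2={h}, pe={pe}")
        if self.rg is not None:
            R = np.asarray(self.rg, dtype=float)
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ValueError("rg matrix must be symmetric with unit "
                                 "diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("rg matrix must be positive semidefinite")

    @property
    def traits(self) -> list:
        return sorted(self.h2)


def simulate_genotypes(config: SimulationConfig, seed: int | None = None
                       ) -> GenotypeMatrix:
    """HWE dosages with marker-specific allele frequencies and a marker
    map with distinct positions spread over the chromosomes."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, m = config.n_individuals, config.n_markers
    p = rng.uniform(*config.maf_range, size=m)
    flip = rng.random(m) < 0.5  # counted allele is minor or major at random
    p = np.where(flip, 1 - p, p)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        dos[rng.random(dos.shape) < config.missing_rate] = np.nan

    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for ci, idx in enumerate(per_chrom, start=1):
        chroms[idx] = str(ci)
        draw = np.unique(rng.integers(
            1, config.chromosome_length_bp, size=2 * len(idx) + 16))
        while len(draw) < len(idx):  # vanishingly unlikely at chip density
            draw = np.unique(np.concatenate(
                [draw, rng.integers(1, config.chromosome_length_bp,
                                    size=len(idx))]))
        pos[idx] = np.sort(rng.choice(draw, size=len(idx), replace=False))
    mm = pd.DataFrame({
        "chrom": chroms,
        "marker": [f"snp{j + 1}" for j in range(m)],
        "cm": 0.0,
        "pos_bp": pos,
    })
    ids = [f"sow{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(dos, ids, mm[["chrom", "marker", "cm", "pos_bp"]])


def simulate_phenotypes(g: GenotypeMatrix, config: SimulationConfig,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Phenotypes with known additive, permanent-environment, group and
    residual components (phenotypic variance 1 per trait).

    Per-marker effects are drawn N(0, sa2/(2 sum p(1-p))) — jointly
    across traits with the requested genetic correlation matrix — and
    planted QTL effects sized to their variance fractions are added.
    Returns a tidy record table (sow_id, trait, rec, group, covariate,
    value) and a truth record with every realized component.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    Z, p, denom = centered_dosages(g)
    n = g.n_individuals
    traits = config.traits
    t = len(traits)
    R = np.asarray(config.rg, float) if config.rg is not None else np.eye(t)

    sa = np.sqrt([config.h2[tr] for tr in traits])
    cov_eff = (np.outer(sa, sa) * R) / denom
    Lc = np.linalg.cholesky(cov_eff + 1e-12 * np.eye(t))
    effects = rng.standard_normal((config.n_markers, t)) @ Lc.T
    for k, tr in enumerate(traits):
        for j, frac in config.planted_qtl.get(tr, []):
            effects[j, k] += np.sqrt(frac / (2 * p[j] * (1 - p[j]))) \
                * rng.choice([-1.0, 1.0])
    a = Z @ effects  # n x t realized additive values

    groups = rng.integers(0, config.n_groups, size=n)
    group_effects = rng.normal(0, config.group_effect_sd,
                               size=(config.n_groups, t))
    rows = []
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "traits": traits,
        "h2": dict(config.h2),
        "pe_fraction": dict(config.pe_fraction),
        "rg": R.tolist(),
        "marker_effects": effects,
        "additive_values": pd.DataFrame(
            a, columns=traits, index=list(g.individual_ids)),
        "groups": groups,
        "pe_values": {},
    }
    for k, tr in enumerate(traits):
        h2 = config.h2[tr]
        pe_frac = config.pe_fraction.get(tr, 0.0)
        n_rec = config.records_per_individual.get(tr, 1)
        sig_e = np.sqrt(max(1.0 - h2 - pe_frac, 1e-12))
        pe = rng.normal(0, np.sqrt(pe_frac), size=n) if pe_frac > 0 \
            else np.zeros(n)
        truth["pe_values"][tr] = pe
        for r in range(n_rec):
            e = rng.normal(0, sig_e, size=n)
            y = a[:, k] + pe + group_effects[groups, k] + e
            rows.append(pd.DataFrame({
                "sow_id": list(g.individual_ids),
                "trait": tr,
                "rec": r + 1,
                "group": [f"g{gg + 1}" for gg in groups],
                "value": y,
            }))
    return pd.concat(rows, ignore_index=True), truth


# ---------------------------------------------------------------------------
# ethogram observation layer
#
# A single latent reactivity value per sow (on a roughly standard-normal
# scale) is thresholded into the observed postures and vocalization
# stage scores; noise standard deviations are chosen so the derived
# session scores retain most of the latent signal, as the real scoring
# protocol is designed to.

# posture cutpoints per time point (before contact the sows mostly lie;
# after handling more of them sit or stand)
_POSTURE_CUTS = {
    0: (0.7, 1.3, 1.9),
    1: (-0.3, 0.3, 1.0),
    2: (-0.3, 0.3, 1.0),
}
_STAGE_NOISE_SD = 0.6
_POSTURE_NOISE_SD = 0.7
# stage-score cutpoints on the latent+noise scale: low grunts are the
# common observation, pure barks rare
_STAGE_CUTS = (-0.64, 0.37, 1.12, 1.80, 2.40, 2.95, 3.45)
_P_NO_INTERVENTION = 0.442      # both sites accessible
_P_BEFORE_FIRST = 0.099         # intervened before the first site
_ST_LOG_MEAN = np.log(50.0)     # seconds
_ST_LOG_SLOPE = 0.30
_ST_LOG_SD = 0.38


def _ordinal(x, cuts):
    return np.searchsorted(np.asarray(cuts), x, side="right")


def simulate_ethogram_sessions(reactivity, config: SimulationConfig,
                               seed: int | None = None) -> pd.DataFrame:
    """Generate one shaving-test session per sow from latent reactivity.

    ``reactivity`` is one latent value per sow (additive plus
    environmental parts, roughly standardized).  Postures at the three
    time points and the per-stage vocalization scores are ordered
    thresholdings of reactivity plus independent noise; sows with an
    intervention get a fourth vocalization stage; shave time is
    log-normal with location increasing in reactivity.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    x = np.asarray(reactivity, dtype=float)
    n = len(x)
    posture_names = np.array(["LDL", "LDS", "SIT", "STD"])

    u = rng.random(n)
    intervention = np.where(
        u < _P_NO_INTERVENTION, "none",
        np.where(u < _P_NO_INTERVENTION + _P_BEFORE_FIRST,
                 "before_first_site", "between_sites"))

    rows = []
    for i in range(n):
        post = [posture_names[_ordinal(
            x[i] + rng.normal(0, _POSTURE_NOISE_SD), _POSTURE_CUTS[tp])]
            for tp in range(3)]
        n_stages = 3 if intervention[i] == "none" else 4
        stages = []
        for _ in range(n_stages):
            sc = int(_ordinal(x[i] + rng.normal(0, _STAGE_NOISE_SD),
                              _STAGE_CUTS))
            subset = STAGE_SCORE_TO_SUBSET[sc]
            stages.append(";".join(sorted(v.value for v in subset))
                          if subset else "NONE")
        stages += [""] * (4 - n_stages)
        st = float(np.exp(rng.normal(
            _ST_LOG_MEAN + _ST_LOG_SLOPE * x[i], _ST_LOG_SD)))
        touches = int(rng.poisson(1.5 + np.exp(0.4 * x[i])))
        rows.append({
            "sow_id": f"sow{i + 1:05d}",
            "posture_1": post[0], "posture_2": post[1], "posture_3": post[2],
            "voc_stage_1": stages[0], "voc_stage_2": stages[1],
            "voc_stage_3": stages[2], "voc_stage_4": stages[3],
            "shave_time_s": round(st, 1),
            "touches": touches,
            "intervention_moment": intervention[i],
            "hair_density": int(rng.integers(1, 4)),
            "contemporary_group": f"wk{1 + i * 6 // max(n, 1)}",
        })
    return pd.DataFrame(rows)


def sessions_to_frame(sessions: pd.DataFrame, path=None) -> pd.DataFrame:
    """Write (optionally) and return the sessions table in the CSV schema
    the scoring module reads."""
    if path is not None:
        sessions.to_csv(path, index=False)
    return sessions
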