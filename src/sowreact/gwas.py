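"""GWAS by back-solving genomic breeding values into SNP effects.

Given a fitted animal model, each retained posterior draw of the
additive effects u is mapped to marker-effect draws

    g_hat = Z' G*^-1 u / (2 sum p(1-p)),

with Z the centered dosage matrix used to build G.  Per-marker test
statistics, the variance explained 2p(1-p) g^2 / s2p, chromosome-wise
Bonferroni thresholds based on the effective number of independent
segments Me = 2 Ne L / ln(Ne L), the genomic inflation factor, and
+-100 kb candidate windows around significant markers follow.

Approximate p-values standardize each marker effect by a standard
error; two conventions are implemented:

* ``"blup"`` (default): the exact sampling SD of the back-solved BLUP at
  the posterior-mean variance components,
  var(g_hat_j) = (sa2/denom)^2 (Z' P Z)_jj with P the absorbed inverse
  phenotypic covariance; linear in y, hence calibrated (lambda ~ 1)
  under the null.
* ``"posterior"``: the posterior SD of the per-draw back-solved effects.
  Because weakly informed markers keep most of their prior uncertainty,
  this is strongly conservative (lambda << 1) on 50K-scale panels and is
  kept only for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import chi2, norm

from .errors import GrmError
from .genotype_qc import GenotypeMatrix
from .grm import GRM, centered_dosages
from .mixed_models import ModelFit

__all__ = [
    "SnpEffects", "ThresholdScheme", "backsolve_snp_effects",
    "approx_pvalues", "variance_explained", "me_thresholds",
    "genomic_inflation", "candidate_windows", "run_gwas",
    "windows_to_bed",
]

CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class SnpEffects:
    """Back-solved per-marker effect summaries (allele-substitution
    scale) plus what is needed for the test statistics."""

    mean: np.ndarray           # posterior mean effect per marker
    psd: np.ndarray            # posterior SD per marker
    freqs: np.ndarray          # counted-allele frequency per marker
    denom: float               # 2 sum p(1-p)
    blup: np.ndarray           # BLUP effect at posterior-mean variances
    blup_se: np.ndarray        # exact sampling SD of the BLUP
    ols: np.ndarray            # unshrunken single-marker GLS effect
    marker_map: pd.DataFrame


@dataclass
class ThresholdScheme:
    """Chromosome-wise Bonferroni thresholds alpha / Me."""

    ne: int
    alpha: float
    per_chromosome: pd.DataFrame  # chrom, length_morgans, me, threshold
    log_base: str = "natural"

    def threshold_for(self, chrom) -> float:
        t = self.per_chromosome.set_index("chrom")["threshold"]
        return float(t.loc[str(chrom)])


def backsolve_snp_effects(fit: ModelFit, genotypes: GenotypeMatrix,
                          grm: GRM, trait: str | None = None) -> SnpEffects:
    """Map posterior draws of the additive effects to marker effects.

    ``grm`` must be the (stabilized) kernel used in the fit and
    ``genotypes`` the QC-passed matrix it was built from; id and marker
    provenance are checked.  For two-trait fits, ``trait`` selects
    ``"trait1"`` or ``"trait2"``.
    """
    if list(map(str, genotypes.individual_ids)) != \
            list(map(str, grm.individual_ids)):
        raise GrmError("genotype individuals do not match the GRM")
    if list(map(str, fit.individual_ids)) != \
            list(map(str, grm.individual_ids)):
        raise GrmError("model-fit individuals do not match the GRM")
    if genotypes.n_markers != len(grm.allele_freqs):
        raise GrmError("marker count does not match the GRM provenance")
    a_draws = fit.a_draws
    if isinstance(a_draws, dict):
        if trait is None:
            raise ValueError("two-trait fit: specify trait='trait1'|'trait2'")
        a_draws = a_draws[trait]
    if a_draws is None:
        raise ValueError("fit has no stored additive-effect draws")

    Z, p, denom = centered_dosages(genotypes)
    cf = sla.cho_factor(grm.matrix)
    B = sla.cho_solve(cf, a_draws)            # G*^-1 u, n x ndraws
    eff_draws = (Z.T @ B) / denom             # m x ndraws
    mean = eff_draws.mean(axis=1)
    psd = eff_draws.std(axis=1, ddof=1)

    # exact BLUP and its sampling SD at the posterior-mean variances:
    # g_hat = (sa2/denom) Z' W' P y,  var(g_hat) = (sa2/denom)^2 Z'W' P WZ
    # with W the record->individual incidence and P the phenotypic
    # inverse covariance absorbed for the fixed effects (P V P = P)
    def pick(entry):
        return entry[trait] if isinstance(entry, dict) else entry
    if fit.kind == "two_trait":
        cols = {"trait1": ("sigma_a2_1", "sigma_e2_1", "sigma_pe2_1"),
                "trait2": ("sigma_a2_2", "sigma_e2_2", "sigma_pe2_2")}[trait]
    else:
        cols = ("sigma_a2", "sigma_e2", "sigma_pe2")
    s = fit.samples
    sa2 = float(s[cols[0]].mean())
    se2 = float(s[cols[1]].mean())
    spe2 = float(s[cols[2]].mean()) if cols[2] in s else 0.0
    X = pick(fit.meta["X"])
    rec = pick(fit.meta["rec2ind"])
    yv = pick(fit.meta["y"])
    V = sa2 * grm.matrix[np.ix_(rec, rec)] + se2 * np.eye(len(rec))
    if spe2 > 0:
        V += spe2 * (rec[:, None] == rec[None, :])
    cv = sla.cho_factor(V)
    Vx = sla.cho_solve(cv, X)
    Zr = Z[rec, :]
    PZ = sla.cho_solve(cv, Zr) - Vx @ np.linalg.solve(X.T @ Vx, Vx.T @ Zr)
    scale = sa2 / denom
    info = np.einsum("ij,ij->j", Zr, PZ).clip(min=0)
    blup = scale * (PZ.T @ yv)
    blup_se = scale * np.sqrt(info)
    # the unshrunken single-marker GLS effect shares the BLUP's z-score
    # but estimates the allele-substitution effect without shrinkage
    with np.errstate(divide="ignore", invalid="ignore"):
        ols = np.where(info > 0, blup / (scale * info), 0.0)
    return SnpEffects(mean, psd, p, denom, blup, blup_se, ols,
                      genotypes.marker_map.copy())


def approx_pvalues(effects: SnpEffects, mode: str = "blup") -> np.ndarray:
    """Two-sided normal-tail p-values from per-marker z statistics.

    ``mode="blup"`` standardizes the analytic BLUP effect by its exact
    sampling SD (calibrated under the null); ``mode="posterior"``
    standardizes the posterior-mean effect by the posterior SD of the
    draws (conservative).  Markers whose SE is numerically zero get
    p = 1 (unidentified).
    """
    if mode == "posterior":
        est, se = effects.mean, effects.psd
    elif mode == "blup":
        est, se = effects.blup, effects.blup_se
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    p = np.ones_like(est)
    ok = se > 0
    z = np.zeros_like(p)
    z[ok] = est[ok] / se[ok]
    p[ok] = np.minimum(2.0 * norm.sf(np.abs(z[ok])), 1.0)
    p[ok] = np.maximum(p[ok], np.finfo(float).tiny)
    return p


def variance_explained(effect, p, total_variance) -> np.ndarray:
    """Fraction of variance explained: 2p(1-p) effect^2 / total.

    ``total_variance`` is the phenotypic variance by default convention;
    pass the additive variance for an additive-fraction scale.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic marker (p in {0,1}); run QC first")
    if not total_variance > 0:
        raise ValueError("total_variance must be positive")
    return 2.0 * p * (1.0 - p) * np.asarray(effect, float) ** 2 \
        / total_variance


def me_thresholds(marker_map: pd.DataFrame, ne: int = 100,
                  alpha: float = 0.05, cm_per_mb: float = 1.0,
                  log_base: str = "natural") -> ThresholdScheme:
    """Per-chromosome significance thresholds alpha / Me.

    Each chromosome's genetic length L (Morgans) is its bp span times
    the map-density conversion; Me = 2 Ne L / log(Ne L) with the natural
    log by default (``log_base="10"`` for a sensitivity check).
    """
    rows = []
    logf = np.log if log_base == "natural" else np.log10
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        span_bp = float(grp["pos_bp"].max() - grp["pos_bp"].min())
        if span_bp <= 0:
            raise ValueError(
                f"chromosome {chrom}: zero bp span (single marker?)")
        L = span_bp / 1e6 * cm_per_mb / 100.0  # Morgans
        nel = ne * L
        if nel <= 1:
            raise ValueError(f"chromosome {chrom}: Ne*L = {nel:.3g} <= 1")
        me = 2.0 * nel / logf(nel)
        rows.append({"chrom": str(chrom), "length_morgans": L,
                     "me": me, "threshold": alpha / me})
    return ThresholdScheme(ne, alpha, pd.DataFrame(rows), log_base)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: the median observed 1-df chi-square
    statistic over the null median (~0.455)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def candidate_windows(results: pd.DataFrame, flank_bp: int = 100_000
                      ) -> pd.DataFrame:
    """+-flank windows around significant markers, merged per chromosome.

    Expects a per-marker table with chrom, pos_bp and significant
    columns; returns half-open 0-based intervals [start, end) with
    starts clamped at 0, overlapping same-chromosome windows merged.
    """
    if flank_bp < 0:
        raise ValueError("flank must be non-negative")
    sig = results.loc[results["significant"]]
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        ivals = sorted(
            (max(0, int(pos) - flank_bp), int(pos) + flank_bp)
            for pos in grp["pos_bp"])
        merged = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rows.extend({"chrom": str(chrom), "start": s, "end": e}
                    for s, e in merged)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def windows_to_bed(windows: pd.DataFrame, path):
    windows.to_csv(path, sep="\t", header=False, index=False)


def run_gwas(fit: ModelFit, genotypes: GenotypeMatrix, grm: GRM,
             total_variance: float, trait: str | None = None,
             ne: int = 100, alpha: float = 0.05, cm_per_mb: float = 1.0,
             flank_bp: int = 100_000, p_mode: str = "blup",
             ) -> tuple[pd.DataFrame, ThresholdScheme, float, pd.DataFrame]:
    """Full per-marker GWAS table for one fitted trait.

    Returns (results, thresholds, lambda, candidate windows); results
    has one row per marker with the effect, its PSD, p-value, variance
    explained (phenotypic denominator), the chromosome-wise threshold
    and the significance flag.
    """
    eff = backsolve_snp_effects(fit, genotypes, grm, trait=trait)
    pvals = approx_pvalues(eff, mode=p_mode)
    scheme = me_thresholds(eff.marker_map, ne=ne, alpha=alpha,
                           cm_per_mb=cm_per_mb)
    thr_by_chrom = scheme.per_chromosome.set_index("chrom")["threshold"]
    thr = eff.marker_map["chrom"].astype(str).map(thr_by_chrom).to_numpy()
    res = eff.marker_map[["chrom", "marker", "pos_bp"]].copy()
    res["freq"] = eff.freqs
    res["effect"] = eff.mean
    res["effect_psd"] = eff.psd
    res["effect_unshrunk"] = eff.ols
    res["p_value"] = pvals
    res["variance_explained"] = variance_explained(
        eff.mean, eff.freqs, total_variance)
    res["threshold"] = thr
    res["significant"] = pvals < thr
    lam = genomic_inflation(pvals)
    windows = candidate_windows(res, flank_bp=flank_bp)
    return res, scheme, lam, windows
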