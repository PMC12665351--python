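"""Genomic relationship matrix (VanRaden method 1).

G = Z Z' / (2 Σ p_j (1 - p_j)), where Z is the dosage matrix centered at
twice the allele frequency (M - 2p) and the sum runs over markers.
Allele frequencies are computed from the analyzed sample; missing
dosages are mean-imputed at 2p before centering.  Because no pedigree is
available for blending, invertibility (required by the Gibbs sampler and
the GWAS back-solve) is guaranteed by an explicit blend with the
identity: G* = (1 - eps) G + eps I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GrmError
from .genotype_qc import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its provenance."""

    matrix: np.ndarray
    individual_ids: list
    allele_freqs: np.ndarray
    denom: float
    epsilon: float = 0.0  # identity-blend weight applied, 0 = raw

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise GrmError("G must be square")
        if len(self.individual_ids) != n:
            raise GrmError("id list length mismatch with G")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def centered_dosages(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean-imputed, centered dosage matrix Z = M - 2p with p from the
    sample; returns (Z, p, denom) with denom = 2 sum p(1-p)."""
    p = g.allele_freqs()
    if np.isnan(p).any():
        raise GrmError("markers with no non-missing call; run QC first")
    dos = g.dosages.copy()
    # mean imputation at 2p, the expected dosage under HWE
    miss = np.isnan(dos)
    if miss.any():
        dos[miss] = np.broadcast_to(2 * p, dos.shape)[miss]
    Z = dos - 2 * p
    denom = float(2 * np.sum(p * (1 - p)))
    return Z, p, denom


def vanraden_g(g: GenotypeMatrix) -> GRM:
    """Build the method-1 genomic relationship matrix from QC-passed
    genotypes.  Raises if the panel is entirely monomorphic."""
    Z, p, denom = centered_dosages(g)
    if denom <= 0:
        raise GrmError("all markers monomorphic: 2*sum(p(1-p)) = 0")
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GRM(G, list(g.individual_ids), p, denom)


def stabilize(grm: GRM, epsilon: float = 0.01) -> GRM:
    """Blend G with the identity: G* = (1-eps) G + eps I.

    Guarantees a positive-definite covariance kernel; eps is recorded in
    the result's provenance.
    """
    if not 0 <= epsilon <= 1:
        raise GrmError(f"epsilon must be in [0, 1], got {epsilon}")
    A = grm.matrix
    if not np.allclose(A, A.T, atol=1e-8):
        raise GrmError("G must be symmetric before stabilization")
    G = (1 - epsilon) * A + epsilon * np.eye(grm.n)
    return GRM(G, list(grm.individual_ids), grm.allele_freqs, grm.denom,
               epsilon=epsilon)


def relationship_distribution(grm: GRM, bins: int = 50) -> dict:
    """Summary of the off-diagonal relationship coefficients.

    Extracts the n(n-1)/2 upper-triangle values (diagonal excluded) and
    returns their mean, SD, quantiles and a histogram table.
    """
    n = grm.n
    if n < 2:
        raise GrmError("need at least 2 individuals for a distribution")
    iu = np.triu_indices(n, k=1)
    vals = grm.matrix[iu]
    counts, edges = np.histogram(vals, bins=bins)
    hist = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })
    qs = np.quantile(vals, [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    return {
        "n_pairs": int(vals.size),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "quantiles": dict(zip(["q01", "q05", "q25", "q50", "q75", "q95", "q99"],
                              map(float, qs))),
        "histogram": hist,
    }


def save_grm(grm: GRM, prefix):
    """Persist G as an .npz plus a plain-text id index."""
    np.savez(f"{prefix}.npz", matrix=grm.matrix, allele_freqs=grm.allele_freqs,
             denom=grm.denom, epsilon=grm.epsilon)
    pd.Series(grm.individual_ids, name="individual_id").to_csv(
        f"{prefix}.ids.csv", index=False)


def load_grm(prefix) -> GRM:
    dat = np.load(f"{prefix}.npz")
    ids = pd.read_csv(f"{prefix}.ids.csv")["individual_id"].astype(str).tolist()
    return GRM(dat["matrix"], ids, dat["allele_freqs"],
               float(dat["denom"]), float(dat["epsilon"]))
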