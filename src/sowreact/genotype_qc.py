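"""Genotype containers, PLINK-style text IO and chip quality control.

Genotypes are held as an individuals x markers dosage matrix with
entries in {0, 1, 2} counting copies of the marker's second (counted)
allele; missing calls are ``NaN``.  The QC stages mirror common SNP-chip
practice for a 50K porcine panel:

1. call rate < threshold (markers first, then individuals),
2. minor allele frequency < threshold,
3. |observed - expected (Hardy-Weinberg) heterozygosity| > threshold,
4. missing or duplicated genomic positions,
5. genotyped individuals without phenotypic records.

Each stage appends an entry to a :class:`QCReport` whose removal counts
reconcile exactly with the matrix dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QCError

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["chrom", "marker", "cm", "pos_bp"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix plus its marker map.

    ``dosages`` is float with entries in {0, 1, 2, NaN}; ``marker_map``
    is a DataFrame with columns chrom, marker, cm, pos_bp (and
    optionally allele1/allele2), aligned to the dosage columns.
    """

    dosages: np.ndarray
    individual_ids: list
    marker_map: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise QCError("dosages must be 2-D (individuals x markers)")
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise QCError("individual_ids length mismatch with dosage rows")
        if len(self.marker_map) != self.dosages.shape[1]:
            raise QCError("marker map length mismatch with dosage columns")
        self.marker_map = self.marker_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, keep],
            list(self.individual_ids),
            self.marker_map.loc[np.asarray(keep)].reset_index(drop=True),
        )

    def take_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        ids = [i for i, k in zip(self.individual_ids, keep) if k] \
            if np.asarray(keep).dtype == bool \
            else [self.individual_ids[i] for i in keep]
        return GenotypeMatrix(self.dosages[keep, :], ids, self.marker_map)

    def allele_freqs(self) -> np.ndarray:
        """Counted-allele frequency per marker from non-missing calls;
        NaN for markers with no call."""
        obs = (~np.isnan(self.dosages)).sum(axis=0)
        total = np.nansum(self.dosages, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, total / (2.0 * obs), np.nan)


@dataclass
class QCReport:
    """Append-only log of QC stages with exact removal bookkeeping."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, markers_removed: int, individuals_removed: int,
            g: GenotypeMatrix, detail: str = ""):
        self.stages.append({
            "stage": stage,
            "markers_removed": int(markers_removed),
            "individuals_removed": int(individuals_removed),
            "n_markers": g.n_markers,
            "n_individuals": g.n_individuals,
            "detail": detail,
        })
        logger.info("QC %s: -%d markers, -%d individuals -> %d x %d",
                    stage, markers_removed, individuals_removed,
                    g.n_individuals, g.n_markers)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=2)


def filter_call_rate(g: GenotypeMatrix, threshold: float = 0.90,
                     report: QCReport | None = None
                     ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers, then individuals, with call rate strictly below
    ``threshold`` (a call rate of exactly the threshold is retained)."""
    if not 0 < threshold <= 1:
        raise QCError(f"call-rate threshold must be in (0, 1], got {threshold}")
    report = report or QCReport()
    obs = ~np.isnan(g.dosages)
    keep_m = obs.mean(axis=0) >= threshold
    n_mark = int((~keep_m).sum())
    g = g.take_markers(keep_m)
    obs = ~np.isnan(g.dosages)
    if g.n_markers == 0:
        keep_i = np.ones(g.n_individuals, dtype=bool)
    else:
        keep_i = obs.mean(axis=1) >= threshold
    n_ind = int((~keep_i).sum())
    g = g.take_individuals(keep_i)
    if g.n_individuals == 0:
        raise QCError("call-rate filter removed all individuals")
    report.add("call_rate", n_mark, n_ind, g, f"threshold={threshold}")
    return g, report


def filter_maf(g: GenotypeMatrix, min_maf: float = 0.01,
               report: QCReport | None = None
               ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with minor allele frequency below ``min_maf``.

    Frequencies are computed from non-missing calls; markers with no
    non-missing call are removed with a distinct reason.
    """
    report = report or QCReport()
    n_obs = (~np.isnan(g.dosages)).sum(axis=0)
    all_missing = n_obs == 0
    p = np.where(all_missing, np.nan, g.allele_freqs())
    maf = np.minimum(p, 1 - p)
    keep = np.where(all_missing, False, maf >= min_maf)
    n_empty = int(all_missing.sum())
    n_mark = int((~keep).sum())
    g = g.take_markers(keep)
    report.add("maf", n_mark, 0, g,
               f"min_maf={min_maf}; {n_empty} with no non-missing call")
    return g, report


def filter_het_deviation(g: GenotypeMatrix, max_dev: float = 0.15,
                         report: QCReport | None = None
                         ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers whose observed heterozygosity deviates from the
    Hardy-Weinberg expectation 2p(1-p) by more than ``max_dev``
    (absolute deviation)."""
    report = report or QCReport()
    obs = ~np.isnan(g.dosages)
    p = g.allele_freqs()
    with np.errstate(invalid="ignore"):
        het_obs = np.nansum(g.dosages == 1, axis=0) / np.maximum(obs.sum(axis=0), 1)
    het_exp = 2 * p * (1 - p)
    keep = np.abs(het_obs - het_exp) <= max_dev
    keep = np.where(np.isnan(p), False, keep)
    n_mark = int((~keep).sum())
    g = g.take_markers(keep)
    report.add("het_deviation", n_mark, 0, g, f"max_dev={max_dev}")
    return g, report


def filter_positions(g: GenotypeMatrix, report: QCReport | None = None
                     ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with missing coordinates and, for duplicated
    (chromosome, position) pairs, all but the first in file order."""
    report = report or QCReport()
    mm = g.marker_map
    pos = pd.to_numeric(mm["pos_bp"], errors="coerce")
    has_pos = pos.notna() & (pos > 0) & mm["chrom"].notna()
    dup = mm.assign(pos_bp=pos).duplicated(subset=["chrom", "pos_bp"], keep="first")
    keep = (has_pos & ~dup).to_numpy()
    n_mark = int((~keep).sum())
    g = g.take_markers(keep)
    report.add("positions", n_mark, 0, g,
               "missing coordinates or duplicated (chrom, pos); first kept")
    return g, report


def drop_unphenotyped(g: GenotypeMatrix, phenotype_ids,
                      report: QCReport | None = None
                      ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove genotyped individuals absent from the phenotype id list.

    Matching is strict string equality; near-misses (e.g. whitespace
    variants) are logged as unmatched, never silently matched.
    """
    report = report or QCReport()
    pheno = set(str(i) for i in phenotype_ids)
    keep = np.array([str(i) in pheno for i in g.individual_ids])
    unmatched = [i for i, k in zip(g.individual_ids, keep) if not k]
    for i in unmatched[:20]:
        if str(i).strip() in pheno:
            logger.warning("id %r unmatched (whitespace variant of a "
                           "phenotyped id); not matched silently", i)
    if not keep.any():
        raise QCError("no genotyped individual has phenotypic records")
    n_ind = int((~keep).sum())
    g = g.take_individuals(keep)
    report.add("unphenotyped", 0, n_ind, g)
    return g, report


def run_qc(g: GenotypeMatrix, phenotype_ids=None, call_rate: float = 0.90,
           min_maf: float = 0.01, max_het_dev: float = 0.15
           ) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC in the standard order: call rate (markers then
    individuals) -> MAF -> heterozygosity deviation -> positions ->
    unphenotyped individuals."""
    report = QCReport()
    report.add("input", 0, 0, g)
    g, report = filter_call_rate(g, call_rate, report)
    g, report = filter_maf(g, min_maf, report)
    g, report = filter_het_deviation(g, max_het_dev, report)
    g, report = filter_positions(g, report)
    if phenotype_ids is not None:
        g, report = drop_unphenotyped(g, phenotype_ids, report)
    return g, report


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map) IO
#
# Dosages count copies of the marker's second observed allele (allele2);
# the allele coding is recorded in the marker map so it is explicit in
# downstream reports.


def read_plink_text(prefix) -> GenotypeMatrix:
    """Read a PLINK .ped/.map text file pair.

    ``prefix`` names the pair (``prefix.ped`` / ``prefix.map``).  The
    counted allele per marker is the second distinct allele observed in
    file order; "0 0" codes a missing call.
    """
    mm = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                     names=MAP_COLUMNS, dtype={"chrom": str})
    ids, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[1])
            rows.append(parts[6:])
    m = len(mm)
    allele1 = [None] * m
    allele2 = [None] * m
    dosages = np.full((len(rows), m), np.nan)
    for i, row in enumerate(rows):
        if len(row) != 2 * m:
            raise QCError(
                f"ped row {i} has {len(row)} allele fields, expected {2 * m}"
            )
        for j in range(m):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            for al in (a, b):
                if allele1[j] is None:
                    allele1[j] = al
                elif allele2[j] is None and al != allele1[j]:
                    allele2[j] = al
            dosages[i, j] = (a == allele2[j]) + (b == allele2[j]) \
                if allele2[j] is not None else 0.0
    mm["allele1"] = allele1
    mm["allele2"] = allele2
    return GenotypeMatrix(dosages, ids, mm)


def write_plink_text(g: GenotypeMatrix, prefix):
    """Write a GenotypeMatrix as a PLINK .ped/.map text pair."""
    mm = g.marker_map.copy()
    if "cm" not in mm:
        mm["cm"] = 0
    mm[MAP_COLUMNS].to_csv(f"{prefix}.map", sep="\t", header=False, index=False)
    a1 = mm["allele1"].tolist() if "allele1" in mm else ["A"] * g.n_markers
    a2 = mm["allele2"].tolist() if "allele2" in mm else ["B"] * g.n_markers
    a1 = ["A" if a is None else a for a in a1]
    a2 = ["B" if a is None else a for a in a2]
    with open(f"{prefix}.ped", "w") as fh:
        for i, iid in enumerate(g.individual_ids):
            fields = [str(iid), str(iid), "0", "0", "0", "-9"]
            for j in range(g.n_markers):
                d = g.dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_dosage_csv(path) -> GenotypeMatrix:
    """Read a dosage CSV: columns chrom, marker, pos_bp then one column
    per individual; rows are markers."""
    df = pd.read_csv(path, dtype={"chrom": str})
    meta = df[["chrom", "marker", "pos_bp"]].copy()
    meta["cm"] = 0.0
    ids = [c for c in df.columns if c not in ("chrom", "marker", "pos_bp")]
    dos = df[ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dos, ids, meta[MAP_COLUMNS])


def write_dosage_csv(g: GenotypeMatrix, path):
    df = g.marker_map[["chrom", "marker", "pos_bp"]].copy()
    for i, iid in enumerate(g.individual_ids):
        df[str(iid)] = g.dosages[i, :]
    df.to_csv(path, index=False)
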