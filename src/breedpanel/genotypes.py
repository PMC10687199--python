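"""Genotype container, PLINK-text/VCF input-output, and quality control.

The central object is :class:`GenotypeTable`: an ``n_samples x n_loci``
matrix of alternate-allele dosages (0, 1, 2, or missing) plus sample and
locus metadata.  Every analysis module in the package consumes this type.

Orientation convention: the *alternate* allele at each locus is the pooled
minor allele at read time (ties broken toward the lexicographically later
allele), so dosage is the minor-allele count.  The chosen orientation is
stored in the locus metadata and preserved on write, making downstream
allele frequencies reproducible regardless of input file ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in the dosage matrix.
MISSING: int = -1

_VALID_ALLELES = {"A", "C", "G", "T"}


class GenotypeParseError(ValueError):
    """Raised when an input file violates the expected genotype format."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    population: str


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chromosome: str = "0"
    position: int = 0
    allele_ref: str = "A"
    allele_alt: str = "B"


@dataclass
class GenotypeTable:
    """Diploid biallelic genotypes for a set of labelled individuals.

    Parameters
    ----------
    samples : list of Sample
        One entry per row of ``dosages``; population labels must be non-empty.
    loci : list of Locus
        One entry per column of ``dosages``.
    dosages : ndarray of int
        Counts of the alternate allele, entries in {0, 1, 2, MISSING}.
    """

    samples: list[Sample]
    loci: list[Locus]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, L = self.dosages.shape
        if n != len(self.samples) or L != len(self.loci):
            raise ValueError(
                f"dosage matrix is {n}x{L} but metadata describe "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid dosage {self.dosages[i, j]} at sample {i}, locus {j}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise ValueError("duplicate locus ids")
        if any(not s.population for s in self.samples):
            raise ValueError("every sample needs a non-empty population label")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    @property
    def population_labels(self) -> np.ndarray:
        return np.asarray([s.population for s in self.samples])

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing entries as NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        locus_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeTable":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeTable(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            dosages=self.dosages[np.ix_(si, li)],
        )

    def subset_loci_by_id(self, locus_ids: Iterable[str]) -> "GenotypeTable":
        wanted = set(locus_ids)
        idx = [j for j, l in enumerate(self.loci) if l.locus_id in wanted]
        missing = wanted - {self.loci[j].locus_id for j in idx}
        if missing:
            raise KeyError(f"loci not present in table: {sorted(missing)}")
        return self.subset(locus_idx=idx)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.dosages, other.dosages)
        )


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def read_plink(ped_path: str | Path, map_path: str | Path) -> GenotypeTable:
    """Read whitespace-delimited PLINK .ped/.map files.

    The .ped family ID column is used as the population label.  ``0 0``
    allele pairs become missing.  The alternate allele is the pooled minor
    allele (tie broken toward the lexicographically later allele).
    """
    loci_meta = _read_map(map_path)
    L = len(loci_meta)

    samples: list[Sample] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * L:
                raise GenotypeParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * L} columns "
                    f"(6 + 2x{L} genotype alleles), found {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            samples.append(Sample(sample_id=iid, population=fid))
            allele_rows.append(fields[6:])

    n = len(samples)
    a1 = np.empty((n, L), dtype="U1")
    a2 = np.empty((n, L), dtype="U1")
    for i, row in enumerate(allele_rows):
        a1[i] = row[0::2]
        a2[i] = row[1::2]

    dosages = np.zeros((n, L), dtype=np.int8)
    loci: list[Locus] = []
    for j in range(L):
        col1, col2 = a1[:, j], a2[:, j]
        miss = (col1 == "0") | (col2 == "0")
        if ((col1 == "0") != (col2 == "0")).any():
            raise GenotypeParseError(
                f"locus {loci_meta[j].locus_id}: half-missing genotype (one allele '0')"
            )
        present = np.concatenate([col1[~miss], col2[~miss]])
        alleles = sorted(set(present))
        if any(a not in _VALID_ALLELES for a in alleles):
            bad = [a for a in alleles if a not in _VALID_ALLELES]
            raise GenotypeParseError(f"locus {loci_meta[j].locus_id}: invalid allele(s) {bad}")
        if len(alleles) > 2:
            raise GenotypeParseError(
                f"locus {loci_meta[j].locus_id}: >2 alleles observed: {alleles}"
            )
        ref, alt = _orient_alleles(present, alleles)
        loci.append(replace(loci_meta[j], allele_ref=ref, allele_alt=alt))
        dcol = (col1 == alt).astype(np.int8) + (col2 == alt).astype(np.int8)
        dcol[miss] = MISSING
        dosages[:, j] = dcol

    return GenotypeTable(samples=samples, loci=loci, dosages=dosages)


def _read_map(map_path: str | Path) -> list[Locus]:
    loci: list[Locus] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise GenotypeParseError(
                    f"{map_path} line {lineno}: expected 4 columns, found {len(fields)}"
                )
            chrom, lid, _cm, pos = fields
            loci.append(Locus(locus_id=lid, chromosome=chrom, position=int(pos)))
    return loci


def _orient_alleles(present: np.ndarray, alleles: list[str]) -> tuple[str, str]:
    """Return (ref, alt) with alt = pooled minor allele, tie -> later allele."""
    if len(alleles) == 0:
        return "A", "B"  # fully missing column; arbitrary placeholder
    if len(alleles) == 1:
        return alleles[0], alleles[0]
    x, y = alleles  # lexicographic order, x < y
    cx = int((present == x).sum())
    cy = int((present == y).sum())
    if cx < cy:
        return y, x
    if cy < cx:
        return x, y
    return x, y  # tie: later allele (y) is alt


def write_plink(table: GenotypeTable, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PLINK text files; inverse of :func:`read_plink` up to orientation."""
    with open(map_path, "w") as fh:
        for l in table.loci:
            fh.write(f"{l.chromosome}\t{l.locus_id}\t0\t{l.position}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(table.samples):
            fields = [s.population, s.sample_id, "0", "0", "0", "-9"]
            for j, l in enumerate(table.loci):
                d = table.dosages[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [l.allele_ref, l.allele_ref]
                elif d == 1:
                    fields += [l.allele_ref, l.allele_alt]
                else:
                    fields += [l.allele_alt, l.allele_alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    vcf_path: str | Path,
    population_map: Mapping[str, str],
    skip_multiallelic: bool = True,
) -> GenotypeTable:
    """Read a VCF (v4.x) via cyvcf2; GT is mapped to alt-dosage directly.

    Dosage follows the file's REF/ALT orientation (no minor-allele re-flip:
    the writer records orientation explicitly, so round-trips are exact).
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    absent = [s for s in vcf_samples if s not in population_map]
    if absent:
        raise GenotypeParseError(f"samples missing from population_map: {absent}")
    samples = [Sample(sample_id=s, population=population_map[s]) for s in vcf_samples]

    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if skip_multiallelic:
                continue
            raise GenotypeParseError(
                f"record {rec.CHROM}:{rec.POS}: not a biallelic SNP (ALT={rec.ALT})"
            )
        lid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        loci.append(
            Locus(
                locus_id=lid,
                chromosome=str(rec.CHROM),
                position=int(rec.POS),
                allele_ref=rec.REF,
                allele_alt=rec.ALT[0],
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(col.astype(np.int8))

    if not cols:
        raise GenotypeParseError(f"{vcf_path}: no usable biallelic SNP records")
    return GenotypeTable(samples=samples, loci=loci, dosages=np.column_stack(cols))


def write_vcf(table: GenotypeTable, vcf_path: str | Path) -> None:
    """Write an uncompressed VCF v4.2 with GT-only records."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedpanel\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, l in enumerate(table.loci):
            ref = l.allele_ref if l.allele_ref in _VALID_ALLELES else "A"
            alt = l.allele_alt if l.allele_alt in _VALID_ALLELES else "C"
            if ref == alt:  # monomorphic column: keep a syntactically valid ALT
                alt = "C" if ref != "C" else "G"
            gts = "\t".join(gt_str[int(d)] for d in table.dosages[:, j])
            fh.write(
                f"{l.chromosome or '1'}\t{max(l.position, 1)}\t{l.locus_id}\t"
                f"{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCConfig:
    """Thresholds for the single-pass QC filter chain.

    Filters run in a fixed order: SNP call rate, pooled MAF, sample call
    rate, IBS pruning.  Each can be disabled independently.
    """

    min_snp_callrate: float = 0.99
    min_maf: float = 0.05
    min_sample_callrate: float = 0.99
    max_ibs: float = 0.95
    filter_snp_callrate: bool = True
    filter_maf: bool = True
    filter_sample_callrate: bool = True
    filter_ibs: bool = True

    def __post_init__(self) -> None:
        for name in ("min_snp_callrate", "min_maf", "min_sample_callrate", "max_ibs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QCReport:
    filter_order: list[str] = field(
        default_factory=lambda: ["snp_callrate", "maf", "sample_callrate", "ibs"]
    )
    snps_removed_callrate: list[str] = field(default_factory=list)
    snps_removed_maf: list[str] = field(default_factory=list)
    samples_removed_callrate: list[str] = field(default_factory=list)
    samples_removed_ibs: list[str] = field(default_factory=list)

    @property
    def n_snps_removed(self) -> int:
        return len(self.snps_removed_callrate) + len(self.snps_removed_maf)

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed_callrate) + len(self.samples_removed_ibs)

    def to_dict(self) -> dict:
        return {
            "filter_order": self.filter_order,
            "snps_removed_callrate": {
                "count": len(self.snps_removed_callrate),
                "ids": self.snps_removed_callrate,
            },
            "snps_removed_maf": {
                "count": len(self.snps_removed_maf),
                "ids": self.snps_removed_maf,
            },
            "samples_removed_callrate": {
                "count": len(self.samples_removed_callrate),
                "ids": self.samples_removed_callrate,
            },
            "samples_removed_ibs": {
                "count": len(self.samples_removed_ibs),
                "ids": self.samples_removed_ibs,
            },
        }


def ibs_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise identity-by-state: mean allele sharing over shared typed loci.

    IBS(i,j) = mean over loci typed in both of (2 - |d_i - d_j|)/2.  A pair
    with no shared typed loci gets NaN.  Symmetric with unit diagonal, and
    invariant to which allele is called alt (|d_i - d_j| is flip-invariant).
    """
    if table.n_samples < 2:
        raise ValueError("IBS needs at least 2 samples")
    d = table.dosages_float()
    n = table.n_samples
    out = np.ones((n, n))
    typed = ~np.isnan(d)
    for i in range(n):
        for j in range(i + 1, n):
            shared = typed[i] & typed[j]
            if not shared.any():
                out[i, j] = out[j, i] = np.nan
                continue
            sim = 1.0 - np.abs(d[i, shared] - d[j, shared]) / 2.0
            out[i, j] = out[j, i] = sim.mean()
    return out


def apply_qc(table: GenotypeTable, config: QCConfig | None = None) -> tuple[GenotypeTable, QCReport]:
    """Apply the QC filter chain; returns the filtered table and a report.

    Order: SNP call rate >= min_snp_callrate, pooled MAF >= min_maf (missing
    genotypes excluded), sample call rate >= min_sample_callrate, then IBS
    pruning (for each pair above max_ibs the member with the lower call rate
    is dropped; ties drop the later sample).
    """
    config = config or QCConfig()
    report = QCReport()
    t = table

    if config.filter_snp_callrate:
        callrate = 1.0 - t.missing_mask().mean(axis=0)
        keep = callrate >= config.min_snp_callrate
        report.snps_removed_callrate = [t.loci[j].locus_id for j in np.flatnonzero(~keep)]
        t = _require_nonempty(t.subset(locus_idx=np.flatnonzero(keep)), "SNP call-rate")

    if config.filter_maf:
        maf = pooled_maf(t)
        keep = maf >= config.min_maf
        report.snps_removed_maf = [t.loci[j].locus_id for j in np.flatnonzero(~keep)]
        t = _require_nonempty(t.subset(locus_idx=np.flatnonzero(keep)), "MAF")

    if config.filter_sample_callrate:
        callrate = 1.0 - t.missing_mask().mean(axis=1)
        keep = callrate >= config.min_sample_callrate
        report.samples_removed_callrate = [t.samples[i].sample_id for i in np.flatnonzero(~keep)]
        t = _require_nonempty(t.subset(sample_idx=np.flatnonzero(keep)), "sample call-rate")

    if config.filter_ibs and t.n_samples >= 2:
        ibs = ibs_matrix(t)
        callrate = 1.0 - t.missing_mask().mean(axis=1)
        drop: set[int] = set()
        n = t.n_samples
        for i in range(n):
            if i in drop:
                continue
            for j in range(i + 1, n):
                if j in drop or np.isnan(ibs[i, j]) or ibs[i, j] <= config.max_ibs:
                    continue
                # drop the lower-call-rate member; tie -> later index
                victim = j if callrate[j] <= callrate[i] else i
                drop.add(victim)
                if victim == i:
                    break
        report.samples_removed_ibs = [t.samples[i].sample_id for i in sorted(drop)]
        keep_idx = [i for i in range(n) if i not in drop]
        t = _require_nonempty(t.subset(sample_idx=keep_idx), "IBS pruning")

    return t, report


def pooled_maf(table: GenotypeTable) -> np.ndarray:
    """Minor-allele frequency per locus over all samples, missing excluded."""
    d = table.dosages_float()
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * np.sum(~np.isnan(d), axis=0))
    return np.fmin(p, 1.0 - p)


def _require_nonempty(t: GenotypeTable, stage: str) -> GenotypeTable:
    if t.n_loci == 0 or t.n_samples == 0:
        raise ValueError(
            f"QC stage '{stage}' removed everything; review thresholds"
        )
    return t
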