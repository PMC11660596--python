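"""Readers, writers and simple variant filters.

Everything downstream of this module consumes in-memory domain types only:
:class:`VariantTable` + :class:`PhasedGenotypes` for genotypes,
:class:`PhenotypeTable` for trait/covariate data and :class:`GeneticMap`
for recombination distances.  VCF input must be phased ("|" separator for
heterozygous genotypes); this module refuses to impute or re-phase.

Coordinate conventions: VCF and GTF positions are 1-based inclusive;
internal variant ordinals are dense and 0-based per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:  # cyvcf2 is the VCF backend; import guarded so pure-array use works anywhere
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "PhasedGenotypes",
    "PhenotypeTable",
    "GeneticMap",
    "read_phased_vcf",
    "write_phased_vcf",
    "filter_variants",
    "phasing_concordance",
]


@dataclass
class VariantTable:
    """Ordered biallelic variants.

    Positions must be strictly increasing within each chromosome; variants
    of one chromosome are stored contiguously.
    """

    chrom: np.ndarray  # object/str, length M
    pos: np.ndarray  # int64, 1-based bp
    ref: np.ndarray  # single-base strings
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        for c, sl in self.chrom_slices().items():
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of variant ordinals per chromosome."""
        out: dict[str, slice] = {}
        if len(self.chrom) == 0:
            return out
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                c = self.chrom[start]
                if c in out:
                    raise ValueError(f"chromosome {c} not contiguous")
                out[c] = slice(start, i)
                start = i
        return out

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask])


@dataclass
class PhasedGenotypes:
    """Two haplotype vectors (0/1 alt-allele indicators) per sample."""

    samples: list[str]
    haps: np.ndarray  # uint8, shape (n_samples, 2, n_variants)

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise ValueError("haps must have shape (n_samples, 2, n_variants)")
        if self.haps.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch")
        if self.haps.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.haps.shape[2]

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix, shape (n_samples, n_variants), values 0/1/2."""
        return self.haps.sum(axis=1, dtype=np.int8)

    def subset_variants(self, mask: np.ndarray) -> "PhasedGenotypes":
        return PhasedGenotypes(list(self.samples), self.haps[:, :, mask])

    def subset_samples(self, ids: Sequence[str]) -> "PhasedGenotypes":
        idx = [self.samples.index(s) for s in ids]
        return PhasedGenotypes(list(ids), self.haps[idx])


@dataclass
class PhenotypeTable:
    """One continuous trait (e.g. body weight in grams) with sex and batch factors."""

    ids: list[str]
    trait: np.ndarray
    sex: np.ndarray  # factor labels
    batch: np.ndarray

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("phenotype ids must be unique")
        n = len(self.ids)
        if not (len(self.trait) == len(self.sex) == len(self.batch) == n):
            raise ValueError("phenotype columns must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "trait": self.trait, "sex": self.sex, "batch": self.batch}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "sex": str, "batch": str})
        return cls(list(df["id"]), df["trait"].to_numpy(), df["sex"].to_numpy(), df["batch"].to_numpy())

    def reorder(self, ids: Sequence[str]) -> "PhenotypeTable":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return PhenotypeTable(list(ids), self.trait[idx], self.sex[idx], self.batch[idx])

    def covariate_design(self) -> np.ndarray:
        """Intercept + sex + batch dummy design matrix Q (reference levels dropped)."""
        n = len(self.ids)
        cols = [np.ones(n)]
        for fac in (self.sex, self.batch):
            levels = sorted(set(fac))
            for lv in levels[1:]:
                cols.append((fac == lv).astype(float))
        return np.column_stack(cols)


@dataclass
class GeneticMap:
    """Physical-to-genetic coordinate map (non-decreasing cM within chromosome)."""

    chrom: np.ndarray
    pos: np.ndarray  # bp
    cm: np.ndarray
    cm_female: np.ndarray | None = None
    cm_male: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom == c
            if np.any(np.diff(self.cm[m]) < 0):
                raise ValueError(f"cM positions decrease on {c}")

    def cm_at(self, chrom: str, pos_bp: np.ndarray) -> np.ndarray:
        m = self.chrom == chrom
        if not m.any():
            raise KeyError(f"chromosome {chrom} absent from genetic map")
        return np.interp(np.asarray(pos_bp, dtype=float), self.pos[m].astype(float), self.cm[m])

    def length_cm(self, chrom: str) -> float:
        m = self.chrom == chrom
        return float(self.cm[m].max() - self.cm[m].min())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "cM": self.cm}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(), df["cM"].to_numpy())


def read_phased_vcf(path: str | Path, region: str | None = None) -> tuple[VariantTable, PhasedGenotypes]:
    """Read a phased VCF into a variant table and haplotype matrix.

    Multi-allelic records are skipped (count logged).  A heterozygous
    genotype written unphased ("0/1") or a missing genotype raises, naming
    the offending sample and site — this loader never imputes.  Homozygous
    genotypes carry no phase information and are accepted either way.
    """
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    vcf = _CyVCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    hap_cols: list[np.ndarray] = []
    n_multi = 0
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty((len(samples), 2), dtype=np.int16)
        for si, g in enumerate(gts):
            a0, a1, phased = g[0], g[1], g[2]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype for sample {samples[si]} at {var.CHROM}:{var.POS}"
                )
            if a0 != a1 and not phased:
                raise ValueError(
                    f"unphased heterozygous genotype for sample {samples[si]} "
                    f"at {var.CHROM}:{var.POS}"
                )
            col[si, 0], col[si, 1] = a0, a1
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        hap_cols.append(col)
    if n_multi:
        logger.info("skipped %d multi-allelic sites", n_multi)
    if not poss:
        raise ValueError(f"no biallelic variants read from {path}")
    haps = np.stack(hap_cols, axis=2).astype(np.uint8)  # (samples, 2, M)
    vt = VariantTable(np.array(chroms, dtype=object), np.array(poss), np.array(refs, dtype=object), np.array(alts, dtype=object))
    return vt, PhasedGenotypes(samples, haps)


def write_phased_vcf(path: str | Path, vt: VariantTable, pg: PhasedGenotypes) -> None:
    """Write a minimal uncompressed VCF 4.2 with phased GT for all samples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, sl in vt.chrom_slices().items():
            fh.write(f"##contig=<ID={c},length={int(vt.pos[sl].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pg.samples) + "\n")
        for m in range(vt.n_variants):
            gts = "\t".join(f"{pg.haps[s, 0, m]}|{pg.haps[s, 1, m]}" for s in range(pg.n_samples))
            fh.write(
                f"{vt.chrom[m]}\t{vt.pos[m]}\t{vt.chrom[m]}_{vt.pos[m]}\t{vt.ref[m]}\t{vt.alt[m]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_variants(
    vt: VariantTable,
    pg: PhasedGenotypes,
    maf_min: float = 0.01,
    max_missing: float = 0.2,
) -> tuple[VariantTable, PhasedGenotypes]:
    """Keep sites with minor allele frequency strictly above ``maf_min``.

    The strict ">" mirrors the usual "MAF > 0.01" filter convention, so
    ``maf_min=0`` still removes monomorphic sites.  Phased post-imputation
    data carries no missingness; ``max_missing`` is retained in the
    signature for raw-table workflows and is a no-op here.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    freq = pg.haps.mean(axis=(0, 1))
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError("all sites removed by MAF filter")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("MAF filter removed %d of %d sites", n_drop, len(keep))
    return vt.subset(keep), pg.subset_variants(keep)


def phasing_concordance(a: PhasedGenotypes, b: PhasedGenotypes) -> float:
    """Fraction of heterozygous genotypes phased identically by two tools.

    The two haplotypes of a sample have no intrinsic labels, so for each
    sample the orientation (hap1↔hap1 or hap1↔hap2) maximizing agreement
    across its heterozygous sites is chosen before scoring.  Only sites
    heterozygous in both inputs are scored.
    """
    if a.samples != b.samples:
        raise ValueError("sample sets differ")
    if a.n_variants != b.n_variants:
        raise ValueError("variant sets differ")
    n_con = 0
    n_tot = 0
    for s in range(a.n_samples):
        het = (a.haps[s, 0] != a.haps[s, 1]) & (b.haps[s, 0] != b.haps[s, 1])
        n = int(het.sum())
        if n == 0:
            continue
        same = int((a.haps[s, 0, het] == b.haps[s, 0, het]).sum())
        n_con += max(same, n - same)
        n_tot += n
    if n_tot == 0:
        raise ValueError("no heterozygous sites to score")
    return n_con / n_tot
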