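"""Partition the genome into fixed-width SNP windows ("haplotype blocks").

A block of *w* consecutive SNPs is treated as one multi-allelic locus whose
alleles are the distinct haplotype strings observed in the block (written in
REF/ALT bases, e.g. "TTAGG").  The default width of five SNPs corresponds to
the physical distance over which linkage disequilibrium decays to r² ≈ 0.1
in a late-generation intercross.  Trailing SNPs that do not fill a block are
dropped so all blocks carry the same degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PhasedGenotypes, VariantTable

logger = logging.getLogger(__name__)

__all__ = ["HaplotypeBlockSet", "HaplotypeSpectrum", "build_blocks", "spectrum"]


@dataclass
class HaplotypeBlockSet:
    """Non-overlapping SNP windows with per-block allele catalogs.

    ``assignments[b, s, h]`` is the catalog index of haplotype *h* of sample
    *s* in block *b*; ``catalogs[b]`` lists the distinct haplotype strings
    of block *b* in order of first appearance.
    """

    block_size: int
    samples: list[str]
    table: pd.DataFrame  # chrom, block_id, start_idx, end_idx, start_bp, end_bp
    catalogs: list[list[str]]
    assignments: np.ndarray  # (n_blocks, n_samples, 2) int32

    @property
    def n_blocks(self) -> int:
        return len(self.catalogs)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def block_index(self, chrom: str, block_id: int) -> int:
        hit = self.table.index[(self.table["chrom"] == chrom) & (self.table["block_id"] == block_id)]
        if len(hit) != 1:
            raise KeyError(f"block {chrom}:{block_id} not found")
        return int(hit[0])

    def allele_counts(self, b: int, sample_idx: Sequence[int] | None = None) -> np.ndarray:
        """Counts per catalog allele over the 2·n haplotypes of the chosen samples."""
        a = self.assignments[b] if sample_idx is None else self.assignments[b][list(sample_idx)]
        return np.bincount(a.ravel(), minlength=len(self.catalogs[b]))

    def subset_samples(self, ids: Sequence[str]) -> "HaplotypeBlockSet":
        idx = [self.samples.index(s) for s in ids]
        return HaplotypeBlockSet(
            self.block_size, list(ids), self.table, self.catalogs, self.assignments[:, idx, :]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["n_alleles"] = [len(c) for c in self.catalogs]
        df["catalog"] = [",".join(c) for c in self.catalogs]
        df.to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeSpectrum:
    """Per-block haplotype-allele counts for one population.

    ``counts[b]`` maps allele string → count over the 2·n haplotypes of the
    population; frequencies are exposed sorted descending, as required by
    pooled-homozygosity statistics (p₁ ≥ p₂ ≥ …, Σpᵢ = 1).
    """

    samples: list[str]
    counts: list[dict[str, int]]

    @property
    def n_blocks(self) -> int:
        return len(self.counts)

    def freqs(self, b: int) -> np.ndarray:
        c = np.array(sorted(self.counts[b].values(), reverse=True), dtype=float)
        return c / c.sum()

    def alleles(self, b: int) -> set[str]:
        return set(self.counts[b])


def build_blocks(vt: VariantTable, pg: PhasedGenotypes, block_size: int = 5) -> HaplotypeBlockSet:
    """Tile each chromosome with ⌊M/block_size⌋ non-overlapping blocks.

    Haplotype strings are spelled in REF/ALT bases.  Chromosomes with fewer
    SNPs than one block contribute no blocks (warned); the trailing
    remainder of every chromosome is dropped (logged).
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    rows = []
    catalogs: list[list[str]] = []
    assign_list: list[np.ndarray] = []
    bases = np.stack([vt.ref, vt.alt], axis=1)  # (M, 2)
    for chrom, sl in vt.chrom_slices().items():
        m = sl.stop - sl.start
        nb = m // block_size
        if nb == 0:
            logger.warning("chromosome %s has %d < %d SNPs: no blocks", chrom, m, block_size)
            continue
        dropped = m - nb * block_size
        if dropped:
            logger.info("chromosome %s: dropped %d trailing SNPs", chrom, dropped)
        for b in range(nb):
            i0 = sl.start + b * block_size
            i1 = i0 + block_size - 1
            sub = pg.haps[:, :, i0 : i1 + 1]  # (N, 2, w)
            blk_bases = bases[i0 : i1 + 1]  # (w, 2)
            flat = sub.reshape(-1, block_size)
            strings = ["".join(blk_bases[j, al] for j, al in enumerate(row)) for row in flat]
            catalog: list[str] = []
            index: dict[str, int] = {}
            codes = np.empty(len(strings), dtype=np.int32)
            for k, s in enumerate(strings):
                if s not in index:
                    index[s] = len(catalog)
                    catalog.append(s)
                codes[k] = index[s]
            rows.append(
                dict(
                    chrom=chrom,
                    block_id=b,
                    start_idx=i0,
                    end_idx=i1,
                    start_bp=int(vt.pos[i0]),
                    end_bp=int(vt.pos[i1]),
                )
            )
            catalogs.append(catalog)
            assign_list.append(codes.reshape(pg.n_samples, 2))
    if not rows:
        raise ValueError("no chromosome had enough SNPs to form a block")
    table = pd.DataFrame(rows)
    return HaplotypeBlockSet(
        block_size, list(pg.samples), table, catalogs, np.stack(assign_list, axis=0)
    )


def spectrum(hbs: HaplotypeBlockSet, population: Iterable[str]) -> HaplotypeSpectrum:
    """Per-block allele frequency spectrum over the haplotypes of a population."""
    pop = list(population)
    if not pop:
        raise ValueError("empty population")
    missing = [s for s in pop if s not in hbs.samples]
    if missing:
        raise KeyError(f"samples not in block set: {missing[:5]}")
    idx = [hbs.samples.index(s) for s in pop]
    counts: list[dict[str, int]] = []
    for b in range(hbs.n_blocks):
        c = hbs.allele_counts(b, idx)
        counts.append({hbs.catalogs[b][k]: int(c[k]) for k in np.nonzero(c)[0]})
    return HaplotypeSpectrum(pop, counts)
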