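"""Synthetic advanced-intercross-line (AIL) generator with known truth.

The generator emulates the study design the rest of the package analyzes:
two founder chicken lines with small, partially shared haplotype pools
(HQLA, the heavy line, origin code 1; HB, the light line, origin code 0),
an F1 cross followed by generations of random intercrossing with
recombination (no mutation, no selection), and a quantitative trait built
from sex and batch effects, origin-dependent additive block effects,
planted dominance loci, a polygenic term drawn with SNP-GRM covariance and
Gaussian noise.  Every F9 haplotype carries a per-SNP record of its founder
population of descent, so block-level local-ancestry truth is exact by
construction.

Founder haplotypes are drawn from per-population pools of a few distinct
chromosome haplotypes rather than from a coalescent: this reproduces the
low within-line diversity and strong block-level differentiation of real
divergent lines at desk scale.  Mating uses balanced pair contributions
(each breeding pair leaves the same number of offspring), the standard AIL
maintenance design that maximizes effective population size and keeps
genome-wide ancestry near 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlockSet, build_blocks
from .io import GeneticMap, PhasedGenotypes, PhenotypeTable, VariantTable, write_phased_vcf

__all__ = [
    "ChromosomeSpec",
    "CausalBlock",
    "DominanceBlock",
    "SimConfig",
    "SimResult",
    "simulate_founders",
    "gene_drop",
    "simulate_phenotype",
    "simulate_ail",
]

HB, HQLA = 0, 1
_BASES = np.array(list("ACGT"))


@dataclass
class ChromosomeSpec:
    name: str
    n_snps: int
    length_cm: float


@dataclass
class CausalBlock:
    """Additive per-copy effects keyed by (allele string or "*", origin or "*")."""

    chrom: str
    block_id: int
    effects: dict = field(default_factory=dict)  # (allele, origin) -> grams per copy

    def effect_of(self, allele: str, origin: int) -> float:
        for key in ((allele, origin), ("*", origin), (allele, "*"), ("*", "*")):
            if key in self.effects:
                return float(self.effects[key])
        return 0.0


@dataclass
class DominanceBlock:
    """Ancestral-heterozygote bonus (grams) added when the diploid code is 1."""

    chrom: str
    block_id: int
    het_bonus: float


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic AIL.

    Defaults mirror the emulated design: 16 HQLA + 14 HB founders, pools of
    8 distinct chromosome haplotypes per line sharing a third of their
    alleles, nine generations to F9 with 585 final individuals, body-weight
    scale trait (grams) with sex and batch effects and heritability around
    0.4 (σ²_g = 6400, σ²_e = 10000).  Intermediate generations keep 200
    breeding individuals, on the order of the genotyped parental
    generation of such designs.
    """

    seed: int = 0
    chromosomes: list[ChromosomeSpec] = field(
        default_factory=lambda: [ChromosomeSpec("chr1", 200, 100.0), ChromosomeSpec("chr2", 200, 100.0)]
    )
    n_founders: tuple[int, int] = (16, 14)  # (HQLA, HB)
    pool_size: int = 8
    sharing: float = 0.33
    generations: int = 9
    f9_size: int = 585
    gen_size: int = 200
    block_size: int = 5
    trait_mean: float = 1000.0
    sex_effect: float = 150.0  # added for males
    batch_effects: tuple[float, ...] = (0.0, 20.0, -20.0)
    causal_blocks: list[CausalBlock] = field(default_factory=list)
    dominance_blocks: list[DominanceBlock] = field(default_factory=list)
    sigma_g2: float = 6400.0
    sigma_e2: float = 10000.0

    def __post_init__(self) -> None:
        if not 0 <= self.sharing <= 1:
            raise ValueError("sharing fraction must lie in [0, 1]")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class Founders:
    vt: VariantTable
    gmap: GeneticMap
    genotypes: PhasedGenotypes  # all founders, HQLA first
    hqla_ids: list[str]
    hb_ids: list[str]
    origins: np.ndarray  # (N, 2, M) founder population of each SNP (constant per founder)
    pools: dict  # chrom -> (hqla_pool, hb_pool) arrays (pool_size, m)


@dataclass
class SimResult:
    cfg: SimConfig
    vt: VariantTable
    gmap: GeneticMap
    founders: Founders
    f9: PhasedGenotypes
    f9_origins: np.ndarray  # (N, 2, M) per-SNP origin of descent
    hbs: HaplotypeBlockSet  # blocks over the F9 genotypes
    truth_origin: np.ndarray  # (n_blocks, N, 2) block-level origin truth
    phenotypes: PhenotypeTable
    components: pd.DataFrame  # genetic-value decomposition per F9 individual
    pedigree: pd.DataFrame

    def combined_genotypes(self) -> PhasedGenotypes:
        """Founders and F9 in one matrix (for joint block catalogs / panels)."""
        return PhasedGenotypes(
            list(self.founders.genotypes.samples) + list(self.f9.samples),
            np.concatenate([self.founders.genotypes.haps, self.f9.haps], axis=0),
        )

    def combined_blocks(self) -> HaplotypeBlockSet:
        return build_blocks(self.vt, self.combined_genotypes(), self.cfg.block_size)

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset as plain-text files (VCF, TSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_phased_vcf(out / "f0.vcf", self.vt, self.founders.genotypes)
        write_phased_vcf(out / "f9.vcf", self.vt, self.f9)
        write_phased_vcf(out / "all.vcf", self.vt, self.combined_genotypes())
        self.gmap.to_tsv(out / "map.tsv")
        self.phenotypes.to_tsv(out / "phenotypes.tsv")
        self.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        rows = []
        for b in range(self.truth_origin.shape[0]):
            for s, smp in enumerate(self.f9.samples):
                rows.append(
                    (
                        self.hbs.table["chrom"].iat[b],
                        int(self.hbs.table["block_id"].iat[b]),
                        smp,
                        int(self.truth_origin[b, s, 0]),
                        int(self.truth_origin[b, s, 1]),
                    )
                )
        pd.DataFrame(rows, columns=["chrom", "block_id", "sample", "origin_hap1", "origin_hap2"]).to_csv(
            out / "truth_origins.tsv", sep="\t", index=False
        )
        self.components.to_csv(out / "truth_components.tsv", sep="\t", index=False)
        (out / "panel_hqla.txt").write_text("\n".join(self.founders.hqla_ids) + "\n")
        (out / "panel_hb.txt").write_text("\n".join(self.founders.hb_ids) + "\n")


def simulate_founders(cfg: SimConfig, rng: np.random.Generator) -> Founders:
    """Draw founder genotypes from partially shared per-population haplotype pools.

    Per chromosome, SNP alt-allele frequencies come from a U-shaped
    Beta(0.5, 0.5) prior; the two pools share ``round(sharing·pool_size)``
    haplotypes.  Each founder chromosome is a uniform draw from its
    population's pool.
    """
    if cfg.pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    chroms, poss, refs, alts = [], [], [], []
    map_rows = []
    pools: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_shared = int(round(cfg.sharing * cfg.pool_size))
    for spec in cfg.chromosomes:
        m = spec.n_snps
        pos = 5000 * np.arange(1, m + 1)
        q = rng.beta(0.5, 0.5, size=m)
        n_distinct = 2 * cfg.pool_size - n_shared
        pool_all = (rng.random((n_distinct, m)) < q).astype(np.uint8)
        pool_hqla = pool_all[: cfg.pool_size]
        pool_hb = pool_all[cfg.pool_size - n_shared :]
        pools[spec.name] = (pool_hqla, pool_hb)
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        chroms.extend([spec.name] * m)
        poss.extend(pos.tolist())
        refs.extend(_BASES[ref_idx].tolist())
        alts.extend(_BASES[alt_idx].tolist())
        cm = spec.length_cm * (pos - pos[0]) / max(pos[-1] - pos[0], 1)
        for p, c in zip(pos, cm):
            map_rows.append((spec.name, int(p), float(c)))
    vt = VariantTable(np.array(chroms, dtype=object), np.array(poss), np.array(refs, dtype=object), np.array(alts, dtype=object))
    gmap = GeneticMap(
        np.array([r[0] for r in map_rows], dtype=object),
        np.array([r[1] for r in map_rows]),
        np.array([r[2] for r in map_rows]),
    )
    n_hq, n_hb = cfg.n_founders
    hqla_ids = [f"HQLA_{i:03d}" for i in range(n_hq)]
    hb_ids = [f"HB_{i:03d}" for i in range(n_hb)]
    n_tot = n_hq + n_hb
    m_tot = vt.n_variants
    haps = np.empty((n_tot, 2, m_tot), dtype=np.uint8)
    origins = np.empty((n_tot, 2, m_tot), dtype=np.uint8)
    for i in range(n_tot):
        pop = HQLA if i < n_hq else HB
        origins[i] = pop
        off = 0
        for spec in cfg.chromosomes:
            pool = pools[spec.name][0] if pop == HQLA else pools[spec.name][1]
            for h in range(2):
                haps[i, h, off : off + spec.n_snps] = pool[rng.integers(0, cfg.pool_size)]
            off += spec.n_snps
    pg = PhasedGenotypes(hqla_ids + hb_ids, haps)
    return Founders(vt, gmap, pg, hqla_ids, hb_ids, origins, pools)


def _meiosis(
    alleles: np.ndarray,
    origins: np.ndarray,
    cm: np.ndarray,
    length_cm: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: crossovers ~ Poisson(length/100 Morgans), uniform in cM, no interference."""
    m = alleles.shape[1]
    n_cx = rng.poisson(length_cm / 100.0)
    start = rng.integers(0, 2)
    if n_cx == 0:
        return alleles[start], origins[start]
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_cx))
    idx = np.searchsorted(cm, cuts)
    parity = np.zeros(m, dtype=np.int64)
    np.add.at(parity, idx[idx < m], 1)
    sel = (start + np.cumsum(parity)) % 2
    # crossover before variant i flips the strand from variant i onward
    take = np.empty(m, dtype=np.intp)
    take[:] = sel
    return alleles[take, np.arange(m)], origins[take, np.arange(m)]


@dataclass
class _Individual:
    ident: str
    sex: str  # "F" | "M"
    sire: str
    dam: str
    generation: int
    alleles: np.ndarray  # (2, M)
    origins: np.ndarray


def gene_drop(
    cfg: SimConfig, founders: Founders, rng: np.random.Generator
) -> tuple[list[_Individual], pd.DataFrame]:
    """Drop genes from the founders to the final generation.

    F1 crosses HQLA dams with HB sires pair-by-pair; later generations pair
    males and females at random, each pair contributing a balanced share of
    the next generation.  Offspring sexes alternate within families, so the
    sex ratio stays balanced.  Returns the final-generation individuals and
    the full pedigree.
    """
    specs = cfg.chromosomes
    offsets = np.cumsum([0] + [s.n_snps for s in specs])
    cm_all = np.concatenate([founders.gmap.cm_at(s.name, founders.vt.pos[offsets[i] : offsets[i + 1]]) for i, s in enumerate(specs)])

    def make_child(ident: str, sex: str, dam: _Individual, sire: _Individual, gen: int) -> _Individual:
        al = np.empty_like(dam.alleles)
        orr = np.empty_like(dam.origins)
        for i, s in enumerate(specs):
            sl = slice(offsets[i], offsets[i + 1])
            cm = cm_all[sl]
            al[0, sl], orr[0, sl] = _meiosis(dam.alleles[:, sl], dam.origins[:, sl], cm, s.length_cm, rng)
            al[1, sl], orr[1, sl] = _meiosis(sire.alleles[:, sl], sire.origins[:, sl], cm, s.length_cm, rng)
        return _Individual(ident, sex, sire.ident, dam.ident, gen, al, orr)

    ped_rows = []
    founder_inds: dict[int, list[_Individual]] = {HQLA: [], HB: []}
    for i, ident in enumerate(founders.genotypes.samples):
        pop = HQLA if ident in founders.hqla_ids else HB
        ind = _Individual(ident, "F" if pop == HQLA else "M", "0", "0", 0, founders.genotypes.haps[i], founders.origins[i])
        founder_inds[pop].append(ind)
        ped_rows.append((ident, "0", "0", 0, ind.sex))
    if not founder_inds[HQLA] or not founder_inds[HB]:
        raise ValueError("both founder populations must contribute to F1")

    def breed(pairs: list[tuple[_Individual, _Individual]], size: int, gen: int) -> list[_Individual]:
        children = []
        for k in range(size):
            dam, sire = pairs[k % len(pairs)]
            sex = "F" if (k // len(pairs)) % 2 == 0 else "M"
            ident = f"F{gen}_{k:04d}"
            children.append(make_child(ident, sex, dam, sire, gen))
            ped_rows.append((ident, sire.ident, dam.ident, gen, sex))
        return children

    # F1: HQLA dams x HB sires
    n_pairs = min(len(founder_inds[HQLA]), len(founder_inds[HB]))
    pairs = [(founder_inds[HQLA][k], founder_inds[HB][k]) for k in range(n_pairs)]
    size = cfg.f9_size if cfg.generations == 1 else cfg.gen_size
    current = breed(pairs, size, 1)
    for gen in range(2, cfg.generations + 1):
        females = [c for c in current if c.sex == "F"]
        males = [c for c in current if c.sex == "M"]
        if not females or not males:
            raise ValueError(f"generation {gen - 1} lost one sex entirely")
        rng.shuffle(females)
        rng.shuffle(males)
        n_pairs = min(len(females), len(males))
        pairs = [(females[k], males[k]) for k in range(n_pairs)]
        size = cfg.f9_size if gen == cfg.generations else cfg.gen_size
        current = breed(pairs, size, gen)
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "generation", "sex"])
    return current, pedigree


def truth_block_origins(origins: np.ndarray, hbs: HaplotypeBlockSet) -> np.ndarray:
    """Block-level origin truth: the origin of descent at the block's middle SNP."""
    n_blocks = hbs.n_blocks
    out = np.empty((n_blocks, origins.shape[0], 2), dtype=np.int8)
    for b in range(n_blocks):
        mid = (int(hbs.table["start_idx"].iat[b]) + int(hbs.table["end_idx"].iat[b])) // 2
        out[b] = origins[:, :, mid]
    return out


def simulate_phenotype(
    cfg: SimConfig,
    vt: VariantTable,
    pg: PhasedGenotypes,
    hbs: HaplotypeBlockSet,
    truth_origin: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Trait values plus the stored genetic-value decomposition.

    y = mean + sex + batch + Σ additive(allele, origin) + Σ het-bonus
        + polygenic (SNP-GRM covariance) + N(0, σ²_e).
    """
    n = pg.n_samples
    batch_idx = rng.integers(0, len(cfg.batch_effects), size=n)
    additive = np.zeros(n)
    for cb in cfg.causal_blocks:
        b = hbs.block_index(cb.chrom, cb.block_id)
        for s in range(n):
            for h in range(2):
                allele = hbs.catalogs[b][hbs.assignments[b, s, h]]
                additive[s] += cb.effect_of(allele, int(truth_origin[b, s, h]))
    dom = np.zeros(n)
    for db in cfg.dominance_blocks:
        b = hbs.block_index(db.chrom, db.block_id)
        code = truth_origin[b].sum(axis=1)
        dom += db.het_bonus * (code == 1)
    if cfg.sigma_g2 > 0:
        from .relmat import snp_grm

        g = snp_grm(vt, pg).values
        lchol = np.linalg.cholesky(g + 1e-6 * np.eye(n))
        poly = np.sqrt(cfg.sigma_g2) * (lchol @ rng.standard_normal(n))
    else:
        poly = np.zeros(n)
    resid = np.sqrt(cfg.sigma_e2) * rng.standard_normal(n)
    sex_term = cfg.sex_effect * (sexes == "M")
    batch_term = np.array(cfg.batch_effects)[batch_idx]
    y = cfg.trait_mean + sex_term + batch_term + additive + dom + poly + resid
    pt = PhenotypeTable(list(pg.samples), y, np.where(sexes == "M", "M", "F"), np.array([f"b{i}" for i in batch_idx], dtype=object))
    comp = pd.DataFrame(
        {
            "id": pg.samples,
            "sex_term": sex_term,
            "batch_term": batch_term,
            "additive": additive,
            "dominance": dom,
            "polygenic": poly,
            "residual": resid,
        }
    )
    return pt, comp


def simulate_ail(cfg: SimConfig) -> SimResult:
    """End-to-end simulation: founders → gene drop → blocks → phenotype."""
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    final, pedigree = gene_drop(cfg, founders, rng)
    f9 = PhasedGenotypes([c.ident for c in final], np.stack([c.alleles for c in final]))
    f9_origins = np.stack([c.origins for c in final])
    hbs = build_blocks(founders.vt, f9, cfg.block_size)
    truth = truth_block_origins(f9_origins, hbs)
    sexes = np.array([c.sex for c in final], dtype=object)
    phenotypes, components = simulate_phenotype(cfg, founders.vt, f9, hbs, truth, sexes, rng)
    return SimResult(
        cfg, founders.vt, founders.gmap, founders, f9, f9_origins, hbs, truth, phenotypes, components, pedigree
    )
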