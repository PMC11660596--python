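"""Haplotype diversity and between-population dissimilarity statistics.

Diversity per block is summarized by pooled haplotype homozygosity:

    H12   = (p1 + p2)² + Σ_{i≥3} pi²
    H123  = (p1 + p2 + p3)² + Σ_{i≥4} pi²
    H1234 = (p1 + p2 + p3 + p4)² + Σ_{i≥5} pi²

with p1 ≥ p2 ≥ … the descending haplotype-allele frequencies of the block.
Pooling the top alleles makes the statistic insensitive to whether a common
haplotype class is split into a few frequent sub-alleles; lower values mean
higher diversity.

Dissimilarity between two populations at a block is measured on allele sets
(Jaccard distance), frequency distributions (Jensen–Shannon divergence,
natural log, so JSD ∈ [0, ln 2]) and raw counts (Bray–Curtis).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlockSet, HaplotypeSpectrum, spectrum

__all__ = [
    "h_stats",
    "jaccard",
    "jensen_shannon",
    "bray_curtis",
    "diversity_table",
    "dissimilarity_table",
    "split_halves",
]


def h_stats(freqs: Sequence[float]) -> tuple[float, float, float]:
    """(H12, H123, H1234) from a descending frequency vector summing to 1."""
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty spectrum")
    if np.any(np.diff(p) > 1e-12):
        p = np.sort(p)[::-1]
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    out = []
    for top in (2, 3, 4):
        k = min(top, p.size)
        out.append(float(p[:k].sum() ** 2 + (p[k:] ** 2).sum()))
    return tuple(out)  # type: ignore[return-value]


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard distance 1 − |A∩B| / |A∪B| between two allele sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both sets empty")
    return 1.0 - len(a & b) / len(a | b)


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    m = p > 0
    return float(np.sum(p[m] * np.log(p[m] / q[m])))


def jensen_shannon(f_a: Sequence[float], f_b: Sequence[float], sqrt: bool = False) -> float:
    """Jensen–Shannon divergence between two frequency vectors on a shared support.

    Natural logarithm; 0·log(0/·) := 0.  ``sqrt=True`` returns the square
    root (the Jensen–Shannon *distance*, the convention of several numerics
    packages).
    """
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must share a support")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative frequencies")
    if abs(a.sum() - 1) > 1e-9 or abs(b.sum() - 1) > 1e-9:
        raise ValueError("frequency vectors must sum to 1")
    mid = 0.5 * (a + b)
    jsd = 0.5 * _kl(a, mid) + 0.5 * _kl(b, mid)
    jsd = max(jsd, 0.0)
    return math.sqrt(jsd) if sqrt else jsd


def bray_curtis(c_a: Sequence[float], c_b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity 1 − 2·Σmin(SA,SB)/(ΣSA + ΣSB) on count vectors."""
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share a support")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    tot = a.sum() + b.sum()
    if tot == 0:
        raise ValueError("all-zero input")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / tot)


def _aligned(ca: Mapping[str, int], cb: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    support = sorted(set(ca) | set(cb))
    a = np.array([ca.get(k, 0) for k in support], dtype=float)
    b = np.array([cb.get(k, 0) for k in support], dtype=float)
    return a, b


def diversity_table(hbs: HaplotypeBlockSet, populations: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-block H12/H123/H1234 for each named population, plus genome means.

    Genome-level summaries (rows with ``block_id == -1`` and chrom
    ``"genome"``) are unweighted means over blocks.
    """
    rows = []
    for name, ids in populations.items():
        spec = spectrum(hbs, ids)
        vals = np.array([h_stats(spec.freqs(b)) for b in range(hbs.n_blocks)])
        for b in range(hbs.n_blocks):
            rows.append(
                dict(
                    chrom=hbs.table["chrom"].iat[b],
                    block_id=int(hbs.table["block_id"].iat[b]),
                    population=name,
                    H12=vals[b, 0],
                    H123=vals[b, 1],
                    H1234=vals[b, 2],
                )
            )
        rows.append(
            dict(
                chrom="genome",
                block_id=-1,
                population=name,
                H12=vals[:, 0].mean(),
                H123=vals[:, 1].mean(),
                H1234=vals[:, 2].mean(),
            )
        )
    return pd.DataFrame(rows)


def dissimilarity_table(
    hbs: HaplotypeBlockSet,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    sqrt_jsd: bool = False,
) -> pd.DataFrame:
    """Per-block Jaccard / Jensen–Shannon / Bray–Curtis between two populations."""
    sa = spectrum(hbs, pop_a)
    sb = spectrum(hbs, pop_b)
    rows = []
    for b in range(hbs.n_blocks):
        a, bb = _aligned(sa.counts[b], sb.counts[b])
        rows.append(
            dict(
                chrom=hbs.table["chrom"].iat[b],
                block_id=int(hbs.table["block_id"].iat[b]),
                JD=jaccard(sa.alleles(b), sb.alleles(b)),
                JSD=jensen_shannon(a / a.sum(), bb / bb.sum(), sqrt=sqrt_jsd),
                # relative abundances: raw counts would saturate the distance
                # whenever the two populations differ in size
                BCD=bray_curtis(a / a.sum(), bb / bb.sum()),
            )
        )
    df = pd.DataFrame(rows)
    summary = dict(chrom="genome", block_id=-1, JD=df["JD"].mean(), JSD=df["JSD"].mean(), BCD=df["BCD"].mean())
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def split_halves(samples: Sequence[str], seed: int) -> tuple[list[str], list[str]]:
    """Equal-size disjoint random halves of a sample list (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    half = len(samples) // 2
    s = list(samples)
    return [s[i] for i in perm[:half]], [s[i] for i in perm[half : 2 * half]]
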