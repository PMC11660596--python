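"""Ancestry-based dominance scan.

Per block, individuals fall into three ancestral classes irrespective of
allele sequence: HB/HB (code 0), HB/HQLA (code 1, the ancestral
heterozygote) and HQLA/HQLA (code 2).  On phenotypes corrected for sex and
batch, a Kruskal–Wallis test screens each block; blocks surviving
Benjamini–Hochberg FDR get Steel–Dwass all-pairs post-hoc tests, and the
class medians plus pairwise significance decide the label:

* high-parent dominance — the heterozygote median exceeds both homozygote
  medians and both het-vs-homozygote comparisons are significant;
* mid-parent dominance — the heterozygote median exceeds the midpoint of
  the two homozygote medians and the het-vs-nearer-homozygote comparison
  is significant (the weaker of the two contrasts; configurable, since
  several certifying contrasts are defensible).

High-parent dominance implies mid-parent dominance by construction.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "correct_phenotype",
    "kruskal_wallis",
    "steel_dwass",
    "label_dominance",
    "dominance_scan",
]


def correct_phenotype(pt: PhenotypeTable) -> np.ndarray:
    """Least-squares residuals of trait ~ intercept + sex + batch.

    Aliased columns in a confounded design are dropped (minimum-norm
    least squares) with a warning.
    """
    x = pt.covariate_design()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn("confounded sex/batch design: dropping aliased columns")
    beta, *_ = np.linalg.lstsq(x, pt.trait, rcond=None)
    return pt.trait - x @ beta


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p on (k−1) df."""
    if len(groups) < 2:
        raise ValueError("need at least two classes")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _pair_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic on the pair's joint ranking."""
    na, nb = len(a), len(b)
    n = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[:na].sum()
    e = na * (n + 1) / 2.0
    # variance with tie correction via the joint-rank spread
    v = na * nb / (n * (n - 1.0)) * (np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0)
    if v <= 0:
        return 0.0
    return float((ra - e) / np.sqrt(v))


def steel_dwass(
    groups: list[np.ndarray],
    permutations: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """All-pairs Steel–Dwass p-values (k×k symmetric matrix, NaN diagonal).

    Each pair is compared on its own joint ranking; the standardized
    rank-sum statistic t is referred to the studentized-range distribution
    with k groups and infinite degrees of freedom via q = |t|·√2
    (asymptotic mode).  With ``permutations`` set, the pair's p-value is
    instead the permutation tail probability of |t| — the small-sample
    option.  Pairs with an empty class get NaN.
    """
    k = len(groups)
    out = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        a, b = np.asarray(groups[i], float), np.asarray(groups[j], float)
        if len(a) == 0 or len(b) == 0:
            continue
        t = _pair_stat(a, b)
        if permutations:
            # permutation calibration of the pairwise statistic, then the
            # same studentized-range family correction as the asymptotic mode
            rng = rng or np.random.default_rng(0)
            pooled = np.concatenate([a, b])
            n_gt = n_eq = 0
            for _ in range(permutations):
                perm = rng.permutation(pooled)
                s = abs(_pair_stat(perm[: len(a)], perm[len(a) :]))
                if s > abs(t) + 1e-12:
                    n_gt += 1
                elif s >= abs(t) - 1e-12:
                    n_eq += 1
            # mid-p (half-weight on ties): the discrete permutation tail
            # comparable to a continuous reference distribution
            p_pair = (n_gt + 0.5 * n_eq + 0.5) / (permutations + 1)
            z = stats.norm.isf(min(p_pair, 1.0) / 2.0)
            p = float(stats.studentized_range.sf(max(z, 0.0) * np.sqrt(2.0), k, np.inf))
        else:
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, np.inf))
        out[i, j] = out[j, i] = p
    return out


def label_dominance(
    medians: tuple[float, float, float],
    pair_p: np.ndarray,
    alpha: float = 0.05,
    mid_rule: str = "closer",
) -> str:
    """Dominance label from class medians (m00, m01, m11) and pairwise p-values.

    ``pair_p`` is the 3×3 Steel–Dwass matrix indexed by ancestry code.
    ``mid_rule`` names the contrast certifying mid-parent dominance:
    "closer" (default) requires significance of het vs the homozygote class
    whose median is nearer the het's; "both" requires both het contrasts;
    "higher" requires het vs the higher-median homozygote.
    """
    m00, m01, m11 = medians
    p_h0, p_h1 = pair_p[1, 0], pair_p[1, 2]
    high = (
        m01 > m00
        and m01 > m11
        and np.isfinite(p_h0)
        and np.isfinite(p_h1)
        and p_h0 < alpha
        and p_h1 < alpha
    )
    if high:
        return "high-parent"
    if m01 > (m00 + m11) / 2.0:
        if mid_rule == "closer":
            cert = p_h0 if abs(m00 - m01) <= abs(m11 - m01) else p_h1
        elif mid_rule == "higher":
            cert = p_h1 if m11 >= m00 else p_h0
        elif mid_rule == "both":
            cert = max(p_h0, p_h1)
        else:
            raise ValueError(f"unknown mid_rule {mid_rule}")
        if np.isfinite(cert) and cert < alpha:
            return "mid-parent"
    return "none"


def dominance_scan(
    corrected: np.ndarray,
    code: np.ndarray,
    block_table: pd.DataFrame,
    min_class: int = 5,
    fdr: float = 0.05,
    alpha: float = 0.05,
    mid_rule: str = "closer",
    permutations: int | None = None,
) -> pd.DataFrame:
    """Genome scan for ancestry-based dominance.

    ``code`` is the (n_blocks, n_samples) diploid ancestry code matrix.
    Blocks with any class below ``min_class`` are reported untested
    (status "skipped").  KW p-values are BH-corrected across tested
    blocks; post-hoc tests run at nominal ``alpha`` on FDR survivors only.
    """
    rows = []
    for b in range(code.shape[0]):
        groups = [corrected[code[b] == c] for c in (0, 1, 2)]
        sizes = [len(g) for g in groups]
        row = dict(
            chrom=block_table["chrom"].iat[b],
            block_id=int(block_table["block_id"].iat[b]),
            n00=sizes[0],
            n01=sizes[1],
            n11=sizes[2],
            med00=np.nan,
            med01=np.nan,
            med11=np.nan,
            KW_H=np.nan,
            KW_p=np.nan,
            q=np.nan,
            p_het_vs_00=np.nan,
            p_het_vs_11=np.nan,
            p_00_vs_11=np.nan,
            label="none",
            status="tested",
        )
        if min(sizes) < min_class:
            row["status"] = "skipped"
            rows.append(row)
            continue
        row["med00"], row["med01"], row["med11"] = (float(np.median(g)) for g in groups)
        h, p = kruskal_wallis(groups)
        row["KW_H"], row["KW_p"] = h, p
        row["_groups"] = groups
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df["status"] == "tested"
    if tested.any():
        _, qv, _, _ = multipletests(df.loc[tested, "KW_p"], method="fdr_bh")
        df.loc[tested, "q"] = qv
    for i in df.index[tested & (df["q"] <= fdr)]:
        groups = df.at[i, "_groups"]
        pp = steel_dwass(groups, permutations=permutations)
        df.at[i, "p_het_vs_00"] = pp[1, 0]
        df.at[i, "p_het_vs_11"] = pp[1, 2]
        df.at[i, "p_00_vs_11"] = pp[0, 2]
        df.at[i, "label"] = label_dominance(
            (df.at[i, "med00"], df.at[i, "med01"], df.at[i, "med11"]), pp, alpha, mid_rule
        )
    if "_groups" in df.columns:
        df = df.drop(columns=["_groups"])
    return df
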