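"""Mixed-model association scans.

Three GWAS variants share the model y = Qα + xβ + g + e with polygenic
g ~ N(0, σ²_g K):

* SNP mode — x is the SNP alt-allele dosage (0/1/2), K the SNP GRM.
* Ancestral-haplotype mode — x is the diploid ancestry code (copies of
  HQLA origin per block, 0/1/2), K the ancestry GRM; the test asks whether
  *origin* at the block, regardless of allele sequence, moves the trait.
* Haplotype mode — the block's haplotype combination enters as a
  categorical fixed effect tested by a likelihood-ratio test against the
  null model, with the individual-level haplotype relationship matrix H as
  the polygenic structure.

Dosage scans use the EMMAX-style approximation: variance components are
estimated once by REML on the covariate-only null model, the system is
whitened at that variance ratio, and each marker is tested by weighted
least squares (per-marker residual scale re-estimated, t reference), which
collapses to ordinary least squares when K = I.  Block tests refit both
models by full ML, since REML likelihoods are not comparable across
fixed-effect structures.

Multiple testing is controlled by Benjamini–Hochberg FDR; significant
markers/blocks within a gap of each other merge into regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._mixed import KinshipEigen, VarianceFit, fit_variance_components
from .blocks import HaplotypeBlockSet
from .relmat import KinshipMatrix

__all__ = [
    "reml_fit",
    "marker_scan",
    "block_lrt",
    "haplotype_gwas",
    "fdr_and_regions",
]


def _eig(kinship: KinshipMatrix | KinshipEigen | np.ndarray) -> KinshipEigen:
    if isinstance(kinship, KinshipEigen):
        return kinship
    if isinstance(kinship, KinshipMatrix):
        return KinshipEigen.from_kinship(kinship.values)
    return KinshipEigen.from_kinship(np.asarray(kinship, dtype=float))


def reml_fit(
    y: np.ndarray,
    q: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    method: str = "reml",
) -> VarianceFit:
    """Variance components of the covariate-only (null) mixed model."""
    return fit_variance_components(y, q, _eig(kinship), method=method)


def marker_scan(
    y: np.ndarray,
    q: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    dosages: np.ndarray,
    meta: pd.DataFrame | None = None,
    null_fit: VarianceFit | None = None,
) -> pd.DataFrame:
    """Per-marker GLS tests of 0/1/2 dosages under a fixed variance ratio.

    ``dosages`` has shape (n_markers, n_samples).  Monomorphic markers get
    an NA row.  Returns columns beta, se, stat (t), p plus any ``meta``
    columns (aligned by row).
    """
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    x_all = np.asarray(dosages, dtype=float)
    if x_all.ndim != 2 or x_all.shape[1] != y.shape[0]:
        raise ValueError("dosages must have shape (n_markers, n_samples)")
    vals = np.unique(x_all)
    if not np.all(np.isin(vals, [0.0, 1.0, 2.0])):
        raise ValueError("dosages must take values in {0, 1, 2}")
    eig = _eig(kinship)
    if null_fit is None:
        null_fit = fit_variance_components(y, q, eig, method="reml")
    w = 1.0 / np.sqrt(eig.d + null_fit.delta)
    yw = w * eig.rotate(y)
    qw = w[:, None] * eig.rotate(q)
    xw = (w[:, None] * (eig.u.T @ x_all.T)).T  # (markers, N)
    # project covariates out (Frisch–Waugh): per-marker simple regression on residuals
    qq_inv = np.linalg.inv(qw.T @ qw)
    proj = lambda a: a - qw @ (qq_inv @ (qw.T @ a))
    yr = proj(yw)
    xr = proj(xw.T).T  # (markers, N)
    sxx = np.einsum("ij,ij->i", xr, xr)
    sxy = xr @ yr
    n, p = yw.shape[0], qw.shape[1]
    df = n - p - 1
    mono = np.ptp(x_all, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = yr @ yr - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta[mono] = np.nan
    se[mono] = np.nan
    tstat[mono] = np.nan
    pvals[mono] = np.nan
    out = pd.DataFrame({"beta": beta, "se": se, "stat": tstat, "p": pvals})
    if meta is not None:
        out = pd.concat([meta.reset_index(drop=True), out], axis=1)
    return out


def _combination_design(
    hbs: HaplotypeBlockSet, b: int, min_count: int
) -> tuple[np.ndarray, int] | None:
    """Dummy design for the block's haplotype combinations, rare levels pooled.

    Returns (dummies without reference level, n_levels) or None when only a
    single level remains after pooling.
    """
    pairs = [tuple(sorted(hbs.assignments[b, s])) for s in range(hbs.n_samples)]
    counts = pd.Series(pairs).value_counts()
    keep = set(counts.index[counts >= min_count])
    labels = [p if p in keep else "OTHER" for p in pairs]
    levels = sorted(set(labels), key=str)
    if len(levels) < 2:
        return None
    dummies = np.column_stack(
        [[1.0 if lab == lv else 0.0 for lab in labels] for lv in levels[1:]]
    )
    return dummies, len(levels)


def block_lrt(
    y: np.ndarray,
    q: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    hbs: HaplotypeBlockSet,
    block: int,
    min_count: int = 5,
    null_fit: VarianceFit | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the block's haplotype-combination factor.

    Both the null (covariates + polygenic) and alternative (adding the
    combination dummies) models are fit by full ML; the statistic is twice
    the log-likelihood gap, referred to chi-square with
    (#retained levels − 1) degrees of freedom.  Combinations carried by
    fewer than ``min_count`` individuals pool into one OTHER level.
    Returns (nan, 0, nan) when only one level remains.
    """
    eig = _eig(kinship)
    design = _combination_design(hbs, block, min_count)
    if design is None:
        return float("nan"), 0, float("nan")
    dummies, n_levels = design
    if null_fit is None or null_fit.method != "ml":
        null_fit = fit_variance_components(y, q, eig, method="ml")
    x_alt = np.column_stack([q, dummies])
    if np.linalg.matrix_rank(x_alt) < x_alt.shape[1]:
        # aliased combination dummies (e.g. OTHER collinear with covariates)
        keep = []
        base_rank = np.linalg.matrix_rank(q)
        cur = q
        for j in range(dummies.shape[1]):
            trial = np.column_stack([cur, dummies[:, j]])
            if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(cur):
                cur = trial
                keep.append(j)
        dummies = dummies[:, keep]
        if dummies.shape[1] == 0:
            return float("nan"), 0, float("nan")
        x_alt = np.column_stack([q, dummies])
        n_levels = dummies.shape[1] + 1
    alt_fit = fit_variance_components(y, x_alt, eig, method="ml")
    lrt = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    dof = n_levels - 1
    p = float(stats.chi2.sf(lrt, dof))
    return lrt, dof, p


def haplotype_gwas(
    y: np.ndarray,
    q: np.ndarray,
    kinship: KinshipMatrix | KinshipEigen | np.ndarray,
    hbs: HaplotypeBlockSet,
    min_count: int = 5,
) -> pd.DataFrame:
    """Genome scan of block LRTs; the ML null model is fit once and reused."""
    eig = _eig(kinship)
    null_fit = fit_variance_components(y, q, eig, method="ml")
    rows = []
    for b in range(hbs.n_blocks):
        lrt, dof, p = block_lrt(y, q, eig, hbs, b, min_count, null_fit=null_fit)
        rows.append(
            dict(
                chrom=hbs.table["chrom"].iat[b],
                block_id=int(hbs.table["block_id"].iat[b]),
                start_bp=int(hbs.table["start_bp"].iat[b]),
                end_bp=int(hbs.table["end_bp"].iat[b]),
                stat=lrt,
                df=dof,
                p=p,
            )
        )
    return pd.DataFrame(rows)


def fdr_and_regions(
    table: pd.DataFrame,
    q_threshold: float = 0.05,
    gap: int = 1,
    block_col: str = "block_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benjamini–Hochberg q-values and merged significant regions.

    NA p-values are excluded from the correction and never significant.
    Significant entries on one chromosome whose ``block_col`` indices are
    within ``gap`` of each other merge into one region (default: adjacent).
    """
    out = table.copy()
    p = out["p"].to_numpy(dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        _, qv, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = qv
    out["q"] = q
    out["significant"] = (q <= q_threshold) & ok
    regions = []
    sig = out[out["significant"]]
    for chrom, grp in sig.groupby("chrom", sort=False):
        ids = np.sort(grp[block_col].to_numpy())
        start = ids[0]
        prev = ids[0]
        for i in ids[1:]:
            if i - prev > gap:
                regions.append((chrom, int(start), int(prev)))
                start = i
            prev = i
        regions.append((chrom, int(start), int(prev)))
    reg_rows = []
    for chrom, b0, b1 in regions:
        members = out[(out["chrom"] == chrom) & (out[block_col] >= b0) & (out[block_col] <= b1)]
        reg_rows.append(
            dict(
                chrom=chrom,
                first=b0,
                last=b1,
                start_bp=int(members["start_bp"].min()) if "start_bp" in members else np.nan,
                end_bp=int(members["end_bp"].max()) if "end_bp" in members else np.nan,
                n_blocks=int(b1 - b0 + 1),
                min_p=float(members["p"].min()),
            )
        )
    reg_cols = ["chrom", "first", "last", "start_bp", "end_bp", "n_blocks", "min_p"]
    return out, pd.DataFrame(reg_rows, columns=reg_cols)
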