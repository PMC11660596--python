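"""Block-wise haplotype-allele effect estimation.

For one (typically significant) block the model is

    y = Q α + Z_d μ + e,

where Z_d counts the copies of each haplotype allele carried by each
individual (every row sums to 2) and μ is a vector of independent Gaussian
random effects, one per allele.  In ancestral mode each column is an
(allele, origin) pair labeled "<alleleSeq>_<0|1>" (0 = HB, 1 = HQLA), so an
allele sequence present on both ancestral backgrounds gets two columns and
its origin-specific effects can separate.  Effects are returned as BLUPs in
trait units with prediction-error SEs; the variance ratio λ = σ²_e/σ²_μ is
re-estimated per block by REML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mixed import KinshipEigen, fit_variance_components
from .ancestry import AncestryTrack
from .blocks import HaplotypeBlockSet, HaplotypeSpectrum

__all__ = ["DosageMatrix", "build_dosage", "estimate_effects", "flag_exclusivity"]


@dataclass
class DosageMatrix:
    """Copy counts of haplotype alleles (or allele×origin labels) per individual."""

    samples: list[str]
    labels: list[str]  # allele string, or "<allele>_<origin>" in ancestral mode
    values: np.ndarray  # (n_samples, n_labels), rows sum to 2
    ancestral: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(self.values.sum(axis=1) == 2):
            raise ValueError("each row of a dosage matrix must sum to 2")


def build_dosage(
    hbs: HaplotypeBlockSet,
    block: int,
    track: AncestryTrack | None = None,
) -> DosageMatrix:
    """Dosage matrix for one block; pass an ancestry track for ancestral mode.

    Plain mode counts allele copies.  Ancestral mode counts (allele, origin)
    pairs; the track must cover every sample of the block set.
    """
    catalog = hbs.catalogs[block]
    n = hbs.n_samples
    if track is None:
        labels = list(catalog)
        values = np.zeros((n, len(labels)))
        for s in range(n):
            for h in range(2):
                values[s, hbs.assignments[block, s, h]] += 1
        return DosageMatrix(list(hbs.samples), labels, values, ancestral=False)
    pos = {smp: i for i, smp in enumerate(track.samples)}
    missing = [s for s in hbs.samples if s not in pos]
    if missing:
        raise ValueError(f"samples missing from ancestry track: {missing[:5]}")
    origin = track.origin
    labels = [f"{a}_{o}" for a in catalog for o in (0, 1)]
    index = {lab: j for j, lab in enumerate(labels)}
    values = np.zeros((n, len(labels)))
    for s, smp in enumerate(hbs.samples):
        for h in range(2):
            a = catalog[hbs.assignments[block, s, h]]
            o = int(origin[block, pos[smp], h])
            values[s, index[f"{a}_{o}"]] += 1
    return DosageMatrix(list(hbs.samples), labels, values, ancestral=True)


def estimate_effects(
    y: np.ndarray,
    q: np.ndarray,
    zd: DosageMatrix,
    lam: float | None = None,
) -> pd.DataFrame:
    """BLUPs of per-allele random effects with prediction-error SEs.

    λ = σ²_e/σ²_μ is estimated by REML on V = σ²_μ Z Z′ + σ²_e I unless
    given.  Solves the mixed-model equations; effects are in trait units on
    the covariate-adjusted scale.  Columns: label, origin (NA in plain
    mode), effect, se, carriers.
    """
    y = np.asarray(y, dtype=float)
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if q.shape[0] != y.shape[0]:
        q = q.T
    used = zd.values.sum(axis=0) > 0  # carrier-free columns are unidentifiable
    zd = DosageMatrix(
        zd.samples, [lab for lab, u in zip(zd.labels, used) if u], zd.values[:, used], zd.ancestral
    )
    z = zd.values
    carriers = (z > 0).sum(axis=0)
    if z.shape[1] < 2:
        raise ValueError("need at least two allele columns to estimate contrasts")
    if lam is None:
        eig = KinshipEigen.from_kinship(z @ z.T)
        fit = fit_variance_components(y, q, eig, method="reml")
        lam = fit.delta
        sigma_e2 = fit.sigma_e2
    else:
        sigma_e2 = None
    p, m = q.shape[1], z.shape[1]
    c = np.zeros((p + m, p + m))
    c[:p, :p] = q.T @ q
    c[:p, p:] = q.T @ z
    c[p:, :p] = z.T @ q
    c[p:, p:] = z.T @ z + lam * np.eye(m)
    rhs = np.concatenate([q.T @ y, z.T @ y])
    cinv = np.linalg.inv(c)
    sol = cinv @ rhs
    mu = sol[p:]
    if sigma_e2 is None:
        resid = y - q @ sol[:p] - z @ mu
        sigma_e2 = float(resid @ resid / max(len(y) - p, 1))
    se = np.sqrt(np.maximum(np.diag(cinv)[p:], 0.0) * sigma_e2)
    if zd.ancestral:
        origins = [int(lab.rsplit("_", 1)[1]) for lab in zd.labels]
        alleles = [lab.rsplit("_", 1)[0] for lab in zd.labels]
    else:
        origins = [pd.NA] * m
        alleles = list(zd.labels)
    return pd.DataFrame(
        {
            "label": zd.labels,
            "allele": alleles,
            "origin": origins,
            "effect": mu,
            "se": se,
            "carriers": carriers,
        }
    )


def flag_exclusivity(
    allele: str,
    block: int,
    hb_panel: HaplotypeSpectrum,
    hqla_panel: HaplotypeSpectrum,
) -> str:
    """Founder-panel membership of a block allele.

    One of "HQLA-only", "HB-only", "shared" (present in both founder
    panels) or "novel" (absent from both — typically a recombinant formed
    during the intercross generations).
    """
    in_hb = allele in hb_panel.counts[block]
    in_hq = allele in hqla_panel.counts[block]
    if in_hb and in_hq:
        return "shared"
    if in_hq:
        return "HQLA-only"
    if in_hb:
        return "HB-only"
    return "novel"
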