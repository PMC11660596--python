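"""Relationship matrices for the polygenic term of the mixed models.

Three constructions share one estimator shape:

* SNP GRM — centered, per-marker-standardized dosage cross-product,
  G_jk = (1/M) Σ_m (x_jm − 2p_m)(x_km − 2p_m) / (2 p_m (1 − p_m)).
* Ancestry GRM — the same estimator with diploid ancestry codes (copies of
  HQLA origin per block, 0/1/2) in place of SNP dosages, capturing global
  ancestry instead of genotype sharing.
* Haplotype relationship matrix — per block, haplotype alleles score 1 if
  identical and 0 otherwise, giving a 2N×2N matrix Γ_i; Γ = Σ Γ_i / n over
  blocks, reduced to the N×N individual-level H = K Γ K′ / 2 with
  K = I ⊗ [1 1] (each entry of H is the mean pairwise haplotype identity
  between two individuals times two; diagonal ∈ [1, 2]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlockSet
from .io import PhasedGenotypes, VariantTable

__all__ = [
    "KinshipMatrix",
    "HaplotypeGamma",
    "snp_grm",
    "ancestry_grm",
    "haplotype_gamma",
    "gamma_to_h",
]


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray  # (N, N) symmetric
    provenance: str  # "snp" | "ancestry" | "haplotype"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    def is_psd(self, rel_tol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.values)
        n = self.values.shape[0]
        return bool(w.min() >= -rel_tol * np.trace(self.values) / n)

    def save(self, path: str | Path, fmt: str = "tsv") -> None:
        path = Path(path)
        if fmt == "tsv":
            pd.DataFrame(self.values, index=self.samples, columns=self.samples).to_csv(
                path, sep="\t"
            )
        elif fmt == "npy":
            np.save(path, self.values)
        else:
            raise ValueError(f"unknown format {fmt}")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"provenance": self.provenance, "samples": self.samples})
        )

    @classmethod
    def load(cls, path: str | Path) -> "KinshipMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if path.suffix == ".npy":
            vals = np.load(path)
        else:
            vals = pd.read_csv(path, sep="\t", index_col=0).to_numpy()
        return cls(meta["samples"], vals, meta["provenance"])


@dataclass
class HaplotypeGamma:
    """Block-averaged 2N×2N haplotype identity matrix.

    Haplotype order is sample-major: (s1 hap1, s1 hap2, s2 hap1, …).
    """

    samples: list[str]
    values: np.ndarray  # (2N, 2N)
    n_blocks: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("Gamma diagonal must be exactly 1")


def _standardized_grm(dosage: np.ndarray) -> np.ndarray:
    """Centered/scaled cross-product over polymorphic columns of 0/1/2 dosages."""
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 1:
        raise ValueError("no polymorphic markers for GRM")
    x = dosage[:, poly].astype(float)
    pp = p[poly]
    z = (x - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    return (z @ z.T) / poly.sum()


def snp_grm(vt: VariantTable, pg: PhasedGenotypes) -> KinshipMatrix:
    """GRM from all polymorphic SNPs (monomorphic sites skipped)."""
    g = _standardized_grm(pg.dosages())
    return KinshipMatrix(list(pg.samples), g, "snp")


def ancestry_grm(code: np.ndarray, samples: list[str]) -> KinshipMatrix:
    """GRM over diploid ancestry codes, shape (n_blocks, n_samples) 0/1/2.

    Blocks fixed for one origin carry no information and are skipped.
    """
    code = np.asarray(code)
    g = _standardized_grm(code.T)
    return KinshipMatrix(list(samples), g, "ancestry")


def haplotype_gamma(hbs: HaplotypeBlockSet) -> HaplotypeGamma:
    """Γ = Σ_i Γ_i / n accumulated block-by-block (Γ_i never all materialized)."""
    n2 = 2 * hbs.n_samples
    acc = np.zeros((n2, n2))
    for b in range(hbs.n_blocks):
        a = hbs.assignments[b].reshape(-1)  # (2N,) sample-major
        acc += (a[:, None] == a[None, :])
    acc /= hbs.n_blocks
    np.fill_diagonal(acc, 1.0)
    return HaplotypeGamma(list(hbs.samples), acc, hbs.n_blocks)


def gamma_to_h(g: HaplotypeGamma) -> KinshipMatrix:
    """Individual-level H = K Γ K′ / 2: each entry sums a 2×2 sub-block of Γ, halved."""
    n = len(g.samples)
    v = g.values.reshape(n, 2, n, 2).sum(axis=(1, 3)) / 2.0
    return KinshipMatrix(list(g.samples), v, "haplotype")
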