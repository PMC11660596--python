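import numpy as np
import pytest

from ailhap.io import PhasedGenotypes, VariantTable
from ailhap.simulate import ChromosomeSpec, SimConfig, simulate_ail


def make_variants(n, chrom="chr1", start=1000, step=100):
    pos = start + step * np.arange(n)
    return VariantTable(
        np.array([chrom] * n, dtype=object),
        pos,
        np.array(["A"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
    )


def make_genotypes(hap_rows, samples=None):
    """Build PhasedGenotypes from a list of per-haplotype 0/1 rows (2 per sample)."""
    haps = np.array(hap_rows, dtype=np.uint8)
    n = haps.shape[0] // 2
    samples = samples or [f"s{i}" for i in range(n)]
    return PhasedGenotypes(samples, haps.reshape(n, 2, -1))


@pytest.fixture(scope="session")
def small_sim():
    """One modest AIL shared by read-only tests: 2 chromosomes, 120 F9 individuals."""
    cfg = SimConfig(
        seed=7,
        chromosomes=[ChromosomeSpec("chr1", 100, 100.0), ChromosomeSpec("chr2", 100, 100.0)],
        n_founders=(10, 10),
        pool_size=6,
        f9_size=120,
        gen_size=80,
        sigma_g2=400.0,
        sigma_e2=900.0,
    )
    return simulate_ail(cfg)
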