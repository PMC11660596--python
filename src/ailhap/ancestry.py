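"""Local-ancestry assignment of intercross haplotypes to founder populations.

Each haplotype of each admixed individual receives, per haplotype block, a
posterior probability of descending from the high-weight founder line
(HQLA, coded 1) versus the low-weight line (HB, coded 0).  Origins are
called by thresholding the posterior at 0.5, with ties going to HQLA
(posterior ≥ 0.5 → origin 1).

Two routes produce a track: a built-in per-block classifier that compares
the haplotype allele's smoothed frequency in the two founder panels
(optionally followed by a running-mean smoother along the chromosome), or
an importer for externally computed per-window posterior tables in the
style of dedicated local-ancestry tools.  The built-in classifier is
deliberately simple — a naive smoothed-frequency posterior with equal class
priors — not a reimplementation of CRF-based inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlockSet, HaplotypeSpectrum, spectrum

__all__ = [
    "AncestryTrack",
    "classify_window",
    "infer_ancestry",
    "smooth_track",
    "import_rfmix",
    "code_diploid",
    "ancestry_accuracy",
    "write_track",
]

HB, HQLA = 0, 1


@dataclass
class AncestryTrack:
    """Per-haplotype, per-block posterior of HQLA origin with hard calls."""

    samples: list[str]
    chrom: np.ndarray  # per block
    block_id: np.ndarray
    posterior: np.ndarray  # (n_blocks, n_samples, 2) float, P(HQLA)

    def __post_init__(self) -> None:
        self.posterior = np.asarray(self.posterior, dtype=float)
        if ((self.posterior < 0) | (self.posterior > 1)).any():
            raise ValueError("posteriors must lie in [0, 1]")

    @property
    def origin(self) -> np.ndarray:
        """Hard origin calls: 1 (HQLA) iff posterior ≥ 0.5."""
        return (self.posterior >= 0.5).astype(np.int8)

    @property
    def n_blocks(self) -> int:
        return self.posterior.shape[0]


def classify_window(
    allele: str,
    hb_counts: Mapping[str, int],
    hb_n: int,
    hqla_counts: Mapping[str, int],
    hqla_n: int,
    pseudocount: float = 1.0,
) -> float:
    """Posterior P(HQLA origin) of one block allele given the two founder panels.

    Laplace-smoothed panel frequencies with equal class priors:
    f_P = (count_P + c) / (n_P + 2c); posterior = f_HQLA / (f_HQLA + f_HB).
    Alleles unseen in both panels fall back to 0.5.
    """
    c = float(pseudocount)
    f_hb = (hb_counts.get(allele, 0) + c) / (hb_n + 2 * c) if (hb_n + 2 * c) > 0 else 0.0
    f_hq = (hqla_counts.get(allele, 0) + c) / (hqla_n + 2 * c) if (hqla_n + 2 * c) > 0 else 0.0
    if f_hb + f_hq == 0:
        return 0.5
    return f_hq / (f_hq + f_hb)


def infer_ancestry(
    hbs: HaplotypeBlockSet,
    hb_panel: Sequence[str] | HaplotypeSpectrum,
    hqla_panel: Sequence[str] | HaplotypeSpectrum,
    target_samples: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    window: int = 1,
) -> AncestryTrack:
    """Classify every target haplotype per block against the founder panels.

    Panels may be sample-id lists (spectra computed from ``hbs``) or
    precomputed :class:`HaplotypeSpectrum` objects.  ``window`` > 1 applies
    running-mean posterior smoothing along each chromosome (see
    :func:`smooth_track`).
    """
    spec_hb = hb_panel if isinstance(hb_panel, HaplotypeSpectrum) else spectrum(hbs, hb_panel)
    spec_hq = hqla_panel if isinstance(hqla_panel, HaplotypeSpectrum) else spectrum(hbs, hqla_panel)
    targets = list(target_samples) if target_samples is not None else list(hbs.samples)
    tidx = [hbs.samples.index(s) for s in targets]
    n_hb = 2 * len(spec_hb.samples)
    n_hq = 2 * len(spec_hq.samples)
    post = np.empty((hbs.n_blocks, len(targets), 2), dtype=float)
    for b in range(hbs.n_blocks):
        cat = hbs.catalogs[b]
        per_allele = np.array(
            [
                classify_window(a, spec_hb.counts[b], n_hb, spec_hq.counts[b], n_hq, pseudocount)
                for a in cat
            ]
        )
        post[b] = per_allele[hbs.assignments[b][tidx]]
    track = AncestryTrack(
        targets,
        hbs.table["chrom"].to_numpy(),
        hbs.table["block_id"].to_numpy(),
        post,
    )
    if window > 1:
        track = smooth_track(track, window)
    return track


def smooth_track(track: AncestryTrack, window: int) -> AncestryTrack:
    """Replace posteriors by a running mean over ``window`` blocks per chromosome.

    ``window`` must be odd; at chromosome ends (or when the window exceeds
    the chromosome) the window is truncated to the available blocks.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return track
    half = window // 2
    out = np.empty_like(track.posterior)
    for chrom in pd.unique(pd.Series(track.chrom)):
        m = np.nonzero(track.chrom == chrom)[0]
        sub = track.posterior[m]  # (nb, N, 2)
        nb = len(m)
        csum = np.concatenate([np.zeros((1,) + sub.shape[1:]), np.cumsum(sub, axis=0)], axis=0)
        for j in range(nb):
            lo = max(0, j - half)
            hi = min(nb, j + half + 1)
            out[m[j]] = (csum[hi] - csum[lo]) / (hi - lo)
    return AncestryTrack(track.samples, track.chrom, track.block_id, out)


def import_rfmix(path: str | Path, hbs: HaplotypeBlockSet, samples: Sequence[str]) -> AncestryTrack:
    """Import per-window ancestry posteriors from a whitespace-delimited table.

    Accepted dialect (documented by the fixture shipped with the tests):
    one row per window, columns ``chrom  start_bp  end_bp`` followed by two
    posterior columns per haplotype — P(HB) then P(HQLA) — with haplotypes
    ordered sample-major (sample1 hap1, sample1 hap2, sample2 hap1, …)
    matching ``samples``.  Lines starting with ``#`` are ignored.  Each
    block takes the posteriors of the window containing its midpoint.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    n_post_cols = df.shape[1] - 3
    if n_post_cols != 4 * len(samples):  # two columns per haplotype, 2 haps/sample
        raise ValueError(
            f"haplotype count mismatch: file has {n_post_cols // 2} haplotypes, "
            f"expected {2 * len(samples)}"
        )
    file_chroms = set(df[0])
    need = set(map(str, pd.unique(pd.Series(hbs.table["chrom"]))))
    missing = sorted(need - file_chroms)
    if missing:
        raise ValueError(f"chromosomes missing from ancestry file: {missing}")
    # P(HQLA) columns: every second haplotype column starting at offset 4
    p_hqla = df.iloc[:, 4::2].to_numpy(dtype=float)
    post = np.empty((hbs.n_blocks, len(samples), 2), dtype=float)
    for b in range(hbs.n_blocks):
        chrom = str(hbs.table["chrom"].iat[b])
        mid = 0.5 * (hbs.table["start_bp"].iat[b] + hbs.table["end_bp"].iat[b])
        rows = df.index[(df[0] == chrom) & (df[1] <= mid) & (mid <= df[2])]
        if len(rows) == 0:
            raise ValueError(f"no ancestry window covers block {chrom}:{int(hbs.table['block_id'].iat[b])}")
        post[b] = p_hqla[rows[0]].reshape(len(samples), 2)
    return AncestryTrack(
        list(samples), hbs.table["chrom"].to_numpy(), hbs.table["block_id"].to_numpy(), post
    )


def code_diploid(track: AncestryTrack) -> np.ndarray:
    """Diploid ancestry code per (block, sample): copies of HQLA origin, 0/1/2."""
    return track.origin.sum(axis=2, dtype=np.int8)


def ancestry_accuracy(
    track: AncestryTrack,
    truth_origin: np.ndarray | None = None,
    hbs: HaplotypeBlockSet | None = None,
    hb_panel: HaplotypeSpectrum | None = None,
    hqla_panel: HaplotypeSpectrum | None = None,
) -> float:
    """Fraction of assignable haplotype-blocks whose origin call is correct.

    With ``truth_origin`` (same shape as the track's origin array) every
    haplotype-block is assignable.  Alternatively, founder-panel spectra
    define the assignable set as haplotype-blocks carrying an allele unique
    to one panel, whose origin is then known without simulator truth — the
    empirical check available for real data.
    """
    calls = track.origin
    if truth_origin is not None:
        truth = np.asarray(truth_origin)
        if truth.shape != calls.shape:
            raise ValueError("truth shape mismatch")
        return float((calls == truth).mean())
    if hbs is None or hb_panel is None or hqla_panel is None:
        raise ValueError("need truth_origin or (hbs, hb_panel, hqla_panel)")
    tidx = [hbs.samples.index(s) for s in track.samples]
    n_match = 0
    n_assign = 0
    for b in range(hbs.n_blocks):
        hb_set = hb_panel.alleles(b)
        hq_set = hqla_panel.alleles(b)
        unique = {a: HB for a in hb_set - hq_set}
        unique.update({a: HQLA for a in hq_set - hb_set})
        if not unique:
            continue
        for si in range(len(track.samples)):
            for h in range(2):
                allele = hbs.catalogs[b][hbs.assignments[b, tidx[si], h]]
                if allele in unique:
                    n_assign += 1
                    n_match += int(calls[b, si, h] == unique[allele])
    if n_assign == 0:
        raise ValueError("no assignable haplotype-blocks")
    return n_match / n_assign


def read_track(path: str | Path) -> AncestryTrack:
    """Read a track written by :func:`write_track`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    samples = list(dict.fromkeys(df["sample"]))
    blocks_df = df[["chrom", "block_id"]].drop_duplicates().reset_index(drop=True)
    sidx = {s: i for i, s in enumerate(samples)}
    bidx = {(c, b): i for i, (c, b) in enumerate(zip(blocks_df["chrom"], blocks_df["block_id"]))}
    post = np.full((len(blocks_df), len(samples), 2), np.nan)
    post[
        df[["chrom", "block_id"]].apply(lambda r: bidx[(r.iloc[0], r.iloc[1])], axis=1),
        df["sample"].map(sidx),
        df["hap"] - 1,
    ] = df["posterior"]
    if np.isnan(post).any():
        raise ValueError("incomplete ancestry track: missing (sample, hap, block) rows")
    return AncestryTrack(samples, blocks_df["chrom"].to_numpy(), blocks_df["block_id"].to_numpy(), post)


def write_track(track: AncestryTrack, path: str | Path) -> None:
    """TSV writer: sample, hap (1/2), chrom, block_id, posterior, origin."""
    rows = []
    origin = track.origin
    for b in range(track.n_blocks):
        for si, s in enumerate(track.samples):
            for h in range(2):
                rows.append(
                    (s, h + 1, track.chrom[b], int(track.block_id[b]), track.posterior[b, si, h], int(origin[b, si, h]))
                )
    pd.DataFrame(rows, columns=["sample", "hap", "chrom", "block_id", "posterior", "origin"]).to_csv(
        path, sep="\t", index=False
    )
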