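"""Haplotype blocks, block-allele enumeration, and the haplotype GRM.

A haplotype block is a run of consecutive SNPs on one chromosome treated
as a single multiallelic locus whose alleles are the distinct phased
haplotypes observed in the sample.  Three blocking schemes are supported:
a fixed number of SNPs per block, fixed-width genomic windows anchored at
position 1 of each chromosome, and externally supplied regions (e.g.
genes) from a BED file.

The haplotype additive GRM is the Gram matrix of the mean-centered
haplotype-allele count columns pooled over every block, scaled to mean
diagonal 1.  Centering makes the matrix invariant to dropping any one
reference allele per block, so all observed alleles are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import GRM, GenotypeData
from .grm_builders import normalize_grm

logger = logging.getLogger(__name__)

__all__ = [
    "BlockDefinition",
    "HaplotypeAlleleTable",
    "blocks_by_count",
    "blocks_by_window",
    "blocks_from_regions",
    "enumerate_haplotypes",
    "grm_haplotype",
]


@dataclass
class BlockDefinition:
    """Ordered, non-overlapping SNP-index ranges, each on one chromosome.

    ``blocks`` holds ``(chrom, start, end)`` with ``[start, end)`` indexing
    into the genotype panel's variant order.
    """

    blocks: list[tuple[str, int, int]]
    scheme: str  # by_count | by_window | by_region
    parameter: object = None

    def __post_init__(self) -> None:
        prev_end = -1
        for chrom, s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty block {chrom}:{s}-{e}")
            if s < prev_end:
                raise ValueError("blocks overlap")
            prev_end = e

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def snp_indices(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(s, e) for _, s, e in self.blocks]
        ) if self.blocks else np.array([], dtype=int)


def _chrom_runs(gd: GenotypeData) -> list[tuple[str, int, int]]:
    chroms = gd.variants["chrom"].astype(str).to_numpy()
    runs = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            runs.append((chroms[start], start, i))
            start = i
    return runs


def blocks_by_count(gd: GenotypeData, k: int) -> BlockDefinition:
    """Consecutive runs of ``k`` SNPs per chromosome; the trailing partial
    run on each chromosome is kept as a smaller block."""
    if k < 2:
        raise ValueError("need at least 2 SNPs per block")
    blocks = []
    for chrom, s, e in _chrom_runs(gd):
        for b in range(s, e, k):
            blocks.append((chrom, b, min(b + k, e)))
    return BlockDefinition(blocks=blocks, scheme="by_count", parameter=k)


def blocks_by_window(gd: GenotypeData, width: int) -> BlockDefinition:
    """Fixed windows ``[c*width+1, (c+1)*width]`` from position 1 of each
    chromosome; windows without SNPs are dropped."""
    if width < 1:
        raise ValueError("window width must be >= 1 bp")
    pos = gd.variants["pos"].to_numpy()
    blocks = []
    for chrom, s, e in _chrom_runs(gd):
        win = (pos[s:e] - 1) // width
        start = s
        for i in range(s + 1, e + 1):
            if i == e or win[i - s] != win[start - s]:
                blocks.append((chrom, start, i))
                start = i
    return BlockDefinition(blocks=blocks, scheme="by_window", parameter=width)


def blocks_from_regions(
    gd: GenotypeData, regions: str | Path | pd.DataFrame
) -> BlockDefinition:
    """One block per (merged) region containing at least two SNPs.

    ``regions`` is a BED path or a frame with ``chrom, start, end`` in
    0-based half-open coordinates; they are converted to 1-based inclusive
    and overlapping regions are merged before SNPs are assigned.  SNPs
    outside every region are simply left out of the haplotype component.
    """
    if not isinstance(regions, pd.DataFrame):
        regions = pd.read_csv(regions, sep="\t", header=None, comment="#",
                              usecols=[0, 1, 2], names=["chrom", "start", "end"])
    reg = regions.copy()
    reg["chrom"] = reg["chrom"].astype(str)
    reg["start"] = reg["start"].astype(int) + 1  # to 1-based inclusive
    reg["end"] = reg["end"].astype(int)
    reg = reg.sort_values(["chrom", "start"]).reset_index(drop=True)

    merged: list[list] = []
    for row in reg.itertuples(index=False):
        if merged and merged[-1][0] == row.chrom and row.start <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], row.end)
        else:
            merged.append([row.chrom, row.start, row.end])

    pos = gd.variants["pos"].to_numpy()
    blocks = []
    for chrom, s, e in _chrom_runs(gd):
        p = pos[s:e]
        for rchrom, rstart, rend in merged:
            if rchrom != chrom:
                continue
            lo = s + int(np.searchsorted(p, rstart, side="left"))
            hi = s + int(np.searchsorted(p, rend, side="right"))
            if hi - lo >= 2:
                blocks.append((chrom, lo, hi))
    if not blocks:
        raise ValueError("no region contains two or more SNPs")
    blocks.sort(key=lambda b: b[1])
    return BlockDefinition(blocks=blocks, scheme="by_region", parameter="regions")


@dataclass
class HaplotypeAlleleTable:
    """Observed haplotype alleles per block and per-individual counts.

    ``counts`` is ``n x (total alleles over blocks)`` with entries in
    {0, 1, 2}; ``block_slices`` maps each block to its column range;
    ``alleles``/``frequencies`` list the allele strings and their sample
    frequencies per block.
    """

    sample_ids: list[str]
    counts: np.ndarray
    block_slices: list[slice]
    alleles: list[list[str]]
    frequencies: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.counts.shape[0] != n:
            raise ValueError("counts rows must match sample_ids")
        for sl in self.block_slices:
            rowsum = self.counts[:, sl].sum(axis=1)
            if not np.all(rowsum == 2):
                raise ValueError("per-block allele counts must sum to 2")

    @property
    def n_blocks(self) -> int:
        return len(self.block_slices)


def enumerate_haplotypes(
    gd: GenotypeData,
    bd: BlockDefinition,
    min_freq: float = 0.0,
) -> HaplotypeAlleleTable:
    """Enumerate the distinct phased haplotypes of every block.

    Alleles with sample frequency below ``min_freq`` are pooled into one
    "rare" allele per block (off by default).  Any unphased or missing
    call inside a block raises, naming the block.
    """
    n = gd.n_samples
    count_cols: list[np.ndarray] = []
    slices: list[slice] = []
    alleles_out: list[list[str]] = []
    freqs_out: list[np.ndarray] = []
    col = 0
    for chrom, s, e in bd.blocks:
        name = f"{chrom}:[{s},{e})"
        if not gd.phased[s:e].all():
            raise ValueError(f"unphased genotypes inside block {name}")
        H = gd.haplotypes[:, s:e, :]
        if (H < 0).any():
            raise ValueError(f"missing genotypes inside block {name}")
        gametes = H.transpose(0, 2, 1).reshape(2 * n, e - s)
        uniq, inverse = np.unique(gametes, axis=0, return_inverse=True)
        n_all = uniq.shape[0]
        counts = np.zeros((n, n_all), dtype=int)
        np.add.at(counts, (np.repeat(np.arange(n), 2), inverse.ravel()), 1)
        labels = ["".join(map(str, row)) for row in uniq]
        freq = counts.sum(axis=0) / (2 * n)
        if min_freq > 0 and (freq < min_freq).any() and (freq >= min_freq).any():
            rare = freq < min_freq
            pooled = counts[:, rare].sum(axis=1, keepdims=True)
            counts = np.hstack([counts[:, ~rare], pooled])
            labels = [l for l, r in zip(labels, rare) if not r] + ["rare"]
            freq = np.append(freq[~rare], freq[rare].sum())
        count_cols.append(counts)
        slices.append(slice(col, col + counts.shape[1]))
        col += counts.shape[1]
        alleles_out.append(labels)
        freqs_out.append(freq)
    return HaplotypeAlleleTable(
        sample_ids=list(gd.sample_ids),
        counts=np.hstack(count_cols),
        block_slices=slices,
        alleles=alleles_out,
        frequencies=freqs_out,
    )


def grm_haplotype(hat: HaplotypeAlleleTable) -> GRM:
    """Haplotype additive GRM from centered allele counts over all blocks."""
    if hat.n_blocks < 1:
        raise ValueError("need at least one block")
    C = hat.counts.astype(float)
    C = C - C.mean(axis=0, keepdims=True)
    raw = C @ C.T
    return normalize_grm(GRM(label="H", matrix=raw,
                             sample_ids=list(hat.sample_ids),
                             method="haplotype"))
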