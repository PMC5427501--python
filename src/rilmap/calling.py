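"""Sliding-window genotype calling and breakpoint detection.

Noisy per-SNP parental-origin calls are smoothed with the 15-SNP window
rule used for low-coverage RIL genotyping: a window whose Zhang gu : A2
ratio is 11:4 or higher is called Zhang gu, 4:11 or lower A2, anything
between heterozygous.  The window slides one SNP at a time; every SNP
receives a consensus over the windows containing it; maximal runs of
identical smoothed calls become genotype blocks and the boundary between
adjacent blocks is a recombination breakpoint, reported at the first SNP
of the downstream block with the full flanking-SNP interval retained.

Windows may contain heterozygous or missing calls.  Classification uses
informative (parental) calls only, with the printed thresholds scaled as
fractions of the informative count and a minimum informative count per
window; a window in which heterozygous calls hold an absolute majority
is classified heterozygous outright, so true heterozygous tracts keep
their boundaries.

The per-SNP consensus distinguishes the two ways a window can vote
heterozygous.  Around a crossover the middle band of the printed rule
fires on windows that mix the two parental genotypes, so a SNP in a
transition zone collects *conflicting* parental votes; there the
parental majority wins (ties -> heterozygous), which localizes clean
junctions to the exact flanking-SNP interval.  Inside and at the edge of
a real heterozygous tract only one parental class (at most) has any
windows, so when a SNP's parental votes are single-sided the larger of
that count and the heterozygous count wins (ties -> heterozygous), and
SNPs with only heterozygous votes are heterozygous.  SNPs covered by no
called window keep their raw call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import (
    A2,
    BREAKPOINT_COLUMNS,
    HET,
    MISSING,
    ZG,
    SNPCallMatrix,
    empty_breakpoint_table,
)

logger = logging.getLogger(__name__)

_UNCALLED = np.int8(-2)


@dataclass(frozen=True)
class WindowRule:
    """Window size and count thresholds of the sliding-window rule."""

    window_size: int = 15
    upper_count: int = 11
    lower_count: int = 4
    min_informative: int = 8
    min_block_snps: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.lower_count < self.upper_count <= self.window_size:
            raise ValueError("need 0 < lower_count < upper_count <= window_size")
        if not 0 < self.min_informative <= self.window_size:
            raise ValueError("min_informative out of range")


def classify_window(zg_count: int, a2_count: int,
                    rule: WindowRule = WindowRule()) -> int:
    """Classify one full window from its informative counts.

    Literal reading of the printed rule: Zhang gu when ``zg_count`` is at
    least ``upper_count``; A2 when ``zg_count`` is at most ``lower_count``
    and ``a2_count`` at least ``upper_count``; heterozygous otherwise.
    """
    if zg_count < 0 or a2_count < 0:
        raise ValueError("counts must be non-negative")
    if zg_count + a2_count > rule.window_size:
        raise ValueError("counts exceed window size")
    if zg_count >= rule.upper_count:
        return ZG
    if zg_count <= rule.lower_count and a2_count >= rule.upper_count:
        return A2
    return HET


def _sliding_sum(ind: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate([[0], np.cumsum(ind)])
    return cs[w:] - cs[:-w]


def _classify_windows(row: np.ndarray, rule: WindowRule) -> np.ndarray:
    """Classify every contiguous window of ``window_size`` SNPs."""
    w = rule.window_size
    czg = _sliding_sum((row == ZG).astype(np.int32), w)
    ca2 = _sliding_sum((row == A2).astype(np.int32), w)
    chet = _sliding_sum((row == HET).astype(np.int32), w)
    inf = czg + ca2
    wcls = np.full(czg.shape, _UNCALLED, dtype=np.int8)
    het_dom = 2 * chet > w
    wcls[het_dom] = HET
    callable_ = ~het_dom & (inf >= rule.min_informative)
    zg_w = callable_ & (czg * w >= rule.upper_count * inf)
    a2_w = callable_ & (czg * w <= rule.lower_count * inf)
    wcls[callable_] = HET
    wcls[zg_w] = ZG
    wcls[a2_w] = A2
    return wcls


def _vote_counts(wcls: np.ndarray, n_snps: int, w: int,
                 code: int) -> np.ndarray:
    """Per-SNP count of windows of a given class containing the SNP."""
    ind = (wcls == code).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(ind)])
    i = np.arange(n_snps)
    hi = np.clip(i, 0, len(wcls) - 1) + 1
    lo = np.clip(i - w + 1, 0, len(wcls) - 1)
    return cs[hi] - cs[lo]


def _smooth_row(row: np.ndarray, rule: WindowRule,
                label: str = "") -> np.ndarray:
    """Smooth one line-chromosome call vector."""
    n = row.size
    informative = int(np.count_nonzero((row == ZG) | (row == A2)))
    if informative == 0:
        if n:
            logger.warning("no informative SNPs for %s; all-Missing output",
                           label or "line-chromosome")
        return np.full(n, MISSING, dtype=np.int8)
    if informative < rule.window_size or n < rule.window_size:
        # too short for any window: whole chromosome takes the majority call
        n_zg = int(np.count_nonzero(row == ZG))
        n_a2 = informative - n_zg
        call = ZG if n_zg > n_a2 else A2 if n_a2 > n_zg else HET
        return np.full(n, call, dtype=np.int8)
    wcls = _classify_windows(row, rule)
    w = rule.window_size
    vz = _vote_counts(wcls, n, w, ZG)
    va = _vote_counts(wcls, n, w, A2)
    vh = _vote_counts(wcls, n, w, HET)
    out = row.copy()  # SNPs with no called window keep their raw call
    has = (vz + va + vh) > 0
    conflict = (vz > 0) & (va > 0)  # transition zone: parental majority
    zg = conflict & (vz > va)
    a2 = conflict & (va > vz)
    # single-sided parental evidence competes with heterozygous windows
    one_sided = has & ~conflict
    zg |= one_sided & (vz > vh)
    a2 |= one_sided & (va > vh)
    out[has] = HET
    out[zg] = ZG
    out[a2] = A2
    return out


def call_line_genotypes(
    calls: SNPCallMatrix, rule: WindowRule, line_id: str
) -> dict[str, np.ndarray]:
    """Smoothed per-SNP genotype sequence for one line, per chromosome."""
    li = calls.line_index(line_id)
    return {
        chrom: _smooth_row(calls.calls[chrom][li], rule,
                           label=f"{line_id}/{chrom}")
        for chrom in calls.chromosomes
    }


def smooth_population(calls: SNPCallMatrix,
                      rule: WindowRule = WindowRule()) -> SNPCallMatrix:
    """Window-smooth every line of the population."""
    out = calls.copy()
    for chrom in calls.chromosomes:
        mat = out.calls[chrom]
        for li in range(calls.n_lines):
            mat[li] = _smooth_row(mat[li], rule,
                                  label=f"{calls.line_ids[li]}/{chrom}")
    return out


@dataclass
class GenotypeBlock:
    """A maximal run of identical smoothed genotype on one chromosome."""

    line_id: str
    chromosome: str
    start_snp_index: int
    end_snp_index: int
    genotype: int
    supporting_snp_count: int


def blocks_and_breakpoints(
    smoothed: np.ndarray,
    positions: np.ndarray,
    line_id: str = "",
    chromosome: str = "",
    min_block_snps: int = 3,
) -> tuple[list[GenotypeBlock], pd.DataFrame]:
    """Group smoothed calls into blocks and derive breakpoints.

    Missing smoothed calls are skipped (they never split a block).
    Blocks supported by fewer than ``min_block_snps`` called SNPs are
    absorbed into their longer neighbour as a noise guard.  One
    breakpoint is emitted between each pair of adjacent blocks, spanning
    the last SNP of the upstream block to the first SNP of the
    downstream block and reported at the downstream position.
    """
    called_idx = np.nonzero(smoothed != MISSING)[0]
    if called_idx.size == 0:
        return [], empty_breakpoint_table()
    vals = smoothed[called_idx]
    starts = np.concatenate([[0], np.nonzero(vals[1:] != vals[:-1])[0] + 1])
    ends = np.concatenate([starts[1:] - 1, [vals.size - 1]])
    blocks = [
        {"geno": int(vals[s]), "lo": int(s), "hi": int(e)}
        for s, e in zip(starts, ends)
    ]

    def count(b):
        return b["hi"] - b["lo"] + 1

    def fuse(blks):
        out = [blks[0]]
        for b in blks[1:]:
            if b["geno"] == out[-1]["geno"]:
                out[-1]["hi"] = b["hi"]
            else:
                out.append(b)
        return out

    while len(blocks) > 1:
        sizes = [count(b) for b in blocks]
        k = int(np.argmin(sizes))
        if sizes[k] >= min_block_snps:
            break
        if k == 0:
            nb = 1
        elif k == len(blocks) - 1:
            nb = k - 1
        else:
            nb = k - 1 if count(blocks[k - 1]) >= count(blocks[k + 1]) else k + 1
        blocks[k]["geno"] = blocks[nb]["geno"]
        blocks = fuse(blocks)

    out_blocks = [
        GenotypeBlock(
            line_id=line_id,
            chromosome=chromosome,
            start_snp_index=int(called_idx[b["lo"]]),
            end_snp_index=int(called_idx[b["hi"]]),
            genotype=b["geno"],
            supporting_snp_count=count(b),
        )
        for b in blocks
    ]
    rows = []
    for up, dn in zip(out_blocks[:-1], out_blocks[1:]):
        lo = int(positions[up.end_snp_index])
        hi = int(positions[dn.start_snp_index])
        rows.append((line_id, chromosome, lo, hi, hi, up.genotype, dn.genotype))
    bps = pd.DataFrame(rows, columns=BREAKPOINT_COLUMNS) if rows \
        else empty_breakpoint_table()
    return out_blocks, bps


def population_breakpoints(
    smoothed: SNPCallMatrix, min_block_snps: int = 3
) -> tuple[list[GenotypeBlock], pd.DataFrame]:
    """Blocks and breakpoints for every line-chromosome of the population."""
    all_blocks: list[GenotypeBlock] = []
    tables = []
    for chrom in smoothed.chromosomes:
        pos = smoothed.positions[chrom]
        for li, line in enumerate(smoothed.line_ids):
            blocks, bps = blocks_and_breakpoints(
                smoothed.calls[chrom][li], pos, line, chrom, min_block_snps
            )
            all_blocks.extend(blocks)
            if len(bps):
                tables.append(bps)
    table = pd.concat(tables, ignore_index=True) if tables \
        else empty_breakpoint_table()
    return all_blocks, table
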