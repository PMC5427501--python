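"""Recombination-bin construction from population-wide breakpoints.

Breakpoint positions from all lines are pooled per chromosome and
positions closer than a minimal interval (default 50 kb) are merged by
single-linkage clustering, each cluster replaced by its midpoint.  The
resulting boundaries partition each chromosome into candidate intervals;
each line's genotype in an interval is the consensus of its smoothed SNP
calls there; adjacent intervals whose genotype columns agree across the
whole population are merged.  The maximal intervals are the
recombination bins, named bin1..binK in genome order, and serve as the
markers of the genetic map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import A2, HET, MISSING, ZG, SNPCallMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinSpec:
    """Minimal distance between distinct recombination positions (bp)."""

    min_interval: int = 50_000

    def __post_init__(self) -> None:
        if self.min_interval <= 0:
            raise ValueError("min_interval must be > 0")


@dataclass
class BinMatrix:
    """Genome partition into recombination bins with per-line genotypes."""

    bins: pd.DataFrame  # chromosome, bin_name, start_bp, end_bp, size_bp
    geno: np.ndarray  # (n_lines, n_bins) int8
    line_ids: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chromosome"]))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.nonzero((self.bins["chromosome"] == chrom).to_numpy())[0]


def merge_breakpoints(
    breakpoints: pd.DataFrame,
    spec: BinSpec = BinSpec(),
    chromosomes: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Pool breakpoint positions and collapse clusters closer than
    ``min_interval`` to their (rounded) midpoints, per chromosome."""
    if chromosomes is None:
        chromosomes = list(dict.fromkeys(breakpoints["chromosome"]))
    out: dict[str, np.ndarray] = {}
    for chrom in chromosomes:
        pos = np.sort(
            breakpoints.loc[breakpoints["chromosome"] == chrom,
                            "reported_position"].to_numpy(dtype=np.int64)
        )
        if pos.size == 0:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        splits = np.nonzero(np.diff(pos) >= spec.min_interval)[0] + 1
        merged = [
            int(round((c[0] + c[-1]) / 2)) for c in np.split(pos, splits)
        ]
        out[chrom] = np.array(sorted(set(merged)), dtype=np.int64)
    return out


def _interval_consensus(
    sub: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-line consensus genotype of a SNP-call slice (lines x snps)."""
    counts = np.stack([(sub == code).sum(axis=1) for code in (A2, HET, ZG)])
    nm = counts.sum(axis=0)
    top = counts.max(axis=0)
    top_code = np.array([A2, HET, ZG], dtype=np.int8)[counts.argmax(axis=0)]
    unique_top = (counts == top).sum(axis=0) == 1
    ok = (nm > 0) & unique_top & (top >= threshold * nm)
    out = np.full(sub.shape[0], MISSING, dtype=np.int8)
    out[ok] = top_code[ok]
    return out


def build_bins(
    boundaries: dict[str, np.ndarray],
    calls: SNPCallMatrix,
    consensus_threshold: float = 1.0,
) -> BinMatrix:
    """Turn merged boundaries plus smoothed calls into the bin matrix.

    ``consensus_threshold`` is the fraction of a line's non-missing calls
    in an interval that must agree for the interval to receive that
    genotype (otherwise Missing).  The default 1.0 guarantees that the
    bin matrix reproduces the smoothed calls exactly wherever a bin
    genotype is assigned; lower it for unsmoothed input.
    """
    bin_rows = []
    geno_cols = []
    for chrom in calls.chromosomes:
        pos = calls.positions[chrom]
        mat = calls.calls[chrom]
        length = calls.chrom_lengths[chrom]
        cuts = [int(b) for b in boundaries.get(chrom, ()) if 1 < b <= length]
        # interval i spans [starts[i], ends[i]] inclusive
        while True:
            starts = np.array([1] + cuts, dtype=np.int64)
            ends = np.array(cuts + [length], dtype=np.int64) - np.array(
                [1] * len(cuts) + [0], dtype=np.int64
            )
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, ends, side="right")
            empty = np.nonzero(hi - lo == 0)[0]
            if empty.size == 0 or not cuts:
                break
            i = int(empty[0])  # merge toward chromosome start
            drop = cuts[i - 1] if i > 0 else cuts[0]
            logger.info("interval with zero SNPs on %s; dropping boundary %d",
                        chrom, drop)
            cuts.remove(drop)
        cols = [
            _interval_consensus(mat[:, lo[i]:hi[i]], consensus_threshold)
            for i in range(len(starts))
        ]
        # merge adjacent intervals with identical genotype columns
        k = 0
        m_starts, m_ends, m_cols = [int(starts[0])], [int(ends[0])], [cols[0]]
        for i in range(1, len(cols)):
            if np.array_equal(cols[i], m_cols[k]):
                m_ends[k] = int(ends[i])
            else:
                m_starts.append(int(starts[i]))
                m_ends.append(int(ends[i]))
                m_cols.append(cols[i])
                k += 1
        for s, e, c in zip(m_starts, m_ends, m_cols):
            bin_rows.append((chrom, s, e, e - s + 1))
            geno_cols.append(c)
    bins = pd.DataFrame(bin_rows,
                        columns=["chromosome", "start_bp", "end_bp", "size_bp"])
    bins.insert(1, "bin_name", [f"bin{i + 1}" for i in range(len(bins))])
    return BinMatrix(bins=bins, geno=np.column_stack(geno_cols),
                     line_ids=list(calls.line_ids))


def bin_summary(bm: BinMatrix) -> pd.DataFrame:
    """Bin count and size range per chromosome and genome-wide."""
    if bm.n_bins == 0:
        raise ValueError("empty BinMatrix")
    rows = []
    for chrom in bm.chromosomes:
        sizes = bm.bins.loc[bm.bins["chromosome"] == chrom, "size_bp"]
        rows.append((chrom, len(sizes), int(sizes.min()), int(sizes.max()),
                     float(sizes.mean())))
    sizes = bm.bins["size_bp"]
    rows.append(("genome", len(sizes), int(sizes.min()), int(sizes.max()),
                 float(sizes.mean())))
    return pd.DataFrame(
        rows, columns=["chromosome", "n_bins", "min_size_bp", "max_size_bp",
                       "mean_size_bp"]
    ).set_index("chromosome")


def reconstruct_snp_calls(bm: BinMatrix, template: SNPCallMatrix) -> SNPCallMatrix:
    """Expand bin genotypes back onto the template's SNP grid."""
    out = template.copy()
    for chrom in template.chromosomes:
        pos = template.positions[chrom]
        idx = bm.chrom_slice(chrom)
        starts = bm.bins["start_bp"].to_numpy()[idx]
        which = np.searchsorted(starts, pos, side="right") - 1
        out.calls[chrom] = bm.geno[:, idx[np.clip(which, 0, len(idx) - 1)]]
    return out
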