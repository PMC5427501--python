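"""Core genotype containers shared by every pipeline stage.

Parental-origin calls are stored as small integers so that arithmetic on
them is cheap and the additive genotype score is simply ``call - 1``:

=========  =====  ==============================================
constant   value  meaning
=========  =====  ==============================================
A2             0  homozygous for the A2 (female parent) allele
HET            1  heterozygous
ZG             2  homozygous for the Zhang gu allele
MISSING       -1  no call
=========  =====  ==============================================

The on-disk "ab" dialect uses the letters a/h/b/- in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A2: int = 0
HET: int = 1
ZG: int = 2
MISSING: int = -1

#: integer call -> ab-dialect letter
CODE_TO_LETTER = {A2: "a", HET: "h", ZG: "b", MISSING: "-"}
LETTER_TO_CODE = {v: k for k, v in CODE_TO_LETTER.items()}

#: columns of a breakpoint table (one row per breakpoint)
BREAKPOINT_COLUMNS = [
    "line_id",
    "chromosome",
    "interval_start",
    "interval_end",
    "reported_position",
    "upstream_genotype",
    "downstream_genotype",
]


def empty_breakpoint_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "line_id": pd.Series(dtype=object),
            "chromosome": pd.Series(dtype=object),
            "interval_start": pd.Series(dtype=np.int64),
            "interval_end": pd.Series(dtype=np.int64),
            "reported_position": pd.Series(dtype=np.int64),
            "upstream_genotype": pd.Series(dtype=np.int8),
            "downstream_genotype": pd.Series(dtype=np.int8),
        }
    )


@dataclass
class SNPCallMatrix:
    """Per-line, per-SNP parental-origin calls on physical coordinates.

    Parameters
    ----------
    line_ids
        Ordered sample identifiers (rows of every call matrix).
    chromosomes
        Ordered chromosome labels.
    positions
        Per chromosome, strictly increasing 1-based SNP positions (int64).
    calls
        Per chromosome, an ``(n_lines, n_snps)`` int8 matrix of calls.
    chrom_lengths
        Physical length (bp) per chromosome; defaults to the last SNP
        position when not given.
    a2_alleles
        Optional per-SNP nucleotide of the A2 parent, carried through the
        ab dialect round trip.
    """

    line_ids: list[str]
    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    calls: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    a2_alleles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            self.positions[chrom] = pos
            mat = np.asarray(self.calls[chrom], dtype=np.int8)
            if mat.shape != (len(self.line_ids), pos.size):
                raise ValueError(
                    f"call matrix shape {mat.shape} does not match "
                    f"({len(self.line_ids)}, {pos.size}) on {chrom}"
                )
            bad = ~np.isin(mat, (A2, HET, ZG, MISSING))
            if bad.any():
                raise ValueError(f"invalid genotype codes on {chrom}")
            self.calls[chrom] = mat
            self.chrom_lengths.setdefault(
                chrom, int(pos[-1]) if pos.size else 0
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def n_snps(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(p.size for p in self.positions.values()))

    def line_index(self, line_id: str) -> int:
        return self.line_ids.index(line_id)

    def copy(self) -> "SNPCallMatrix":
        return SNPCallMatrix(
            line_ids=list(self.line_ids),
            chromosomes=list(self.chromosomes),
            positions={c: p.copy() for c, p in self.positions.items()},
            calls={c: m.copy() for c, m in self.calls.items()},
            chrom_lengths=dict(self.chrom_lengths),
            a2_alleles={c: a.copy() for c, a in self.a2_alleles.items()},
        )
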