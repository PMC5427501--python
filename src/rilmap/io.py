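"""Readers and writers for the pipeline's table dialects.

The canonical genotype input is the "ab" dialect: one whitespace- or
tab-delimited text file per line (sample), one row per SNP with columns
chromosome, 1-based position, A2 parental allele, and sample code, where
``a`` means the sample matches A2, ``b`` Zhang gu, ``h`` heterozygous,
and ``-`` missing.  Breakpoints are written one row per line-chromosome
as position-genotype tokens such as ``6506087-b``.  Bin descriptions,
bin genotypes, linkage maps, scan curves, and QTL reports are plain TSV;
traits are CSV; configuration is a flat YAML mapping.  Every writer has
a paired reader that accepts its output unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binmap import BinMatrix
from .genotypes import (
    BREAKPOINT_COLUMNS,
    CODE_TO_LETTER,
    LETTER_TO_CODE,
    MISSING,
    SNPCallMatrix,
    empty_breakpoint_table,
)
from .linkage import LinkageMap
from .sim import TraitTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input row, with positional diagnostics."""


# --- ab genotype dialect -----------------------------------------------------

def read_ab(files: dict[str, Path | str]) -> SNPCallMatrix:
    """Read one ab file per line into a call matrix.

    ``files`` maps line_id -> path.  All files must agree on the SNP
    set; rows are sorted by (chromosome, position) with a warning if any
    file is unsorted, and duplicate positions within a chromosome are
    rejected.
    """
    if not files:
        raise ValueError("no input files")
    per_line: dict[str, pd.DataFrame] = {}
    for line_id, path in files.items():
        rows = []
        with open(path) as fh:
            for lineno, text in enumerate(fh, start=1):
                text = text.strip()
                if not text or text.startswith("#"):
                    continue
                parts = text.split()
                if len(parts) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                    )
                chrom, pos_s, a2_allele, code = parts
                if code not in LETTER_TO_CODE:
                    raise FormatError(
                        f"{path}:{lineno}: unknown genotype code {code!r}"
                    )
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad position {pos_s!r}"
                    ) from exc
                rows.append((chrom, pos, a2_allele, LETTER_TO_CODE[code]))
        df = pd.DataFrame(rows, columns=["chromosome", "position",
                                         "a2_allele", "call"])
        if len(df):
            sorted_df = df.sort_values(
                ["chromosome", "position"], kind="stable"
            ).reset_index(drop=True)
            if not df["position"].equals(sorted_df["position"]) or \
                    not df["chromosome"].equals(sorted_df["chromosome"]):
                logger.warning("unsorted ab input %s; sorting", path)
            df = sorted_df
            dup = df.duplicated(["chromosome", "position"])
            if dup.any():
                first = df[dup].iloc[0]
                raise FormatError(
                    f"{path}: duplicate position {first['chromosome']}:"
                    f"{first['position']}"
                )
        per_line[str(line_id)] = df

    line_ids = list(per_line)
    ref = per_line[line_ids[0]]
    chromosomes = list(dict.fromkeys(ref["chromosome"]))
    positions = {
        c: ref.loc[ref["chromosome"] == c, "position"].to_numpy(np.int64)
        for c in chromosomes
    }
    a2_alleles = {
        c: ref.loc[ref["chromosome"] == c, "a2_allele"].to_numpy()
        for c in chromosomes
    }
    calls = {
        c: np.full((len(line_ids), positions[c].size), MISSING, dtype=np.int8)
        for c in chromosomes
    }
    for li, line_id in enumerate(line_ids):
        df = per_line[line_id]
        for c in dict.fromkeys(df["chromosome"]):
            if c not in positions:
                raise FormatError(f"line {line_id}: unexpected chromosome {c}")
            sub = df[df["chromosome"] == c]
            pos = sub["position"].to_numpy(np.int64)
            idx = np.searchsorted(positions[c], pos)
            if (idx >= positions[c].size).any() or \
                    (positions[c][np.clip(idx, 0, None)] != pos).any():
                raise FormatError(
                    f"line {line_id}: SNP set differs from {line_ids[0]} on {c}"
                )
            calls[c][li, idx] = sub["call"].to_numpy(np.int8)
    return SNPCallMatrix(line_ids=line_ids, chromosomes=chromosomes,
                         positions=positions, calls=calls,
                         a2_alleles=a2_alleles)


def write_ab(calls: SNPCallMatrix, directory: Path | str) -> dict[str, Path]:
    """Write one ``<line_id>.ab`` file per line; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for li, line_id in enumerate(calls.line_ids):
        path = directory / f"{line_id}.ab"
        with open(path, "w") as fh:
            for chrom in calls.chromosomes:
                pos = calls.positions[chrom]
                alleles = calls.a2_alleles.get(
                    chrom, np.full(pos.size, "A", dtype="<U1")
                )
                row = calls.calls[chrom][li]
                for p, al, c in zip(pos, alleles, row):
                    fh.write(f"{chrom}\t{p}\t{al}\t{CODE_TO_LETTER[int(c)]}\n")
        paths[line_id] = path
    return paths


# --- breakpoint tables -------------------------------------------------------

def write_breakpoints(
    breakpoints: pd.DataFrame,
    path: Path | str,
    line_ids: list[str] | None = None,
    chromosomes: list[str] | None = None,
) -> None:
    """One row per line-chromosome: ids then ``position-genotype`` tokens.

    When ``line_ids``/``chromosomes`` are given, every combination gets
    a row even if it has no breakpoints (ids-only row), so
    non-recombinant chromosomes remain visible in the table.
    """
    bp = breakpoints.sort_values(
        ["line_id", "chromosome", "reported_position"], kind="stable"
    )
    groups = {k: g for k, g in bp.groupby(["line_id", "chromosome"],
                                          sort=True)}
    if line_ids is None:
        keys = sorted(groups)
    else:
        chroms = chromosomes or sorted({c for _, c in groups})
        keys = [(l, c) for l in line_ids for c in chroms]
    with open(path, "w") as fh:
        for line_id, chrom in keys:
            grp = groups.get((line_id, chrom))
            tokens = [] if grp is None else [
                f"{int(r.reported_position)}-"
                f"{CODE_TO_LETTER[int(r.downstream_genotype)]}"
                for r in grp.itertuples()
            ]
            fh.write("\t".join([str(line_id), str(chrom)] + tokens) + "\n")


def read_breakpoints(path: Path | str) -> pd.DataFrame:
    """Parse a breakpoint table back into breakpoint rows.

    The token format records the reported position and downstream
    genotype only, so interval bounds and upstream genotypes are
    restored as far as the dialect allows: ``interval_start`` of the
    first breakpoint is unknown (0) and each subsequent breakpoint's
    upstream genotype is the previous token's genotype.
    """
    rows = []
    with open(path) as fh:
        for lineno, text in enumerate(fh, start=1):
            text = text.rstrip("\n")
            if not text.strip():
                continue
            parts = text.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected id and "
                                  "chromosome columns")
            line_id, chrom, tokens = parts[0], parts[1], parts[2:]
            prev_geno = MISSING
            prev_pos = 0
            for tok in tokens:
                try:
                    pos_s, code = tok.rsplit("-", 1)
                    pos = int(pos_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: bad token {tok!r}"
                    ) from exc
                if code not in LETTER_TO_CODE:
                    raise FormatError(
                        f"{path}:{lineno}: unknown genotype in {tok!r}"
                    )
                rows.append((line_id, chrom, prev_pos, pos, pos, prev_geno,
                             LETTER_TO_CODE[code]))
                prev_geno = LETTER_TO_CODE[code]
                prev_pos = pos
    if not rows:
        return empty_breakpoint_table()
    return pd.DataFrame(rows, columns=BREAKPOINT_COLUMNS)


# --- bin tables --------------------------------------------------------------

def write_bins(bm: BinMatrix, path: Path | str) -> None:
    """Bin descriptions: chromosome, name, start, end, size (TSV)."""
    bm.bins.to_csv(path, sep="\t", index=False)


def write_bin_genotypes(bm: BinMatrix, path: Path | str) -> None:
    """Line x bin genotype matrix in a/b/h/- codes (TSV)."""
    letters = np.vectorize(CODE_TO_LETTER.get)(bm.geno)
    df = pd.DataFrame(letters, index=pd.Index(bm.line_ids, name="line_id"),
                      columns=bm.bins["bin_name"])
    df.to_csv(path, sep="\t")


def read_bin_matrix(bins_path: Path | str,
                    genotypes_path: Path | str) -> BinMatrix:
    """Rebuild a BinMatrix from its two written tables."""
    bins = pd.read_csv(bins_path, sep="\t", float_precision="round_trip")
    geno_df = pd.read_csv(genotypes_path, sep="\t", index_col=0)
    if list(geno_df.columns) != list(bins["bin_name"]):
        raise FormatError("bin genotype columns do not match bin table")
    geno = np.vectorize(LETTER_TO_CODE.get)(
        geno_df.to_numpy(dtype="<U1")
    ).astype(np.int8)
    return BinMatrix(bins=bins, geno=geno,
                     line_ids=[str(i) for i in geno_df.index])


# --- linkage map, traits, scans ----------------------------------------------

def write_map(lmap: LinkageMap, path: Path | str) -> None:
    lmap.table.to_csv(path, sep="\t", index=False)


def read_map(path: Path | str,
             mapping_function: str = "kosambi") -> LinkageMap:
    return LinkageMap(table=pd.read_csv(path, sep="\t",
                                    float_precision="round_trip"),
                      mapping_function=mapping_function)


def write_traits(tt: TraitTable, path: Path | str) -> None:
    tt.values.to_csv(path)


def read_traits(path: Path | str, environment: str = "other") -> TraitTable:
    return TraitTable(values=pd.read_csv(path, index_col="line_id",
                                      float_precision="round_trip"),
                      environment=environment)


def write_scan(table: pd.DataFrame, path: Path | str) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_qtl_report(report: pd.DataFrame, path: Path | str) -> None:
    report.to_csv(path, sep="\t", index=False)


# --- optional VCF import -----------------------------------------------------

def vcf_to_ab(
    vcf_path: Path | str,
    parent_a2: str,
    parent_zg: str,
) -> SNPCallMatrix:
    """Thin converter from a VCF to ab-dialect calls.

    Keeps biallelic SNV sites at which the two parent samples are
    homozygous for different alleles; every other sample's genotype is
    then coded relative to the parents (matches A2 -> a, matches Zhang
    gu -> b, heterozygous -> h, otherwise missing).  The ab dialect
    remains the canonical input; this exists for populations whose
    upstream calling produced a joint VCF.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for parent in (parent_a2, parent_zg):
        if parent not in samples:
            raise FormatError(f"parent sample {parent!r} not in VCF")
    ia, ib = samples.index(parent_a2), samples.index(parent_zg)
    progeny = [s for s in samples if s not in (parent_a2, parent_zg)]
    prog_idx = [samples.index(s) for s in progeny]
    by_chrom: dict[str, list] = {}
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gts = var.genotype.array()[:, :2]
        pa, pb = gts[ia], gts[ib]
        if (pa < 0).any() or (pb < 0).any():
            continue
        if pa[0] != pa[1] or pb[0] != pb[1] or pa[0] == pb[0]:
            continue  # parents must be homozygous and different
        codes = np.full(len(prog_idx), MISSING, dtype=np.int8)
        for k, i in enumerate(prog_idx):
            g = gts[i]
            if (g < 0).any():
                continue
            if g[0] == g[1] == pa[0]:
                codes[k] = LETTER_TO_CODE["a"]
            elif g[0] == g[1] == pb[0]:
                codes[k] = LETTER_TO_CODE["b"]
            elif set(g) == {pa[0], pb[0]}:
                codes[k] = LETTER_TO_CODE["h"]
        by_chrom.setdefault(var.CHROM, []).append(
            (var.POS, var.REF if pa[0] == 0 else var.ALT[0], codes)
        )
    chromosomes = list(by_chrom)
    positions, a2_alleles, calls = {}, {}, {}
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: r[0])
        positions[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
        a2_alleles[chrom] = np.array([r[1] for r in rows])
        calls[chrom] = np.column_stack([r[2] for r in rows]) if rows \
            else np.empty((len(progeny), 0), dtype=np.int8)
    return SNPCallMatrix(line_ids=progeny, chromosomes=chromosomes,
                         positions=positions, calls=calls,
                         a2_alleles=a2_alleles)


# --- configuration -----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration of every pipeline stage."""

    # simulation
    n_chromosomes: int = 9
    chrom_physical_length: float = 44_000_000
    chrom_genetic_length: float = 2.15
    n_snps: int = 3731
    n_lines: int = 439
    final_generation: int = 10
    call_error_rate: float = 0.01
    missing_rate: float = 0.2
    # calling
    window_size: int = 15
    upper_count: int = 11
    lower_count: int = 4
    min_informative: int = 8
    min_block_snps: int = 3
    # binning
    min_interval: int = 50_000
    consensus_threshold: float = 1.0
    # mapping
    mapping_function: str = "kosambi"
    min_lines_two_point: int = 20
    # scanning
    grid_step: float = 1.0
    n_cofactors: int = 5
    blocking_window: float = 10.0
    n_perm: int = 1000
    alpha: float = 0.05
    min_lines_scan: int = 30
    # shared
    rng_seed: int = 0
    traits: list = field(default_factory=list)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
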