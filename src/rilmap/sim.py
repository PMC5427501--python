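"""Synthetic biparental RIL populations with known crossover truth.

The generator emulates the mapping population the downstream pipeline
expects: an F1 from a Zhang gu x A2 cross selfed by single seed descent
(one offspring per line per generation, no selection) to a target
generation, with crossovers per meiosis drawn Poisson with mean equal to
the chromosome's genetic length in Morgans (Haldane model, no
interference) and crossover positions uniform on the genetic map.  The
cM<->bp relation is linear by default and piecewise linear when anchor
points are supplied, so recombination deserts can be emulated.

Everything downstream of meiosis is deterministic given the RNG seed, so
all outputs are byte-identical across runs with the same specs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import A2, HET, MISSING, ZG, SNPCallMatrix, BREAKPOINT_COLUMNS


def _per_chrom(value, n: int, name: str) -> list:
    """Broadcast a scalar or validate a per-chromosome list."""
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return value


@dataclass
class GenomeSpec:
    """Physical and genetic geometry of the simulated genome.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes (>= 1).
    chrom_physical_length
        Physical length in bp, scalar or per chromosome.
    chrom_genetic_length
        Genetic length in Morgans, scalar or per chromosome.  0 is legal
        and yields no crossovers on that chromosome.
    n_snps
        Parental SNPs per chromosome, scalar or per chromosome; ignored
        when ``snp_positions`` is given.
    snp_positions
        Optional explicit 1-based SNP positions per chromosome label.
    recomb_anchors
        Optional per-chromosome piecewise cM<->bp anchors, a list of
        ``(bp, morgan)`` pairs that must start at (0, 0) and end at
        (physical length, genetic length).  Default is a linear relation.
    """

    n_chromosomes: int = 9
    chrom_physical_length: float | list = 44_000_000
    chrom_genetic_length: float | list = 2.15
    n_snps: int | list = 3731
    snp_positions: dict[str, np.ndarray] | None = None
    recomb_anchors: dict[str, list[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        self.chromosomes = [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]
        self._phys = dict(
            zip(
                self.chromosomes,
                [int(v) for v in _per_chrom(
                    self.chrom_physical_length, self.n_chromosomes,
                    "chrom_physical_length")],
            )
        )
        self._gen = dict(
            zip(
                self.chromosomes,
                [float(v) for v in _per_chrom(
                    self.chrom_genetic_length, self.n_chromosomes,
                    "chrom_genetic_length")],
            )
        )
        if any(v <= 0 for v in self._phys.values()):
            raise ValueError("physical lengths must be > 0")
        if any(v < 0 for v in self._gen.values()):
            raise ValueError("genetic lengths must be >= 0")
        self._n_snps = dict(
            zip(
                self.chromosomes,
                [int(v) for v in _per_chrom(
                    self.n_snps, self.n_chromosomes, "n_snps")],
            )
        )
        if self.snp_positions is not None:
            for chrom, pos in self.snp_positions.items():
                pos = np.asarray(pos, dtype=np.int64)
                if pos.size and (
                    np.any(np.diff(pos) <= 0)
                    or pos[0] < 1
                    or pos[-1] > self._phys[chrom]
                ):
                    raise ValueError(f"bad SNP positions on {chrom}")
                self.snp_positions[chrom] = pos
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self.chromosomes:
            if self.recomb_anchors and chrom in self.recomb_anchors:
                pts = np.asarray(self.recomb_anchors[chrom], dtype=float)
                bp, mo = pts[:, 0], pts[:, 1]
                if (
                    bp[0] != 0
                    or mo[0] != 0
                    or bp[-1] != self._phys[chrom]
                    or not np.isclose(mo[-1], self._gen[chrom])
                    or np.any(np.diff(bp) <= 0)
                    or np.any(np.diff(mo) < 0)
                ):
                    raise ValueError(f"bad recombination anchors on {chrom}")
            else:
                bp = np.array([0.0, self._phys[chrom]])
                mo = np.array([0.0, self._gen[chrom]])
            self._anchors[chrom] = (bp, mo)

    def physical_length(self, chrom: str) -> int:
        return self._phys[chrom]

    def genetic_length(self, chrom: str) -> float:
        """Genetic length in Morgans."""
        return self._gen[chrom]

    def bp_to_morgan(self, chrom: str, bp) -> np.ndarray:
        b, m = self._anchors[chrom]
        return np.interp(np.asarray(bp, dtype=float), b, m)

    def morgan_to_bp(self, chrom: str, morgan) -> np.ndarray:
        b, m = self._anchors[chrom]
        return np.interp(np.asarray(morgan, dtype=float), m, b)


@dataclass
class PopulationSpec:
    """Population size, inbreeding depth, and call-degradation rates."""

    n_lines: int = 439
    final_generation: int = 10  # F-number; F10 = 9 selfing meioses past F1
    call_error_rate: float = 0.01
    missing_rate: float = 0.2
    rng_seed: int = 0
    #: optional (chromosome label, position in cM, P(transmit Zhang gu))
    #: gamete-transmission bias hook for segregation-distortion tests
    distortion_locus: tuple[str, float, float] | None = None

    def __post_init__(self) -> None:
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2")
        for r in (self.call_error_rate, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.distortion_locus is not None:
            tau = self.distortion_locus[2]
            if not 0 < tau < 1:
                raise ValueError("transmission bias must lie in (0, 1)")


@dataclass
class TraitSpec:
    """A multi-QTL additive trait for one environment.

    ``planted_qtl`` holds ``(chromosome, position_cM, additive_effect)``
    triples; a positive effect means the Zhang gu allele increases the
    trait (the sign convention used throughout the package).
    """

    trait_name: str
    planted_qtl: list[tuple[str, float, float]]
    residual_sd: float = 1.0
    environment_label: str = "long_day"

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass
class TraitTable:
    """Line-by-trait phenotype values for one environment."""

    values: pd.DataFrame  # index: line_id, columns: trait names
    environment: str = "other"


# --- meiosis -----------------------------------------------------------------
# A haplotype on one chromosome is (ends, alleles): ``ends`` ascending with
# ends[-1] == genetic length L, segment i covering (ends[i-1], ends[i]].

def _gamete(hap_a, hap_b, length: float, rng: np.random.Generator):
    n_xo = rng.poisson(length) if length > 0 else 0
    cur = int(rng.integers(2))
    haps = (hap_a, hap_b)
    if n_xo == 0:
        ends, alleles = haps[cur]
        return ends.copy(), alleles.copy()
    cuts = np.unique(rng.random(n_xo) * length)
    out_ends: list[float] = []
    out_alleles: list[int] = []
    prev = 0.0
    for cut in itertools.chain(cuts, (length,)):
        if cut > prev:
            ends, alleles = haps[cur]
            first = np.searchsorted(ends, prev, side="right")
            last = np.searchsorted(ends, cut, side="left")
            for i in range(first, last):
                out_ends.append(float(ends[i]))
                out_alleles.append(int(alleles[i]))
            out_ends.append(float(cut))
            out_alleles.append(int(alleles[min(last, len(alleles) - 1)]))
        cur ^= 1
        prev = cut
    # fuse equal-allele neighbours
    ends_arr = np.array(out_ends)
    all_arr = np.array(out_alleles, dtype=np.int8)
    keep = np.append(all_arr[1:] != all_arr[:-1], True)
    return ends_arr[keep], all_arr[keep]


def _allele_at(hap, pos: float) -> int:
    ends, alleles = hap
    return int(alleles[min(np.searchsorted(ends, pos, side="left"),
                           len(alleles) - 1)])


def _diplotype_segments(hap_a, hap_b):
    """Merge two haplotypes into genotype segments (ends, genotypes)."""
    ends = np.unique(np.concatenate([hap_a[0], hap_b[0]]))
    idx_a = np.searchsorted(hap_a[0], ends, side="left")
    idx_b = np.searchsorted(hap_b[0], ends, side="left")
    geno = hap_a[1][np.minimum(idx_a, len(hap_a[1]) - 1)].astype(np.int8) + \
        hap_b[1][np.minimum(idx_b, len(hap_b[1]) - 1)].astype(np.int8)
    keep = np.append(geno[1:] != geno[:-1], True)
    return ends[keep], geno[keep]


def simulate_ril_population(
    genome: GenomeSpec, pop: PopulationSpec
) -> tuple[SNPCallMatrix, pd.DataFrame]:
    """Simulate an SSD RIL population; return error-free truth.

    Returns
    -------
    truth : SNPCallMatrix
        Complete (no Missing) parental-origin calls per line and SNP.
    true_breakpoints : pandas.DataFrame
        One row per realized junction in each line's final genotype
        mosaic, with continuous physical position (``position_bp``),
        genetic position in cM, and flanking genotypes.  Junction
        positions are strictly increasing within each line-chromosome.
    """
    rng = np.random.default_rng(pop.rng_seed)
    positions: dict[str, np.ndarray] = {}
    for chrom in genome.chromosomes:
        if genome.snp_positions is not None and chrom in genome.snp_positions:
            pos = genome.snp_positions[chrom]
        else:
            n = genome._n_snps[chrom]
            pos = np.sort(
                rng.choice(genome.physical_length(chrom), size=n, replace=False)
            ).astype(np.int64) + 1
        if pos.size == 0:
            raise ValueError(f"chromosome {chrom} has zero SNPs")
        positions[chrom] = pos
    snp_morgans = {
        c: genome.bp_to_morgan(c, positions[c]) for c in genome.chromosomes
    }

    line_ids = [f"RIL{i + 1:03d}" for i in range(pop.n_lines)]
    calls = {
        c: np.empty((pop.n_lines, positions[c].size), dtype=np.int8)
        for c in genome.chromosomes
    }
    bp_rows: list[tuple] = []

    dist = pop.distortion_locus
    for li, line in enumerate(line_ids):
        for chrom in genome.chromosomes:
            length = genome.genetic_length(chrom)
            hap_a = (np.array([length]), np.array([1], dtype=np.int8))  # ZG
            hap_b = (np.array([length]), np.array([0], dtype=np.int8))  # A2
            plant = (hap_a, hap_b)  # F1
            bias = None
            if dist is not None and dist[0] == chrom:
                bias = (dist[1] / 100.0, dist[2])  # cM -> Morgans
            for _ in range(pop.final_generation - 1):
                gametes = []
                for _g in range(2):
                    while True:
                        g = _gamete(plant[0], plant[1], length, rng)
                        if bias is None:
                            break
                        tau = bias[1]
                        p_acc = tau if _allele_at(g, bias[0]) == 1 else 1 - tau
                        if rng.random() < p_acc / max(tau, 1 - tau):
                            break
                    gametes.append(g)
                plant = (gametes[0], gametes[1])
            ends, geno = _diplotype_segments(plant[0], plant[1])
            gm = snp_morgans[chrom]
            seg = np.minimum(
                np.searchsorted(ends, gm, side="left"), len(geno) - 1
            )
            calls[chrom][li] = geno[seg]
            junctions = ends[:-1]
            if junctions.size:
                jx_bp = genome.morgan_to_bp(chrom, junctions)
                for k, (jm, jb) in enumerate(zip(junctions, jx_bp)):
                    bp_rows.append(
                        (line, chrom, float(jb), float(jm) * 100.0,
                         int(geno[k]), int(geno[k + 1]))
                    )

    truth = SNPCallMatrix(
        line_ids=line_ids,
        chromosomes=list(genome.chromosomes),
        positions=positions,
        calls=calls,
        chrom_lengths={c: genome.physical_length(c) for c in genome.chromosomes},
    )
    true_breakpoints = pd.DataFrame(
        bp_rows,
        columns=["line_id", "chromosome", "position_bp", "position_cm",
                 "upstream_genotype", "downstream_genotype"],
    )
    return truth, true_breakpoints


def resolvable_breakpoints(
    truth: SNPCallMatrix,
) -> pd.DataFrame:
    """True junctions as observable on the SNP grid.

    Junctions falling in the same inter-SNP gap collapse to their net
    effect: the returned table has one row per genotype change in the
    per-SNP truth sequence, with the flanking SNP positions as the
    breakpoint interval (same columns as the calling stage reports).
    """
    rows = []
    for chrom in truth.chromosomes:
        pos = truth.positions[chrom]
        mat = truth.calls[chrom]
        for li, line in enumerate(truth.line_ids):
            row = mat[li]
            chg = np.nonzero(row[1:] != row[:-1])[0]
            for i in chg:
                rows.append(
                    (line, chrom, int(pos[i]), int(pos[i + 1]),
                     int(pos[i + 1]), int(row[i]), int(row[i + 1]))
                )
    return pd.DataFrame(rows, columns=BREAKPOINT_COLUMNS)


def degrade_calls(truth: SNPCallMatrix, pop: PopulationSpec) -> SNPCallMatrix:
    """Apply per-call missingness and parental flip errors.

    Each call is independently set to Missing with ``missing_rate``;
    each surviving homozygous call is flipped to the opposite parent
    with ``call_error_rate``.  Heterozygous calls are never flipped (the
    error model acts on parental reads, and residual heterozygotes are
    ~0.2% at F10).  Deterministic under ``pop.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(pop.rng_seed), 1]))
    out = truth.copy()
    for chrom in out.chromosomes:
        mat = out.calls[chrom]
        miss = rng.random(mat.shape) < pop.missing_rate
        flip = rng.random(mat.shape) < pop.call_error_rate
        hom = (mat == A2) | (mat == ZG)
        mat[flip & hom & ~miss] = 2 - mat[flip & hom & ~miss]
        mat[miss] = MISSING
    return out


def simulate_traits(
    truth: SNPCallMatrix,
    genome: GenomeSpec,
    traits: list[TraitSpec],
    rng_seed: int,
) -> dict[str, TraitTable]:
    """Additive phenotypes from planted QTL, one table per environment.

    phenotype = sum_q a_q * x_q + N(0, residual_sd^2), with x_q = +1 for
    Zhang gu homozygotes, -1 for A2, 0 for heterozygotes at the SNP
    nearest each planted QTL.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 2]))
    by_env: dict[str, dict[str, np.ndarray]] = {}
    for spec in traits:
        y = np.zeros(truth.n_lines)
        for chrom, cm, effect in spec.planted_qtl:
            if chrom not in truth.chromosomes:
                raise ValueError(f"QTL chromosome {chrom} not in genome")
            if not 0 <= cm <= genome.genetic_length(chrom) * 100.0:
                raise ValueError(
                    f"QTL position {cm} cM outside {chrom}"
                )
            bp = float(genome.morgan_to_bp(chrom, cm / 100.0))
            idx = int(np.argmin(np.abs(truth.positions[chrom] - bp)))
            score = truth.calls[chrom][:, idx].astype(float) - 1.0
            y = y + effect * score
        if spec.residual_sd > 0:
            y = y + rng.normal(0.0, spec.residual_sd, truth.n_lines)
        by_env.setdefault(spec.environment_label, {})[spec.trait_name] = y
    return {
        env: TraitTable(
            values=pd.DataFrame(cols, index=pd.Index(truth.line_ids,
                                                     name="line_id")),
            environment=env,
        )
        for env, cols in by_env.items()
    }


def heterozygous_fraction(truth: SNPCallMatrix) -> np.ndarray:
    """Per-line fraction of heterozygous calls across all SNPs."""
    het = np.zeros(truth.n_lines)
    total = 0
    for chrom in truth.chromosomes:
        het += (truth.calls[chrom] == HET).sum(axis=1)
        total += truth.positions[chrom].size
    return het / max(total, 1)
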