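"""Genome scans on bin markers: interval mapping, composite interval
mapping, permutation thresholds, and QTL declaration.

Scans use Haley-Knott regression: at each grid position the phenotype is
regressed on the expected genotype score x = P(ZhangGu) - P(A2), with
LOD = (n/2) log10(RSS0/RSS1).  Between observed bins the genotype
probabilities follow a two-state Markov chain along the RIL mosaic whose
transition probability over map distance d is the selfed-RIL recombinant
fraction R(d) = 2r/(1+2r) with r from the inverse mapping function.
Composite interval mapping conditions on background bin cofactors chosen
once per trait by forward stepwise regression; cofactors within a
blocking window of the test position are dropped.  With zero cofactors
the scan reduces exactly (bit-for-bit) to plain interval mapping.

Sign convention: Zhang gu homozygotes are scored +1 and A2 homozygotes
-1, so a positive additive effect means the Zhang gu allele increases
the trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import BinMatrix
from .genotypes import A2, HET, MISSING, ZG
from .linkage import LinkageMap, inverse_map_distance, ril_observed_R
from .sim import TraitTable

_LOD_CAP_RSS = 1e-12  # RSS1 floored at RSS0 * this; caps LOD at 6n


@dataclass
class ScanGrid:
    """Per-line genotype probabilities on the scan grid.

    ``probs[l, g]`` is ``(P_ZhangGu, P_Het, P_A2)`` for line ``l`` at
    grid point ``g``.
    """

    chromosome: np.ndarray  # (G,) labels
    cm: np.ndarray  # (G,) positions
    probs: np.ndarray  # (n_lines, G, 3)
    line_ids: list[str]

    @property
    def score(self) -> np.ndarray:
        """Expected additive genotype score, (n_lines, G)."""
        return self.probs[:, :, 0] - self.probs[:, :, 2]


@dataclass
class ScanResult:
    """One trait's scan curve plus its significance threshold."""

    trait: str
    table: pd.DataFrame  # chromosome, cm, lod, additive, r2
    threshold: float | None = None
    permutations: int = 0
    alpha: float = 0.05
    environment: str = "other"


@dataclass
class QTL:
    """A declared QTL with peak statistics and support interval."""

    name: str
    trait: str
    chromosome: str
    peak_bin: str
    peak_position: float
    lod: float
    additive: float
    r2: float
    support_interval: tuple[float, float]


def genotype_probabilities(
    bm: BinMatrix, lmap: LinkageMap, grid_step: float = 1.0
) -> ScanGrid:
    """Pseudomarker probabilities on a cM grid (plus all bin positions).

    At an observed bin the distribution is degenerate on the observed
    genotype.  Between informative (homozygous) flanking bins the
    conditional distribution over the two homozygote states follows the
    Markov chain; missing or heterozygous bins widen to the nearest
    informative flanks.  Lines with no informative bin on a chromosome
    get the uniform prior over homozygotes.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    n_lines = len(bm.line_ids)
    chrom_arrs, cm_arrs, prob_arrs = [], [], []
    for chrom in bm.chromosomes:
        idx = bm.chrom_slice(chrom)
        b_cm = lmap.positions(chrom)
        if b_cm.size != idx.size:
            raise ValueError("linkage map does not match bin matrix")
        length = float(b_cm[-1]) if b_cm.size else 0.0
        grid = np.unique(np.concatenate(
            [np.arange(0.0, length + grid_step / 2, grid_step), b_cm]
        ))
        grid = grid[grid <= length + 1e-9]
        probs = np.zeros((n_lines, grid.size, 3))
        geno = bm.geno[:, idx]
        # map grid points that coincide with bins
        at_bin = np.searchsorted(b_cm, grid)
        at_bin_ok = (at_bin < b_cm.size) & np.isclose(
            b_cm[np.minimum(at_bin, b_cm.size - 1)], grid
        )
        for li in range(n_lines):
            row = geno[li]
            hom = np.isin(row, (A2, ZG))
            h_cm = b_cm[hom]
            h_sc = (row[hom] == ZG)  # True where Zhang gu
            if h_cm.size == 0:
                probs[li, :, 0] = 0.5
                probs[li, :, 2] = 0.5
            else:
                left = np.searchsorted(h_cm, grid, side="right") - 1
                right = left + 1
                has_l = left >= 0
                has_r = right < h_cm.size
                dl = np.where(has_l, grid - h_cm[np.clip(left, 0, None)], 0.0)
                dr = np.where(has_r,
                              h_cm[np.clip(right, 0, h_cm.size - 1)] - grid,
                              0.0)
                Rl = ril_observed_R(
                    inverse_map_distance_vec(dl, lmap.mapping_function))
                Rr = ril_observed_R(
                    inverse_map_distance_vec(dr, lmap.mapping_function))
                # P(flank -> ZG): 1-R if flank is ZG else R
                zl = h_sc[np.clip(left, 0, None)]
                zr = h_sc[np.clip(right, 0, h_cm.size - 1)]
                pl_zg = np.where(has_l, np.where(zl, 1 - Rl, Rl), 0.5)
                pr_zg = np.where(has_r, np.where(zr, 1 - Rr, Rr), 0.5)
                w_zg = pl_zg * pr_zg
                w_a2 = (1 - pl_zg) * (1 - pr_zg)
                p_zg = w_zg / (w_zg + w_a2)
                probs[li, :, 0] = p_zg
                probs[li, :, 2] = 1.0 - p_zg
            # degenerate at observed bins (including heterozygous ones)
            obs = at_bin_ok & (row[np.minimum(at_bin, b_cm.size - 1)] != MISSING)
            og = row[np.minimum(at_bin, b_cm.size - 1)]
            probs[li, obs, :] = 0.0
            probs[li, obs & (og == ZG), 0] = 1.0
            probs[li, obs & (og == HET), 1] = 1.0
            probs[li, obs & (og == A2), 2] = 1.0
        chrom_arrs.append(np.full(grid.size, chrom, dtype=object))
        cm_arrs.append(grid)
        prob_arrs.append(probs)
    return ScanGrid(
        chromosome=np.concatenate(chrom_arrs),
        cm=np.concatenate(cm_arrs),
        probs=np.concatenate(prob_arrs, axis=1),
        line_ids=list(bm.line_ids),
    )


def inverse_map_distance_vec(d_cm: np.ndarray, mapping_function: str) -> np.ndarray:
    if mapping_function == "kosambi":
        return 0.5 * np.tanh(np.asarray(d_cm, dtype=float) / 50.0)
    if mapping_function == "haldane":
        return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))
    raise ValueError(f"unknown mapping function {mapping_function!r}")


def _trait_vector(tt: TraitTable, line_ids: list[str],
                  trait: str | None) -> tuple[str, np.ndarray]:
    if trait is None:
        if tt.values.shape[1] != 1:
            raise ValueError("trait name required for multi-trait tables")
        trait = str(tt.values.columns[0])
    y = tt.values[trait].reindex(line_ids).to_numpy(dtype=float)
    return trait, y


def _cofactor_groups(
    grid_chrom: np.ndarray,
    grid_cm: np.ndarray,
    cof_chrom: np.ndarray,
    cof_cm: np.ndarray,
    blocking_window: float,
) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Group grid points by the set of cofactors retained at each."""
    if cof_chrom.size == 0:
        return [((), np.arange(grid_cm.size))]
    keys: dict[tuple[int, ...], list[int]] = {}
    for g in range(grid_cm.size):
        keep = tuple(
            j for j in range(cof_chrom.size)
            if cof_chrom[j] != grid_chrom[g]
            or abs(cof_cm[j] - grid_cm[g]) > blocking_window
        )
        keys.setdefault(keep, []).append(g)
    return [(k, np.array(v)) for k, v in keys.items()]


def _scan_batch(
    Y: np.ndarray,  # (m, n) response rows (typically 1 trait or m perms)
    X: np.ndarray,  # (n, G) genotype scores
    groups: list[tuple[tuple[int, ...], np.ndarray]],
    cof: np.ndarray,  # (n, k) cofactor scores
):
    """Haley-Knott scan of every row of Y at every grid point.

    Returns (lod, additive, r2) of shape (m, G).  Model per grid point:
    y ~ 1 + retained cofactors + x; LOD and partial R2 are relative to
    the same model without x.
    """
    m, n = Y.shape
    G = X.shape[1]
    lod = np.zeros((m, G))
    add = np.zeros((m, G))
    r2 = np.zeros((m, G))
    ones = np.ones((n, 1))
    for keep, cols in groups:
        C = np.concatenate([ones, cof[:, list(keep)]], axis=1) if keep \
            else ones
        Q, _ = np.linalg.qr(C)
        Yres = Y - (Y @ Q) @ Q.T
        Xg = X[:, cols]
        Xres = Xg - Q @ (Q.T @ Xg)
        xn2 = np.einsum("ij,ij->j", Xres, Xres)
        ok = xn2 > n * 1e-12
        num = Yres @ Xres  # (m, Gg)
        rss0 = np.einsum("ij,ij->i", Yres, Yres)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = rss0[:, None] - np.where(ok, num**2 / np.where(ok, xn2, 1.0),
                                            0.0)
            rss1 = np.maximum(rss1, rss0[:, None] * _LOD_CAP_RSS)
            pos = rss0 > 0
            lod_g = np.zeros_like(rss1)
            lod_g[pos] = (n / 2.0) * np.log10(rss0[pos, None] / rss1[pos])
            r2_g = np.zeros_like(rss1)
            r2_g[pos] = (1.0 - rss1[pos] / rss0[pos, None]) * 100.0
            add_g = np.where(ok, num / np.where(ok, xn2, 1.0), 0.0)
        lod[:, cols] = lod_g
        add[:, cols] = add_g
        r2[:, cols] = r2_g
    return lod, add, r2


def _prepare(y: np.ndarray, grid: ScanGrid, min_lines: int):
    use = ~np.isnan(y)
    if use.sum() < min_lines:
        raise ValueError(
            f"only {int(use.sum())} informative lines; need >= {min_lines}"
        )
    yv = y[use]
    X = grid.score[use]
    if np.var(yv) == 0:
        warnings.warn("zero phenotypic variance; LOD curve is all zero",
                      stacklevel=3)
    return use, yv, X


def im_scan(
    tt: TraitTable,
    grid: ScanGrid,
    trait: str | None = None,
    min_lines: int = 30,
) -> ScanResult:
    """Plain interval mapping (the zero-cofactor special case of CIM)."""
    return cim_scan(tt, grid, bm=None, lmap=None, n_cofactors=0,
                    trait=trait, min_lines=min_lines)


def cim_scan(
    tt: TraitTable,
    grid: ScanGrid,
    bm: BinMatrix | None,
    lmap: LinkageMap | None,
    n_cofactors: int = 5,
    blocking_window: float = 10.0,
    trait: str | None = None,
    min_lines: int = 30,
) -> ScanResult:
    """Composite interval mapping with stepwise-selected bin cofactors."""
    trait_name, y = _trait_vector(tt, grid.line_ids, trait)
    use, yv, X = _prepare(y, grid, min_lines)
    if n_cofactors > 0:
        if bm is None or lmap is None:
            raise ValueError("cim_scan with cofactors needs bm and lmap")
        cof_idx = _select_cofactors(yv, bm, use, n_cofactors)
        cof = (bm.geno[np.ix_(use, cof_idx)].astype(float) - 1.0)
        cof[bm.geno[np.ix_(use, cof_idx)] == MISSING] = 0.0
        cof_chrom = bm.bins["chromosome"].to_numpy()[cof_idx]
        cof_cm = np.array([
            float(lmap.table["cm"].to_numpy()[j]) for j in cof_idx
        ])
    else:
        cof = np.empty((int(use.sum()), 0))
        cof_chrom = np.empty(0, dtype=object)
        cof_cm = np.empty(0)
    groups = _cofactor_groups(grid.chromosome, grid.cm, cof_chrom, cof_cm,
                              blocking_window)
    lod, add, r2 = _scan_batch(yv[None, :], X, groups, cof)
    table = pd.DataFrame(
        {
            "chromosome": grid.chromosome,
            "cm": grid.cm,
            "lod": lod[0],
            "additive": add[0],
            "r2": r2[0],
        }
    )
    return ScanResult(trait=trait_name, table=table,
                      environment=tt.environment)


def _select_cofactors(
    yv: np.ndarray,
    bm: BinMatrix,
    use: np.ndarray,
    n_cofactors: int,
    p_enter: float = 0.01,
) -> list[int]:
    """Forward stepwise selection of cofactor bins on genotype scores.

    Selection stops at ``n_cofactors`` or when the best candidate's
    partial F no longer reaches ``p_enter``.  Without the F-to-enter
    gate the tail cofactors are pure overfit: they shrink the residual
    genome-wide and, once dropped inside the blocking window, hand their
    chance association to the test position as a ghost peak.
    """
    from scipy import stats

    n = yv.size
    max_k = min(n_cofactors, max(n - 10, 0))
    scores = bm.geno[use].astype(float) - 1.0
    scores[bm.geno[use] == MISSING] = 0.0
    Q = np.ones((n, 1)) / np.sqrt(n)
    chosen: list[int] = []
    for _ in range(max_k):
        Xr = scores - Q @ (Q.T @ scores)
        r = yv - Q @ (Q.T @ yv)
        rss = float(r @ r)
        xn2 = np.einsum("ij,ij->j", Xr, Xr)
        ok = xn2 > n * 1e-10
        if not ok.any() or rss <= 0:
            break
        gain = np.zeros(scores.shape[1])
        gain[ok] = (Xr[:, ok].T @ r) ** 2 / xn2[ok]
        for j in chosen:
            gain[j] = -1.0
        best = int(np.argmax(gain))
        df_res = n - len(chosen) - 2
        if gain[best] <= 0 or df_res <= 0:
            break
        f_stat = gain[best] / max((rss - gain[best]) / df_res, 1e-300)
        if stats.f.sf(f_stat, 1, df_res) > p_enter:
            break
        chosen.append(best)
        qn = Xr[:, best] / np.sqrt(xn2[best])
        Q = np.concatenate([Q, qn[:, None]], axis=1)
    return sorted(chosen)


def permutation_threshold(
    tt: TraitTable,
    grid: ScanGrid,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    trait: str | None = None,
    min_lines: int = 30,
    bm: BinMatrix | None = None,
    lmap: LinkageMap | None = None,
    n_cofactors: int = 0,
    blocking_window: float = 10.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted across lines ``n_perm`` times, each
    permutation is rescanned with the same model as the real scan, and
    the threshold is the empirical (1 - alpha) quantile of the
    genome-wide maximum LOD.  With ``n_cofactors > 0`` every permutation
    re-runs composite interval mapping including cofactor re-selection -
    the null distribution must be given the same opportunity to overfit
    background markers as the real trait, otherwise CIM ghost peaks pass
    an interval-mapping threshold.  Deterministic given ``rng_seed``.
    """
    if n_perm * alpha < 5:
        warnings.warn("n_perm * alpha < 5: unstable quantile", stacklevel=2)
    maxlods = permutation_max_lods(tt, grid, n_perm, rng_seed, trait,
                                   min_lines, bm, lmap, n_cofactors,
                                   blocking_window)
    return float(np.quantile(maxlods, 1.0 - alpha, method="higher"))


def permutation_max_lods(
    tt: TraitTable,
    grid: ScanGrid,
    n_perm: int,
    rng_seed: int = 0,
    trait: str | None = None,
    min_lines: int = 30,
    bm: BinMatrix | None = None,
    lmap: LinkageMap | None = None,
    n_cofactors: int = 0,
    blocking_window: float = 10.0,
) -> np.ndarray:
    """Genome-wide maximum LOD of each phenotype permutation."""
    _, y = _trait_vector(tt, grid.line_ids, trait)
    use, yv, X = _prepare(y, grid, min_lines)
    rng = np.random.default_rng(rng_seed)
    if n_cofactors <= 0:
        Y = np.stack([rng.permutation(yv) for _ in range(n_perm)])
        groups = [((), np.arange(X.shape[1]))]
        lod, _, _ = _scan_batch(Y, X, groups, np.empty((yv.size, 0)))
        return lod.max(axis=1)
    if bm is None or lmap is None:
        raise ValueError("CIM permutations need bm and lmap")
    bin_cm = lmap.table["cm"].to_numpy()
    bin_chrom = bm.bins["chromosome"].to_numpy()
    maxlods = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(yv)
        cof_idx = _select_cofactors(yp, bm, use, n_cofactors)
        cof = bm.geno[np.ix_(use, cof_idx)].astype(float) - 1.0
        cof[bm.geno[np.ix_(use, cof_idx)] == MISSING] = 0.0
        groups = _cofactor_groups(
            grid.chromosome, grid.cm, bin_chrom[cof_idx],
            bin_cm[cof_idx], blocking_window,
        )
        lod, _, _ = _scan_batch(yp[None, :], X, groups, cof)
        maxlods[p] = lod.max()
    return maxlods


def declare_qtl(
    scan: ScanResult,
    trait_abbrev: str,
    lmap: LinkageMap | None = None,
) -> list[QTL]:
    """Declare QTL from above-threshold segments of a scan.

    Each maximal contiguous above-threshold segment yields one QTL at
    its LOD peak (ties broken toward the smaller cM position); the
    support interval contains positions within 1.5 LOD of the peak.
    Names follow the ``q<trait><chrom>`` convention with ``-1``, ``-2``
    suffixes in cM order when a trait has several QTL on one chromosome.
    """
    if scan.threshold is None:
        raise ValueError("scan has no threshold; run permutation_threshold")
    tbl = scan.table
    hits: list[QTL] = []
    for chrom in dict.fromkeys(tbl["chromosome"]):
        sel = tbl[tbl["chromosome"] == chrom].reset_index(drop=True)
        above = (sel["lod"] >= scan.threshold).to_numpy()
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        stops = list(np.nonzero(edges == -1)[0])
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            stops = stops + [len(above) - 1]
        lods = sel["lod"].to_numpy()
        cms = sel["cm"].to_numpy()
        for s, e in zip(starts, stops):
            peak = s + int(np.argmax(lods[s:e + 1]))
            lo = peak
            while lo > 0 and lods[lo - 1] >= lods[peak] - 1.5:
                lo -= 1
            hi = peak
            while hi < len(lods) - 1 and lods[hi + 1] >= lods[peak] - 1.5:
                hi += 1
            peak_bin = ""
            if lmap is not None:
                pos = lmap.positions(chrom)
                names = lmap.table.loc[lmap.table["chromosome"] == chrom,
                                       "bin_name"].to_numpy()
                peak_bin = str(names[int(np.argmin(np.abs(pos - cms[peak])))])
            hits.append(QTL(
                name="",
                trait=scan.trait,
                chromosome=str(chrom),
                peak_bin=peak_bin,
                peak_position=float(cms[peak]),
                lod=float(lods[peak]),
                additive=float(sel["additive"].to_numpy()[peak]),
                r2=float(sel["r2"].to_numpy()[peak]),
                support_interval=(float(cms[lo]), float(cms[hi])),
            ))
    # name per chromosome in cM order
    abbrev = trait_abbrev.lower()
    by_chrom: dict[str, list[QTL]] = {}
    for q in hits:
        by_chrom.setdefault(q.chromosome, []).append(q)
    for chrom, qs in by_chrom.items():
        qs.sort(key=lambda q: q.peak_position)
        digits = "".join(ch for ch in chrom if ch.isdigit())
        num = str(int(digits)) if digits else chrom
        for i, q in enumerate(qs):
            q.name = f"q{abbrev}{num}" if len(qs) == 1 \
                else f"q{abbrev}{num}-{i + 1}"
    hits.sort(key=lambda q: (q.chromosome, q.peak_position))
    return hits


def effect_sign_convention(additive_coefficient: float) -> float:
    """Signed additive effect under the Zhang gu = +1, A2 = -1 coding.

    With that coding the fitted coefficient already satisfies the
    reporting convention - positive means the Zhang gu allele increases
    the trait - so this is the identity; it exists to document (and pin
    in tests) the convention.
    """
    return additive_coefficient


def qtl_report(qtls: list[QTL]) -> pd.DataFrame:
    """QTL table with the standard report columns."""
    return pd.DataFrame(
        [
            {
                "Trait": q.trait,
                "QTL": q.name,
                "Chrom.": q.chromosome,
                "Bin": q.peak_bin,
                "QTL Peak Position (cM)": round(q.peak_position, 2),
                "LOD Score": round(q.lod, 2),
                "Additive": round(q.additive, 2),
                "R2 (%)": round(q.r2, 2),
            }
            for q in qtls
        ],
        columns=["Trait", "QTL", "Chrom.", "Bin", "QTL Peak Position (cM)",
                 "LOD Score", "Additive", "R2 (%)"],
    )
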