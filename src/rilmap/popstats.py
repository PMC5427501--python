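"""Segregation-distortion scanning and trait-level statistics.

Each bin's parental-allele counts are tested against the Mendelian 1:1
expectation of a biparental RIL population with a 1-df chi-square
goodness-of-fit test (heterozygous and missing lines excluded), with
Bonferroni correction across bins by default.  Trait correlations are
pairwise-complete product-moment coefficients with two-sided p-values
flagged at the 0.05 and 0.01 levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import BinMatrix
from .genotypes import A2, HET, MISSING, ZG
from .sim import TraitTable


@dataclass
class DistortionRecord:
    """Per-bin allele counts and the 1:1 segregation test."""

    bin_name: str
    chromosome: str
    n_zg: int
    n_a2: int
    n_het: int
    n_missing: int
    chi2: float
    p: float  # NaN when too few informative lines
    direction: str  # toward_ZhangGu / toward_A2 / none


def distortion_scan(
    bm: BinMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    min_informative: int = 20,
) -> list[DistortionRecord]:
    """Chi-square 1:1 segregation test for every bin.

    ``direction`` is set (from the sign of n_ZG - n_A2) only for bins
    whose corrected p-value falls below ``alpha``.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    geno = bm.geno
    n_zg = (geno == ZG).sum(axis=0)
    n_a2 = (geno == A2).sum(axis=0)
    n_het = (geno == HET).sum(axis=0)
    n_mis = (geno == MISSING).sum(axis=0)
    factor = bm.n_bins if correction == "bonferroni" else 1
    records = []
    for j in range(bm.n_bins):
        nz, na = int(n_zg[j]), int(n_a2[j])
        tot = nz + na
        if tot < min_informative:
            chi2, p = 0.0, float("nan")
            flagged = False
        else:
            exp = tot / 2.0
            chi2 = (nz - exp) ** 2 / exp + (na - exp) ** 2 / exp
            p = float(stats.chi2.sf(chi2, df=1))
            flagged = min(p * factor, 1.0) < alpha
        if flagged and nz > na:
            direction = "toward_ZhangGu"
        elif flagged and na > nz:
            direction = "toward_A2"
        else:
            direction = "none"
        records.append(DistortionRecord(
            bin_name=str(bm.bins["bin_name"].iloc[j]),
            chromosome=str(bm.bins["chromosome"].iloc[j]),
            n_zg=nz, n_a2=na, n_het=int(n_het[j]), n_missing=int(n_mis[j]),
            chi2=float(chi2), p=p, direction=direction,
        ))
    return records


def distortion_table(records: list[DistortionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class CorrelationRecord:
    """One trait pair's product-moment correlation."""

    trait_a: str
    trait_b: str
    r: float
    p: float
    significance: str  # ns / p<0.05 / p<0.01


def trait_correlations(
    tt: TraitTable, method: str = "pearson"
) -> list[CorrelationRecord]:
    """All pairwise trait correlations, pairwise-complete observations."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    cols = list(tt.values.columns)
    out = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = tt.values[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                out.append(CorrelationRecord(a, b, float("nan"),
                                             float("nan"), "ns"))
                continue
            if method == "pearson":
                res = stats.pearsonr(pair[a], pair[b])
            else:
                res = stats.spearmanr(pair[a], pair[b])
            r, p = float(res.statistic), float(res.pvalue)
            sig = "p<0.01" if p < 0.01 else "p<0.05" if p < 0.05 else "ns"
            out.append(CorrelationRecord(a, b, r, p, sig))
    return out


def correlation_matrix(
    records: list[CorrelationRecord], traits: list[str]
) -> pd.DataFrame:
    """Lower-triangle correlation matrix with significance stars."""
    mat = pd.DataFrame("", index=traits, columns=traits, dtype=object)
    for t in traits:
        mat.loc[t, t] = "1"
    for rec in records:
        stars = {"ns": "", "p<0.05": "*", "p<0.01": "**"}[rec.significance]
        cell = "" if np.isnan(rec.r) else f"{rec.r:.3f}{stars}"
        a, b = rec.trait_a, rec.trait_b
        lo, hi = (a, b) if traits.index(a) > traits.index(b) else (b, a)
        mat.loc[lo, hi] = cell
    return mat


def trait_summary(tt: TraitTable) -> pd.DataFrame:
    """Per-trait n, mean, sd, range, skewness, and excess kurtosis."""
    rows = []
    for col in tt.values.columns:
        v = tt.values[col].dropna().to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"trait {col} has fewer than 2 values")
        rows.append({
            "trait": col,
            "environment": tt.environment,
            "n": v.size,
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "skewness": float(stats.skew(v)) if np.std(v) > 0 else 0.0,
            "kurtosis": float(stats.kurtosis(v)) if np.std(v) > 0 else 0.0,
        })
    return pd.DataFrame(rows).set_index("trait")
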