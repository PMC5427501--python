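"""Simulator behavior: inbreeding decay, crossover model, degradation,
and phenotype construction."""

import numpy as np
import pandas as pd
import pytest

import rilmap as rm
from rilmap.linkage import ril_observed_R


def test_heterozygosity_halves_each_selfing_generation():
    """Mean het fraction at F_t is (1/2)^(t-1) within 3 SE over lines."""
    genome = rm.GenomeSpec(n_chromosomes=3, chrom_physical_length=10_000_000,
                           chrom_genetic_length=1.0, n_snps=400)
    for gen, expected in [(4, 0.125), (10, 0.5 ** 9)]:
        pop = rm.PopulationSpec(n_lines=250, final_generation=gen, rng_seed=2)
        truth, _ = rm.simulate_ril_population(genome, pop)
        het = rm.heterozygous_fraction(truth)
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - expected) < 3 * se + 1e-9


def test_zero_genetic_length_gives_parental_chromosomes():
    genome = rm.GenomeSpec(n_chromosomes=1, chrom_physical_length=1_000_000,
                           chrom_genetic_length=0.0, n_snps=100)
    pop = rm.PopulationSpec(n_lines=40, rng_seed=3)
    truth, bp = rm.simulate_ril_population(genome, pop)
    assert len(bp) == 0
    calls = truth.calls["chr01"]
    # every line is uniformly one parent (or uniformly heterozygous)
    assert (calls == calls[:, :1]).all()


def test_zero_snp_chromosome_rejected():
    genome = rm.GenomeSpec(n_chromosomes=1, chrom_physical_length=1_000_000,
                           chrom_genetic_length=1.0, n_snps=0)
    with pytest.raises(ValueError, match="zero SNPs"):
        rm.simulate_ril_population(genome, rm.PopulationSpec(n_lines=2))


def test_terminal_marker_recombinants_match_haldane_waddington():
    """Observed recombinant fraction between chromosome ends approaches
    R = 2r/(1+2r) with r from Haldane's function, in the F-infinity limit."""
    d = 1.0  # Morgans between terminal markers
    r = (1.0 - np.exp(-2.0 * d)) / 2.0
    expected = ril_observed_R(r)
    genome = rm.GenomeSpec(n_chromosomes=1, chrom_physical_length=10_000_000,
                           chrom_genetic_length=d,
                           snp_positions={"chr01": np.array([1, 10_000_000])})
    pop = rm.PopulationSpec(n_lines=800, final_generation=25, rng_seed=5)
    truth, _ = rm.simulate_ril_population(genome, pop)
    calls = truth.calls["chr01"]
    hom = np.isin(calls[:, 0], (rm.A2, rm.ZG)) & np.isin(calls[:, 1],
                                                         (rm.A2, rm.ZG))
    R_obs = np.mean(calls[hom, 0] != calls[hom, 1])
    se = np.sqrt(expected * (1 - expected) / hom.sum())
    assert abs(R_obs - expected) < 4 * se


def test_simulation_deterministic_under_seed(small_genome, small_pop):
    t1, b1 = rm.simulate_ril_population(small_genome, small_pop)
    t2, b2 = rm.simulate_ril_population(small_genome, small_pop)
    for c in t1.chromosomes:
        assert np.array_equal(t1.calls[c], t2.calls[c])
        assert np.array_equal(t1.positions[c], t2.positions[c])
    pd.testing.assert_frame_equal(b1, b2)


def test_true_junctions_strictly_increasing(small_sim):
    _, bp = small_sim
    for (_, _), grp in bp.groupby(["line_id", "chromosome"]):
        pos = grp["position_bp"].to_numpy()
        assert (np.diff(pos) > 0).all()


def test_degrade_identity_when_rates_zero(small_sim):
    truth, _ = small_sim
    pop = rm.PopulationSpec(n_lines=truth.n_lines, call_error_rate=0.0,
                            missing_rate=0.0, rng_seed=1)
    out = rm.degrade_calls(truth, pop)
    for c in truth.chromosomes:
        assert np.array_equal(out.calls[c], truth.calls[c])


def test_degrade_all_missing_when_rate_one(small_sim):
    truth, _ = small_sim
    pop = rm.PopulationSpec(n_lines=truth.n_lines, missing_rate=1.0,
                            rng_seed=1)
    out = rm.degrade_calls(truth, pop)
    for c in truth.chromosomes:
        assert (out.calls[c] == rm.MISSING).all()


def test_degrade_flip_rate_matches_binomial(small_sim):
    """1% error on homozygous truth flips ~1% of calls (binomial count)."""
    truth, _ = small_sim
    pop = rm.PopulationSpec(n_lines=truth.n_lines, call_error_rate=0.01,
                            missing_rate=0.0, rng_seed=7)
    out = rm.degrade_calls(truth, pop)
    flipped = total = 0
    for c in truth.chromosomes:
        hom = np.isin(truth.calls[c], (rm.A2, rm.ZG))
        flipped += (out.calls[c][hom] != truth.calls[c][hom]).sum()
        total += hom.sum()
    se = np.sqrt(0.01 * 0.99 / total)
    assert abs(flipped / total - 0.01) < 4 * se


def test_noiseless_single_qtl_phenotypes_exact(small_genome, small_sim):
    truth, _ = small_sim
    spec = rm.TraitSpec("T", [("chr01", 50.0, 1.0)], residual_sd=0.0)
    tt = rm.simulate_traits(truth, small_genome, [spec], 1)["long_day"]
    vals = tt.values["T"].to_numpy()
    bp = float(small_genome.morgan_to_bp("chr01", 0.5))
    idx = int(np.argmin(np.abs(truth.positions["chr01"] - bp)))
    score = truth.calls["chr01"][:, idx].astype(float) - 1.0
    assert np.array_equal(vals, score)
    assert set(np.unique(vals)).issubset({-1.0, 0.0, 1.0})


def test_qtl_variance_explained_near_ten_percent(small_genome, small_sim):
    """a=1, sigma=3 gives R^2 = a^2/(a^2+sigma^2) = 0.1 at the QTL marker."""
    truth, _ = small_sim
    spec = rm.TraitSpec("T", [("chr02", 40.0, 1.0)], residual_sd=3.0)
    tt = rm.simulate_traits(truth, small_genome, [spec], 9)["long_day"]
    bp = float(small_genome.morgan_to_bp("chr02", 0.4))
    idx = int(np.argmin(np.abs(truth.positions["chr02"] - bp)))
    x = truth.calls["chr02"][:, idx].astype(float) - 1.0
    rho = np.corrcoef(tt.values["T"], x)[0, 1]
    assert rho**2 == pytest.approx(0.10, abs=0.08)


def test_environments_share_planted_qtl(small_genome, small_sim):
    truth, _ = small_sim
    shared = ("chr01", 30.0, 2.0)
    specs = [
        rm.TraitSpec("A", [shared], residual_sd=0.0,
                     environment_label="long_day"),
        rm.TraitSpec("B", [shared, ("chr02", 60.0, 1.5)], residual_sd=0.0,
                     environment_label="short_day"),
    ]
    tables = rm.simulate_traits(truth, small_genome, specs, 3)
    assert set(tables) == {"long_day", "short_day"}
    a = tables["long_day"].values["A"]
    b = tables["short_day"].values["B"]
    # the shared QTL contributes identically in both environments
    assert np.corrcoef(a, b)[0, 1] > 0.5


def test_qtl_position_outside_map_rejected(small_genome, small_sim):
    truth, _ = small_sim
    spec = rm.TraitSpec("T", [("chr01", 500.0, 1.0)])
    with pytest.raises(ValueError, match="outside"):
        rm.simulate_traits(truth, small_genome, [spec], 1)
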