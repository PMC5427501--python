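"""Shared fixtures: one mid-sized simulated population reused across tests."""

import numpy as np
import pytest

import rilmap as rm


@pytest.fixture(scope="session")
def small_genome():
    return rm.GenomeSpec(
        n_chromosomes=2,
        chrom_physical_length=20_000_000,
        chrom_genetic_length=1.0,
        n_snps=1200,
    )


@pytest.fixture(scope="session")
def small_pop():
    return rm.PopulationSpec(n_lines=80, rng_seed=11)


@pytest.fixture(scope="session")
def small_sim(small_genome, small_pop):
    """Error-free truth plus continuous junction table."""
    truth, true_bp = rm.simulate_ril_population(small_genome, small_pop)
    return truth, true_bp


@pytest.fixture(scope="session")
def smoothed_truth(small_sim):
    truth, _ = small_sim
    return rm.smooth_population(truth)


@pytest.fixture(scope="session")
def bin_matrix(smoothed_truth):
    _, bps = rm.population_breakpoints(smoothed_truth)
    boundaries = rm.merge_breakpoints(
        bps, rm.BinSpec(), chromosomes=smoothed_truth.chromosomes
    )
    return rm.build_bins(boundaries, smoothed_truth)


@pytest.fixture(scope="session")
def linkage_map(bin_matrix):
    return rm.assemble_map(bin_matrix)


@pytest.fixture(scope="session")
def scan_grid(bin_matrix, linkage_map):
    return rm.genotype_probabilities(bin_matrix, linkage_map)


def make_calls(rows, positions=None, chrom="chr01", line_ids=None):
    """Build a single-chromosome SNPCallMatrix from literal call rows."""
    rows = np.asarray(rows, dtype=np.int8)
    if rows.ndim == 1:
        rows = rows[None, :]
    n_lines, n_snps = rows.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1, dtype=np.int64) * 1000
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n_lines)]
    return rm.SNPCallMatrix(
        line_ids=list(line_ids),
        chromosomes=[chrom],
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        calls={chrom: rows},
    )
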