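"""End-to-end pipeline: simulate -> call -> bin -> map -> scan -> stats.

Each stage writes its artifacts to the run directory and later stages
can resume from them, so the pipeline is a pure function of (inputs,
configuration, seed).  A run manifest records the configuration, seed,
package version, and a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .binmap import BinSpec, build_bins, merge_breakpoints
from .calling import WindowRule, population_breakpoints, smooth_population
from .io import (
    PipelineConfig,
    read_ab,
    read_bin_matrix,
    read_breakpoints,
    read_map,
    read_traits,
    write_ab,
    write_bin_genotypes,
    write_bins,
    write_breakpoints,
    write_map,
    write_qtl_report,
    write_scan,
    write_traits,
)
from .linkage import assemble_map
from .popstats import (
    correlation_matrix,
    distortion_scan,
    distortion_table,
    trait_correlations,
    trait_summary,
)
from .qtl import (
    cim_scan,
    declare_qtl,
    genotype_probabilities,
    permutation_threshold,
    qtl_report,
)
from .sim import (
    GenomeSpec,
    PopulationSpec,
    TraitSpec,
    degrade_calls,
    simulate_ril_population,
    simulate_traits,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "bin", "map", "scan", "stats")


def _default_traits(config: PipelineConfig) -> list[TraitSpec]:
    if config.traits:
        return [
            TraitSpec(
                trait_name=t["trait_name"],
                planted_qtl=[tuple(q) for q in t["planted_qtl"]],
                residual_sd=float(t.get("residual_sd", 1.0)),
                environment_label=t.get("environment_label", "long_day"),
            )
            for t in config.traits
        ]
    # one ~10%-variance QTL mid-chromosome 1 as a demonstration trait
    mid = config.chrom_genetic_length * 100.0 / 2.0
    return [TraitSpec(trait_name="TR1",
                      planted_qtl=[("chr01", mid, 1.0)],
                      residual_sd=3.0, environment_label="long_day")]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: Path | str,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> Path:
    """Run the requested stages, resuming from on-disk artifacts.

    Returns the run directory.  A stage whose outputs already exist is
    loaded rather than recomputed unless ``force`` is set.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ab_dir = out / "genotypes"
    paths = {
        "breakpoints": out / "breakpoints.tsv",
        "bins": out / "bins.tsv",
        "bin_genotypes": out / "bin_genotypes.tsv",
        "map": out / "linkage_map.tsv",
        "qtl": out / "qtl_report.tsv",
        "distortion": out / "distortion.tsv",
        "summary": out / "trait_summary.tsv",
    }
    genome = GenomeSpec(
        n_chromosomes=config.n_chromosomes,
        chrom_physical_length=config.chrom_physical_length,
        chrom_genetic_length=config.chrom_genetic_length,
        n_snps=config.n_snps,
    )
    pop = PopulationSpec(
        n_lines=config.n_lines,
        final_generation=config.final_generation,
        call_error_rate=config.call_error_rate,
        missing_rate=config.missing_rate,
        rng_seed=config.rng_seed,
    )
    rule = WindowRule(
        window_size=config.window_size,
        upper_count=config.upper_count,
        lower_count=config.lower_count,
        min_informative=config.min_informative,
        min_block_snps=config.min_block_snps,
    )
    trait_specs = _default_traits(config)
    environments = sorted({t.environment_label for t in trait_specs})

    calls = bm = lmap = None
    smoothed = breakpoints = None
    trait_tables = {}

    def timer(stage):
        t0 = time.monotonic()
        return lambda: logger.info("stage %s: %.1f s", stage,
                                   time.monotonic() - t0)

    if "simulate" in stages:
        done = timer("simulate")
        if ab_dir.is_dir() and any(ab_dir.glob("*.ab")) and not force:
            calls = read_ab({p.stem: p for p in sorted(ab_dir.glob("*.ab"))})
            trait_tables = {
                env: read_traits(out / f"traits_{env}.csv", env)
                for env in environments
            }
        else:
            truth, _ = simulate_ril_population(genome, pop)
            calls = degrade_calls(truth, pop)
            write_ab(calls, ab_dir)
            trait_tables = simulate_traits(truth, genome, trait_specs,
                                           config.rng_seed)
            for env, tt in trait_tables.items():
                write_traits(tt, out / f"traits_{env}.csv")
        done()

    if "call" in stages:
        done = timer("call")
        if paths["breakpoints"].exists() and not force:
            breakpoints = read_breakpoints(paths["breakpoints"])
            smoothed = None
        else:
            if calls is None:
                calls = read_ab(
                    {p.stem: p for p in sorted(ab_dir.glob("*.ab"))}
                )
            smoothed = smooth_population(calls, rule)
            _, breakpoints = population_breakpoints(
                smoothed, rule.min_block_snps
            )
            write_breakpoints(breakpoints, paths["breakpoints"])
        done()

    if "bin" in stages:
        done = timer("bin")
        if paths["bins"].exists() and not force:
            bm = read_bin_matrix(paths["bins"], paths["bin_genotypes"])
        else:
            if calls is None:
                calls = read_ab(
                    {p.stem: p for p in sorted(ab_dir.glob("*.ab"))}
                )
            if smoothed is None:
                smoothed = smooth_population(calls, rule)
            if breakpoints is None:
                _, breakpoints = population_breakpoints(
                    smoothed, rule.min_block_snps
                )
            boundaries = merge_breakpoints(
                breakpoints, BinSpec(config.min_interval),
                chromosomes=smoothed.chromosomes,
            )
            bm = build_bins(boundaries, smoothed,
                            consensus_threshold=config.consensus_threshold)
            write_bins(bm, paths["bins"])
            write_bin_genotypes(bm, paths["bin_genotypes"])
        done()

    if "map" in stages:
        done = timer("map")
        if paths["map"].exists() and not force:
            lmap = read_map(paths["map"], config.mapping_function)
        else:
            if bm is None:
                bm = read_bin_matrix(paths["bins"], paths["bin_genotypes"])
            lmap = assemble_map(bm, config.mapping_function,
                                config.min_lines_two_point)
            write_map(lmap, paths["map"])
        done()

    if "scan" in stages:
        done = timer("scan")
        if bm is None:
            bm = read_bin_matrix(paths["bins"], paths["bin_genotypes"])
        if lmap is None:
            lmap = read_map(paths["map"], config.mapping_function)
        if not trait_tables:
            trait_tables = {
                env: read_traits(out / f"traits_{env}.csv", env)
                for env in environments
            }
        grid = genotype_probabilities(bm, lmap, config.grid_step)
        reports = []
        for env in environments:
            tt = trait_tables[env]
            for trait in tt.values.columns:
                scan = cim_scan(tt, grid, bm, lmap,
                                n_cofactors=config.n_cofactors,
                                blocking_window=config.blocking_window,
                                trait=trait,
                                min_lines=config.min_lines_scan)
                scan.threshold = permutation_threshold(
                    tt, grid, n_perm=config.n_perm, alpha=config.alpha,
                    rng_seed=config.rng_seed, trait=trait,
                    min_lines=config.min_lines_scan,
                    bm=bm, lmap=lmap, n_cofactors=config.n_cofactors,
                    blocking_window=config.blocking_window,
                )
                scan.permutations = config.n_perm
                scan.alpha = config.alpha
                write_scan(scan.table, out / f"scan_{env}_{trait}.tsv")
                report = qtl_report(declare_qtl(scan, trait, lmap))
                report.insert(0, "Environment", env)
                reports.append(report)
        write_qtl_report(pd.concat(reports, ignore_index=True), paths["qtl"])
        done()

    if "stats" in stages:
        done = timer("stats")
        if bm is None:
            bm = read_bin_matrix(paths["bins"], paths["bin_genotypes"])
        if not trait_tables:
            trait_tables = {
                env: read_traits(out / f"traits_{env}.csv", env)
                for env in environments
            }
        distortion_table(
            distortion_scan(bm, alpha=config.alpha)
        ).to_csv(paths["distortion"], sep="\t", index=False)
        summaries = []
        for env, tt in trait_tables.items():
            summaries.append(trait_summary(tt))
            recs = trait_correlations(tt)
            correlation_matrix(recs, list(tt.values.columns)).to_csv(
                out / f"correlations_{env}.tsv", sep="\t"
            )
        pd.concat(summaries).to_csv(paths["summary"], sep="\t")
        done()

    manifest = {
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "stages": list(stages),
        "config": {k: v for k, v in config.__dict__.items()},
        "checksums": {
            str(p.relative_to(out)): _checksum(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
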