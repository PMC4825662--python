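"""End-to-end demo pipeline: simulate → analyze → report.

Runs the three synthetic assays (marker test cross, MSAP, expression),
feeds each through its analysis stage and writes all report tables to
the configured output directory.  Every stage's seed derives
deterministically from the run seed, so the same configuration always
produces byte-identical numeric output.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, msap, segregation
from .io import RunConfig, write_json, write_table
from .pairing import TETRASOMIC
from .simulate import (
    SimulationConfig,
    TetraploidIndividual,
    default_parents,
    progeny_genotype_table,
    simulate_bsp_cross,
    simulate_expression_matrix,
    simulate_marker_counts,
    simulate_msap_profiles,
)

__all__ = ["run_pipeline"]


def _repulsion_config(chrom: str) -> segregation.LocusConfiguration:
    """A two-allele marker with one seed- and one pollen-derived carrier."""
    return segregation.LocusConfiguration(
        locus_id=f"ssr_{chrom}",
        chromosome=chrom,
        tracked_alleles=(("A", frozenset({0})), ("B", frozenset({2}))),
    )


def run_pipeline(config: RunConfig) -> dict[str, float]:
    """Execute the full synthetic pipeline; returns per-stage wall times."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    timings: dict[str, float] = {}

    # Stage 1: BSP cross and marker segregation.
    t0 = time.perf_counter()
    n_progeny = int(config.extra.get("n_progeny", 200))
    p1, p2 = default_parents()
    cross_cfg = SimulationConfig(n_progeny=n_progeny, seed=config.seed)
    progeny = simulate_bsp_cross(p1, p2, cross_cfg)
    genotable = progeny_genotype_table(progeny, p1, p2)
    write_table(genotable, out / "progeny_genotypes.tsv", seed=config.seed, config=cfg_dict)

    tetraploids = [ind for ind in progeny if ind.ploidy == 4]
    tests = []
    if tetraploids:
        bsp = TetraploidIndividual.from_individual(tetraploids[0])
        rng = np.random.default_rng(config.seed + 1)
        test_cfg = SimulationConfig(
            n_progeny=int(config.extra.get("n_testcross", 60)),
            pairing_preference=float(config.extra.get("pairing_preference", 0.0)),
            seed=config.seed + 1,
        )
        for chrom in sorted(bsp.homologs):
            locus_cfg = _repulsion_config(chrom)
            counts = simulate_marker_counts(locus_cfg, test_cfg, rng)
            tests.append(segregation.test_marker(locus_cfg, counts))
        write_table(
            segregation.marker_test_table(tests),
            out / "marker_tests.tsv",
            seed=config.seed,
            config=cfg_dict,
        )
        calls = [
            segregation.classify_chromosome([t], t.chromosome) for t in tests
        ]
        call_table = pd.DataFrame(
            [{"chromosome": c.chromosome, "call": c.call} for c in calls]
        )
        write_table(call_table, out / "chromosome_calls.tsv", seed=config.seed, config=cfg_dict)
    timings["segregation"] = time.perf_counter() - t0

    # Stage 2: MSAP.
    t0 = time.perf_counter()
    sim = simulate_msap_profiles(
        n_sites=int(config.extra.get("n_sites", 400)),
        event_rates={
            "parental_P1_like": 0.20,
            "parental_P2_like": 0.13,
            "de_novo_methylation": 0.14,
            "demethylation": 0.10,
            "ambiguous": 0.02,
        },
        n_hybrids=6,
        seed=config.seed + 2,
    )
    bands_out = sim.bands.reset_index()
    write_table(bands_out, out / "msap_bands.tsv", seed=config.seed, config=cfg_dict)
    states = msap.score_band_matrix(sim.bands)
    classes = msap.classify_hybrid_sites(states, *sim.parents, hybrids=list(sim.hybrids))
    summary = msap.class_summary(classes)
    write_table(summary, out / "msap_class_summary.tsv", seed=config.seed, config=cfg_dict)
    levels = msap.methylation_levels(states, per_individual=True).reset_index(
        names="individual"
    )
    write_table(levels, out / "msap_levels.tsv", seed=config.seed, config=cfg_dict)
    coords, explained = msap.pcoa_profiles(sim.bands)
    coords_out = coords.iloc[:, :2].reset_index()
    write_table(coords_out, out / "msap_pcoa.tsv", seed=config.seed, config=cfg_dict)
    timings["msap"] = time.perf_counter() - t0

    # Stage 3: expression partition.
    t0 = time.perf_counter()
    study, truth = simulate_expression_matrix(
        n_genes=int(config.extra.get("n_genes", 2000)),
        frac_nonadditive=float(config.extra.get("frac_nonadditive", 0.1)),
        effect_log2fc=float(config.extra.get("effect_log2fc", 2.0)),
        sigma=float(config.extra.get("sigma", 0.5)),
        seed=config.seed + 3,
    )
    partition, results = expression.nonadditive_partition(
        study, log2fc_cutoff=config.log2fc_cutoff, fdr=config.fdr
    )
    for name, res in results.items():
        write_table(
            res.reset_index(), out / f"contrast_{name}.tsv", seed=config.seed, config=cfg_dict
        )
    write_json(
        {
            "HS": sorted(partition.hs),
            "HPS": sorted(partition.hps),
            "PS": sorted(partition.ps),
            "n_HS": len(partition.hs),
            "n_HPS": len(partition.hps),
            "n_PS": len(partition.ps),
        },
        out / "partition.json",
        seed=config.seed,
        config=cfg_dict,
    )
    timings["expression"] = time.perf_counter() - t0

    write_json(timings, out / "stage_timings.json", seed=config.seed, config=cfg_dict)
    return timings
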