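"""End-to-end orchestration: sweep → build → δ → epistasis → accessibility
→ null comparison → structure, with a reproducibility manifest.

Every skipped analysis (δ unavailable, tied extremum, zero squares) is
recorded in the manifest with its reason; a fixed seed reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as eio
from .accessibility import AmbiguousExtremumError, accessibility_summary
from .epistasis import (
    classify_network,
    estimate_delta,
    fraction_identical_neighbors,
    summarize_epistasis,
)
from .network import count_squares, maf_filter, sweep_cutoffs
from .nulls import empirical_quantile, network_statistics, null_distribution
from .panel import AssociationTable
from .simulate import SimulationConfig, compute_association_pvalues, simulate_panel
from .structure import detect_modules, module_phenotype_test, vertex_betweenness

logger = logging.getLogger("epinet")

__all__ = ["PipelineConfig", "run_pipeline", "SIMULATION_PRESETS"]

#: ready-made synthetic architectures for demonstration and smoke testing
SIMULATION_PRESETS: dict[str, SimulationConfig] = {
    # distinct subset sums: every one of the 16 haplotype values is
    # unique, so the phenotypic extremum is unique in any subnetwork
    "additive": SimulationConfig(
        n_accessions=400, n_causal_loci=4, n_neutral_loci=30,
        minor_allele_freq=0.4, additive_effects=(5.0, 6.0, 7.0, 9.0),
        noise_sd=0.0, baseline=10.0, seed=0,
    ),
    # asymmetric effects keep per-locus marginals detectable while the
    # strong negative interactions flip mutation signs between backgrounds
    "reciprocal-heavy": SimulationConfig(
        n_accessions=500, n_causal_loci=4, n_neutral_loci=30,
        minor_allele_freq=0.3, additive_effects=(6.0, 5.0, 6.0, 5.0),
        interaction_terms=((0, 1, -7.0), (2, 3, -7.0)),
        noise_sd=0.0, baseline=10.0, seed=0,
    ),
}


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    association_path: str | None = None
    simulate: SimulationConfig | None = None
    phenotype_name: str = "phenotype"
    sweep_grid: list[float] | None = None
    maf_threshold: float = 0.0
    null_reps: int = 1000
    seed: int = 0
    delta_override: float | None = None
    delta_mode: str = "literal"
    path_cap: int = 10**6


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"][name] = info
    logger.info("stage %s: %s", name, info)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the manifest (also written to
    ``out_dir/manifest.json`` along with all stage tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": vars(config).copy(), "stages": {}, "skips": []}
    manifest["config"]["simulate"] = (
        vars(config.simulate).copy() if config.simulate else None
    )

    if config.simulate is not None:
        panel = simulate_panel(config.simulate)
        assoc = compute_association_pvalues(panel, config.phenotype_name)
        eio.write_panel(panel, assoc, out, prefix="input")
    else:
        if not (config.genotype_path and config.phenotype_path and config.association_path):
            raise ValueError("either simulate or the three input paths are required")
        panel, assoc = eio.read_panel(
            config.genotype_path, config.phenotype_path,
            config.association_path, config.phenotype_name,
        )
    _stage(manifest, "input", n_accessions=len(panel.accessions), n_loci=len(panel.loci))

    if config.maf_threshold > 0:
        panel = maf_filter(panel, config.maf_threshold)
        assoc = AssociationTable(
            assoc.pvalues[assoc.pvalues.index.isin(panel.loci)],
            phenotype_name=assoc.phenotype_name,
        )
        _stage(manifest, "maf_filter", n_loci=len(panel.loci))

    sweep = sweep_cutoffs(panel, assoc, config.sweep_grid, config.phenotype_name)
    sweep.table.to_csv(out / "sweep.tsv", sep="\t", index=False)
    if sweep.selected_network is None:
        manifest["skips"].append({"stage": "sweep", "reason": "no non-degenerate cutoff"})
        eio.write_json(manifest, out / "manifest.json")
        return manifest
    net = sweep.selected_network
    _stage(
        manifest, "sweep",
        selected_cutoff=sweep.selected_cutoff,
        n_vertices=net.graph.number_of_nodes(),
        n_isolates=len(net.isolates),
    )

    bc = vertex_betweenness(net)
    modules = None
    module_test = None
    if net.graph.number_of_nodes() >= 2:
        partition = detect_modules(net, seed=config.seed)
        modules = partition.assignment
        if len(partition.module_phenotypes) >= 2:
            module_test = module_phenotype_test(partition)
        _stage(
            manifest, "structure",
            modularity=partition.modularity,
            n_modules=len(partition.module_phenotypes),
            module_test=module_test,
        )
    eio.write_network(net, out, prefix="network", betweenness=bc, modules=modules)

    noise = estimate_delta(net)
    if config.delta_override is not None:
        delta = config.delta_override
        delta_source = "override"
    elif noise.available:
        delta = noise.delta
        delta_source = "estimated"
    else:
        delta = None
        delta_source = "unavailable"
    _stage(
        manifest, "delta",
        delta=delta, source=delta_source,
        n_contributing=noise.n_contributing,
        contributing_fraction=noise.contributing_fraction,
    )

    summary_row = {
        "phenotype": config.phenotype_name,
        "cutoff": sweep.selected_cutoff,
        "n_loci": len(net.loci),
        "n_vertices": net.graph.number_of_nodes(),
        "n_squares": count_squares(net)["total"],
        "delta": delta,
    }

    if delta is None:
        manifest["skips"].append(
            {"stage": "epistasis", "reason": "delta unavailable (no vertex with >= 3 members)"}
        )
    else:
        if net.graph.number_of_edges():
            summary_row["fraction_identical_neighbors"] = fraction_identical_neighbors(net, delta)
        calls, skipped = classify_network(net, delta, config.delta_mode)
        epi = summarize_epistasis(net, delta, config.delta_mode)
        rows = [
            {
                "ab": c.square.ab, "Ab": c.square.Ab,
                "aB": c.square.aB, "AB": c.square.AB,
                "v_ab": c.square.v_ab, "v_Ab": c.square.v_Ab,
                "v_aB": c.square.v_aB, "v_AB": c.square.v_AB,
                "epsilon": c.epsilon, "delta": c.delta, "class": c.klass,
            }
            for c in calls
        ]
        pd.DataFrame(
            rows,
            columns=["ab", "Ab", "aB", "AB", "v_ab", "v_Ab", "v_aB", "v_AB",
                     "epsilon", "delta", "class"],
        ).to_csv(out / "epistasis.tsv", sep="\t", index=False)
        _stage(
            manifest, "epistasis",
            n_squares=epi.n_squares, n_skipped=epi.n_skipped,
            counts=epi.counts, analyzable=epi.analyzable,
        )
        if not epi.analyzable:
            manifest["skips"].append({"stage": "epistasis", "reason": "zero squares"})
        summary_row.update(
            epistatic_fraction=epi.epistatic_fraction,
            magnitude_fraction=epi.fractions["magnitude"],
            simple_sign_fraction=epi.fractions["simple_sign"],
            reciprocal_sign_fraction=epi.fractions["reciprocal_sign"],
            all_epistatic=epi.all_epistatic,
        )

        for direction in ("max", "min"):
            try:
                rep = accessibility_summary(
                    net, delta=delta, direction=direction, cap=config.path_cap
                )
            except AmbiguousExtremumError as exc:
                manifest["skips"].append(
                    {"stage": f"accessibility_{direction}", "reason": str(exc)}
                )
                continue
            rep.per_source.to_csv(
                out / f"accessibility_{direction}.tsv", sep="\t", index=False
            )
            rep.binned_fractions.to_csv(
                out / f"accessibility_{direction}_binned.tsv", sep="\t", index=False
            )
            _stage(
                manifest, f"accessibility_{direction}",
                extremum=rep.extremum,
                fraction_accessible=rep.fraction_accessible,
                mean_path_length=rep.mean_path_length,
            )
            if direction == "max":
                summary_row["fraction_accessible_max"] = rep.fraction_accessible
                summary_row["mean_path_length"] = rep.mean_path_length
            else:
                summary_row["fraction_accessible_min"] = rep.fraction_accessible

    if config.null_reps > 0:
        strings = [
            h for h, data in net.graph.nodes(data=True) for _ in data["members"]
        ] + [h for h, data in net.isolates.items() for _ in data["members"]]
        null = null_distribution(strings, n_reps=config.null_reps, seed=config.seed)
        null.table.to_csv(out / "null.tsv", sep="\t", index=False)
        observed = network_statistics(net)
        comparison = {
            stat: empirical_quantile(observed[stat], null.table[stat])
            for stat in null.table.columns
        }
        _stage(manifest, "null", observed=observed, comparison=comparison)

    pd.DataFrame([summary_row]).to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest["summary"] = summary_row
    eio.write_json(manifest, out / "manifest.json")
    return manifest
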