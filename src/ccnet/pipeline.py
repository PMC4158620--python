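"""End-to-end pipeline: simulate-or-load -> infer -> analyses -> manifest.

One master seed deterministically derives the per-stage seeds (simulation,
bootstrap, permutation test), so a rerun with the same configuration and
seed produces byte-identical outputs; the manifest records inputs,
parameters, derived seeds and a sha256 checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import networkx as nx

from ccnet import genomic, gpea, inference, io, netstats, synthetic
from ccnet._util import derive_seeds, log


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Everything one run needs; paths may be None when simulating."""

    # inputs (all None -> simulate)
    expression_path: str | None = None
    positions_path: str | None = None
    gmt_path: str | None = None
    census_path: str | None = None
    # simulation
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    # inference
    B: int = 20
    alpha_mi: float = 0.05
    alpha_edge: float = 0.05
    # GPEA
    min_size: int = 3
    max_size: int = 999
    alpha_gpea: float = 0.001
    gpea_correction: str = "bonferroni"
    alpha_census: float = 0.05
    # cooperativity
    E: int = 100_000
    alpha_cooc: float = 0.05
    # windows
    window: int = 1_000_000
    step: int = 500_000
    min_genes: int = 2
    gcc_flag_threshold: int = 10
    anchor: str = "start"
    # cspnn
    seeds_genes: list[str] = field(default_factory=list)
    # master seed
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_mi", "alpha_edge", "alpha_gpea", "alpha_census", "alpha_cooc"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise PipelineError(f"config: {name} must be in (0, 1)")
        given = [self.expression_path, self.positions_path, self.gmt_path, self.census_path]
        if any(given) and not (self.expression_path and self.positions_path):
            raise PipelineError(
                "config: supplying real data requires at least expression and positions paths"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _gpea_frame(results: list[gpea.GPEAResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.description,
                "n_genes": r.n_genes,
                "n_interactions": r.k,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "gcc_size": r.gcc_size,
                "census_count": r.census_count,
                "census_flag": "+" if r.census_enriched else "",
            }
            for r in results
        ]
    )


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every stage, write results under ``outdir``, return the manifest."""
    config.validate()
    io.ensure_dir(outdir)
    seeds = derive_seeds(config.seed, 3)
    seed_map = {"simulate": seeds[0], "infer": seeds[1], "cooccur": seeds[2]}
    outputs: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(outdir, name)
        outputs[name] = path
        return path

    # -- stage: simulate or load ---------------------------------------------
    try:
        if config.expression_path is None:
            sim_cfg = dataclasses.replace(config.sim, seed=seed_map["simulate"])
            truth = synthetic.simulate(sim_cfg)
            expr = synthetic.sample_expression(truth, sim_cfg)
            positions = truth.positions
            collection = truth.term_collection
            census = truth.census_genes
            chrom_lengths = sim_cfg.chromosome_lengths
            io.write_expression(expr, out("expression.tsv"))
            io.write_positions(positions, out("positions.tsv"))
            io.write_gmt(collection, out("terms.gmt"))
            io.write_gene_list(census, out("census.txt"))
            io.write_network(truth.true_network, out("truth_edges.tsv"))
        else:
            expr = io.read_expression(config.expression_path)
            positions = io.read_positions(config.positions_path)
            collection = io.read_gmt(config.gmt_path) if config.gmt_path else None
            census = io.read_gene_list(config.census_path) if config.census_path else set()
            chrom_lengths = (
                positions.groupby("chromosome")["end"].max().astype(int).to_dict()
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"simulate/load: {exc}") from exc

    # -- stage: infer ----------------------------------------------------------
    try:
        net, edge_stats, _ = inference.bc3net(
            expr,
            B=config.B,
            alpha_mi=config.alpha_mi,
            alpha_edge=config.alpha_edge,
            seed=seed_map["infer"],
        )
        io.write_network(net, out("network.tsv"), edge_stats=edge_stats)
        io.write_sif(net, out("network.sif"))
    except Exception as exc:
        raise PipelineError(f"infer: {exc}") from exc

    # -- stage: summarize -------------------------------------------------------
    try:
        summary = netstats.network_summary(net)
        io.write_key_values(dataclasses.asdict(summary), out("summary.tsv"))
    except Exception as exc:
        raise PipelineError(f"summarize: {exc}") from exc

    # -- stage: gpea -------------------------------------------------------------
    try:
        if collection is not None and len(collection):
            results = gpea.run_gpea(
                net,
                collection,
                min_size=config.min_size,
                max_size=config.max_size,
                alpha=config.alpha_gpea,
                correction=config.gpea_correction,
            )
            if census:
                gpea.annotate_census(
                    results, collection, census, set(net.nodes), alpha=config.alpha_census
                )
            _gpea_frame(results).to_csv(out("gpea.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"gpea: {exc}") from exc

    # -- stage: cooccur -----------------------------------------------------------
    try:
        cooc = genomic.cooperativity_test(
            net, positions, E=config.E, alpha=config.alpha_cooc, seed=seed_map["cooccur"]
        )
        cooc.s.to_csv(out("cooperativity_counts.tsv"), sep="\t")
        cooc.p_adjusted.to_csv(out("cooperativity_p_adjusted.tsv"), sep="\t")
        sig = cooc.significant_pairs(config.alpha_cooc)
        with open(out("cooperativity_significant.tsv"), "w", encoding="utf-8") as fh:
            fh.write("chrom_a\tchrom_b\tp_adjusted\n")
            for a, b, padj in sig:
                fh.write(f"{a}\t{b}\t{padj!r}\n")
        cis, trans, _ = genomic.classify_cis_trans(net, positions)
        sets = genomic.ecs_sets(edge_stats, positions)
        ecs = genomic.ecs_summary(sets)
        io.write_key_values(
            {
                "cis_count": cis,
                "trans_count": trans,
                "cis_percent": 100.0 * cis / (cis + trans) if cis + trans else float("nan"),
                "cis_median_of_means_ecr": ecs.cis_median_of_means,
                "trans_median_of_means_ecr": ecs.trans_median_of_means,
                "n_cis_sets": ecs.n_cis_sets,
                "n_trans_sets": ecs.n_trans_sets,
            },
            out("cis_trans.tsv"),
        )
        ecs.per_pair_mean.to_csv(out("ecs_mean.tsv"), sep="\t")
        ecs.per_pair_median.to_csv(out("ecs_median.tsv"), sep="\t")
    except Exception as exc:
        raise PipelineError(f"cooccur: {exc}") from exc

    # -- stage: windows ------------------------------------------------------------
    try:
        windows = genomic.make_windows(chrom_lengths, config.window, config.step)
        wres = genomic.window_gpea(
            net,
            positions,
            windows,
            min_genes=config.min_genes,
            alpha=config.alpha_gpea,
            anchor=config.anchor,
            gcc_flag_threshold=config.gcc_flag_threshold,
            collection=collection,
            annotation_alpha=config.alpha_census,
        )
        wres.to_csv(out("windows.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"windows: {exc}") from exc

    # -- stage: cspnn -----------------------------------------------------------------
    try:
        seeds_genes = config.seeds_genes or sorted(census)[:6]
        seeds_present = [s for s in seeds_genes if s in net]
        if seeds_present:
            result = netstats.cspnn(net, seeds_present)
            io.write_network(result.network, out("cspnn_edges.tsv"))
            roles = result.roles()
            with open(out("cspnn_nodes.tsv"), "w", encoding="utf-8") as fh:
                fh.write("gene\trole\n")
                for g in sorted(roles):
                    fh.write(f"{g}\t{roles[g]}\n")
        else:
            log.warning("cspnn skipped: no seed genes present in the network")
    except Exception as exc:
        raise PipelineError(f"cspnn: {exc}") from exc

    # -- manifest ----------------------------------------------------------------------
    manifest = {
        "parameters": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("sim", "seeds_genes")
            },
            "sim": dataclasses.asdict(config.sim),
            "seeds_genes": list(config.seeds_genes),
        },
        "derived_seeds": seed_map,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
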