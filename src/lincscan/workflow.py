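"""End-to-end workflow on simulated data: simulate -> identify -> conserve ->
profile -> network -> enrich, with a machine-readable summary."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import conservation as cons
from . import expression_profiles as ep
from .config import RunConfig
from .enrichment import go_enrich, results_frame
from .io_formats import write_bed, write_expression_table, write_fasta, write_gtf, write_sample_metadata
from .pipeline_filters import run_pipeline
from .synthetic_data import STAGE_NAMES, simulate_expression, simulate_genome

logger = logging.getLogger(__name__)


def development_traits(matrix) -> list[cx.TraitVector]:
    """The three development trait vectors from sample metadata."""
    days = np.array([m.time_days for m in matrix.samples], dtype=float)
    ranks = np.array([m.time_rank for m in matrix.samples], dtype=float)
    stage_order = [s for s in STAGE_NAMES if s in {m.stage for m in matrix.samples}]
    ordinal = np.array(
        [stage_order.index(m.stage) + 1 for m in matrix.samples], dtype=float
    )
    return [
        cx.TraitVector("time_days", days),
        cx.TraitVector("time_order", ranks),
        cx.TraitVector("stage_ordinal", ordinal),
    ]


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage on the simulated scene and write a summary JSON.

    Returns the summary dict; everything is deterministic in config.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    logger.info("simulate: seed=%d", config.seed)
    scene = simulate_genome(config.simulation)
    tissue_matrix, dev_matrix = simulate_expression(scene.truth, config.simulation)
    inputs = outdir / "inputs"
    scene.write(inputs)
    write_expression_table(tissue_matrix, inputs / "tissue_fpkm.tsv")
    write_sample_metadata(tissue_matrix.samples, inputs / "tissue_meta.tsv")
    write_expression_table(dev_matrix, inputs / "development_fpkm.tsv")
    write_sample_metadata(dev_matrix.samples, inputs / "development_meta.tsv")

    logger.info("identify: %d assembled transcripts", len(scene.assembly))
    result = run_pipeline(
        scene.assembly,
        scene.genome,
        scene.annotation,
        hk_db=scene.housekeeping_db,
        min_length=config.min_length,
        orf_max=config.orf_max,
        flank_bp=config.flank_bp,
        hk_evalue=config.hk_evalue,
        cluster_identity=config.cluster_identity,
    )
    catalog = sorted(result.catalog, key=lambda t: t.transcript_id)
    catalog_ids = [t.transcript_id for t in catalog]
    write_gtf(catalog, outdir / "catalog.gtf")
    write_bed(catalog, outdir / "catalog.bed")
    write_fasta({t.transcript_id: t.sequence for t in catalog}, outdir / "catalog.fa")
    result.report.write_tsv(outdir / "filter_report.tsv")
    summary["filter_counts"] = result.report.counts()
    summary["catalog_size"] = len(catalog)
    summary["mean_linc_length_bp"] = round(
        float(np.mean([t.length for t in catalog])), 1
    ) if catalog else 0.0
    summary["pct_single_exon"] = round(
        100.0 * sum(1 for t in catalog if t.n_exons == 1) / len(catalog), 1
    ) if catalog else 0.0

    logger.info("conserve: %d subject genomes", len(scene.subject_genomes))
    linc_seqs = {t.transcript_id: t.sequence for t in catalog}
    cons_summary = cons.conservation_summary(linc_seqs, scene.subject_genomes)
    pd.DataFrame(
        [
            {"species": sp, "n_conserved": len(ids), "linc_ids": ",".join(sorted(ids))}
            for sp, ids in sorted(cons_summary.per_species_conserved.items())
        ]
    ).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    summary["conserved_per_species"] = {
        sp: len(ids) for sp, ids in sorted(cons_summary.per_species_conserved.items())
    }
    summary["n_conserved_all_species"] = len(cons_summary.intersection_all)

    logger.info("profile: tissue + development expression")
    linc_set = set(catalog_ids)
    expressed_tissue = ep.expressed_set(tissue_matrix, config.min_fpkm) & linc_set
    spec_results, tissue_counts = ep.tissue_specific(
        tissue_matrix.subset(sorted(linc_set)),
        tau_threshold=config.tau_threshold,
        min_fpkm=config.min_fpkm,
    )
    pd.DataFrame(
        [
            {"feature_id": r.feature_id, "tau": r.tau, "argmax_tissue": r.argmax_tissue}
            for r in sorted(spec_results.values(), key=lambda r: r.feature_id)
        ]
    ).to_csv(outdir / "tau_table.tsv", sep="\t", index=False)
    summary["n_expressed_tissue"] = len(expressed_tissue)
    summary["n_tissue_specific"] = int(sum(tissue_counts.values()))
    summary["tissue_specific_counts"] = {t: int(c) for t, c in sorted(tissue_counts.items())}

    stage_calls = ep.stage_specific(dev_matrix.subset(sorted(linc_set)), config.min_fpkm)
    specific_calls = [c for c in stage_calls if c.specific_stage is not None]
    stage_counts: dict[str, int] = {}
    for c in specific_calls:
        stage_counts[c.specific_stage] = stage_counts.get(c.specific_stage, 0) + 1
    pd.DataFrame(
        [
            {
                "feature_id": c.feature_id,
                "stages_expressed": ",".join(sorted(c.stages_expressed)),
                "specific_stage": c.specific_stage or "",
            }
            for c in stage_calls
        ]
    ).to_csv(outdir / "stage_calls.tsv", sep="\t", index=False)
    summary["n_stage_specific"] = len(specific_calls)
    summary["stage_specific_counts"] = dict(sorted(stage_counts.items()))

    stages_present = [s for s in STAGE_NAMES if s in {m.stage for m in dev_matrix.samples}]
    eyed, spat = stages_present[-2], stages_present[-1]
    on_a, on_b = ep.settlement_contrast(
        dev_matrix.subset(sorted(linc_set)), eyed, spat, config.hi_fpkm, config.min_fpkm
    )
    with open(outdir / "settlement.tsv", "w") as fh:
        fh.write("set\tfeature_id\n")
        for fid in sorted(on_a):
            fh.write(f"on_in_{eyed}_off_in_{spat}\t{fid}\n")
        for fid in sorted(on_b):
            fh.write(f"on_in_{spat}_off_in_{eyed}\t{fid}\n")
    summary["settlement_on_eyed_larvae"] = len(on_a)
    summary["settlement_on_spat"] = len(on_b)

    mrna_ids = [f for f in tissue_matrix.feature_ids if f not in linc_set]
    dc = ep.density_compare(
        tissue_matrix.values.loc[sorted(expressed_tissue)].mean(axis=1),
        tissue_matrix.values.loc[mrna_ids].mean(axis=1),
    )
    pd.DataFrame(
        {
            "log2_fpkm_plus1": dc.grid,
            "linc_density": dc.linc_density,
            "mrna_density": dc.mrna_density,
        }
    ).to_csv(outdir / "kde_curves.tsv", sep="\t", index=False)
    summary["ks_statistic"] = round(dc.ks_statistic, 4)
    summary["ks_p_value"] = float(dc.p_value)

    neighbors, fraction, neighbor_genes = ep.neighbor_distances(
        catalog, scene.annotation, window=config.neighbor_window
    )
    pd.DataFrame(
        [
            {
                "linc_id": r.linc_id,
                "nearest_gene_id": r.nearest_gene_id,
                "distance_bp": r.distance_bp,
                "within_10kb": r.within_10kb,
            }
            for r in neighbors
        ]
    ).to_csv(outdir / "neighbors.tsv", sep="\t", index=False)
    summary["fraction_within_10kb"] = round(fraction, 3)
    summary["n_neighbor_genes"] = len(neighbor_genes)

    logger.info("network: %d features x %d samples", *dev_matrix.values.shape)
    traits = development_traits(dev_matrix)
    net = cx.build_network(
        dev_matrix.values, traits, config.network, linc_ids=linc_set
    )
    pd.DataFrame(
        [
            {"feature_id": fid, "module": net.module_assignment[fid]}
            for fid in net.feature_ids
        ]
    ).to_csv(outdir / "module_membership.tsv", sep="\t", index=False)
    grid_rows = []
    for mod in net.modules:
        row = {"module": mod.label, "size": len(mod.member_ids)}
        for name, (rho, p) in sorted(mod.trait_correlations.items()):
            row[f"{name}_rho"] = round(rho, 4)
            row[f"{name}_p"] = p
        row["flagged_trait_related"] = mod.flagged_trait_related
        grid_rows.append(row)
    pd.DataFrame(grid_rows).to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "feature_id": g.feature_id,
                "module": g.module,
                "rho": g.rho,
                "p": g.p,
                "p_fdr": g.p_fdr,
                "sign": g.sign,
            }
            for g in net.gene_trait_results
        ]
    ).to_csv(outdir / "gene_trait.tsv", sep="\t", index=False)
    with open(outdir / "hubs.tsv", "w") as fh:
        fh.write("module\thub_id\tkIM\n")
        for label in sorted(net.hubs):
            for h in net.hubs[label]:
                kim = dict(
                    next(m for m in net.modules if m.label == label).intramodular_connectivity
                )[h]
                fh.write(f"{label}\t{h}\t{kim:.4f}\n")
    pd.DataFrame(net.edges, columns=["module", "node1", "node2", "weight"]).to_csv(
        outdir / "edges.tsv", sep="\t", index=False
    )
    flagged = [m for m in net.modules if m.flagged_trait_related]
    summary["soft_power"] = net.beta
    summary["n_modules"] = len(net.modules)
    summary["module_sizes"] = {m.label: len(m.member_ids) for m in net.modules}
    summary["n_trait_related_modules"] = len(flagged)
    summary["trait_related_modules"] = sorted(m.label for m in flagged)
    summary["n_hub_linked_lincs"] = len(net.linked_lincs)
    summary["hub_linked_lincs"] = sorted(net.linked_lincs)
    sig_lincs = [
        g
        for g in net.gene_trait_results
        if g.feature_id in linc_set
        and not np.isnan(g.p_fdr)
        and g.p_fdr < config.network.gene_trait_fdr_max
        and g.module != cx.UNASSIGNED
    ]
    summary["n_linc_trait_correlated"] = len(sig_lincs)
    summary["n_linc_trait_negative"] = sum(1 for g in sig_lincs if g.sign == "-")
    summary["n_linc_trait_positive"] = sum(1 for g in sig_lincs if g.sign == "+")

    logger.info("enrich: %d flagged modules", len(flagged))
    background = [f for f in dev_matrix.feature_ids if f not in linc_set]
    enriched_top = {}
    for mod in flagged:
        gene_members = [f for f in mod.member_ids if f not in linc_set]
        if not gene_members:
            continue
        results = go_enrich(gene_members, background, scene.truth.term_map)
        results_frame(results).to_csv(
            outdir / f"enrichment_{mod.label}.tsv", sep="\t", index=False
        )
        if results:
            enriched_top[mod.label] = results[0].term_id
    summary["top_enriched_term_per_module"] = dict(sorted(enriched_top.items()))
    if neighbor_genes:
        neighbor_results = go_enrich(
            sorted(neighbor_genes), sorted(set(scene.truth.coding_ids)), scene.truth.term_map
        )
        results_frame(neighbor_results).to_csv(
            outdir / "enrichment_neighbors.tsv", sep="\t", index=False
        )
        summary["n_neighbor_terms_raw_significant"] = sum(
            1 for r in neighbor_results if r.p < 0.05
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
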