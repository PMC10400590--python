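"""End-to-end orchestration: simulate -> demux -> align -> call -> cellcall
-> cluster -> dmr, with plain-text intermediates and a JSON run report.

Each stage writes standard text formats (FASTA, FASTQ, TSV, BED-like
tables) so any stage can also be fed externally produced data.  A stage
whose outputs already exist is skipped, making reruns no-ops and the
run resumable.  All randomness derives from one master seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from dropmet import droplet_stats as ds
from dropmet import sim, demux as dx, bsalign, methcall, cellqc, methcluster, dmrcall
from dropmet.allctable import read_allc, write_allc
from dropmet.config import load_config

log = logging.getLogger("dropmet")


def _child_seed(master: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % 2**31
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % 2**31)


def design_from_config(cfg: dict) -> ds.DropletDesign:
    d = cfg["design"]
    return ds.DropletDesign(
        droplet_diameter=d["droplet_diameter"],
        aqueous_flow=d["aqueous_flow"],
        run_time=d["run_time"],
        cell_lambda=ds.calibrate_lambda(d["occupied_fraction"]),
        bead_occupancy=d["bead_occupancy"],
        fusion_efficiency=d["fusion_efficiency"],
        barcode_droplet_rate=d["barcode_droplet_rate"],
        n_beads=d["n_beads"],
    )


def design_table(cfg: dict) -> dict:
    """Closed-form design statistics for the report / `design` subcommand."""
    d = cfg["design"]
    lam = ds.calibrate_lambda(d["occupied_fraction"])
    return {
        "cell_lambda": lam,
        "p_single_cell": ds.poisson_occupancy(lam, "exactly_k", 1),
        "p_double_occupancy": ds.poisson_occupancy(lam, "exactly_k", 2),
        "p_occupied": ds.poisson_occupancy(lam, "at_least_k", 1),
        "droplet_count": ds.droplet_count(
            d["aqueous_flow"], d["run_time"], d["droplet_diameter"]
        ),
        "generation_rate_per_s": ds.generation_rate(
            d["aqueous_flow"], d["droplet_diameter"]
        ),
        "fusion_runtime_min": ds.fusion_runtime(
            d["n_beads"], d["bead_occupancy"], d["barcode_droplet_rate"]
        ),
    }


def run(config: dict | None = None, outdir="run", config_path=None) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    cfg = config if config is not None else load_config(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"config": cfg, "stages": {}}

    # ---- simulate -------------------------------------------------------
    genome_fa = out / "genome.fa"
    r1_fq, r2_fq = out / "R1.fastq.gz", out / "R2.fastq.gz"
    sidecar_tsv = out / "read_truth.tsv"
    planted_bed = out / "planted_dmrs.tsv"
    truth_tsv = out / "barcode_truth.tsv"
    if not r2_fq.exists():
        log.info("stage simulate")
        g = cfg["genome"]
        genome = sim.make_genome(
            n_contigs=g["n_contigs"],
            contig_length=g["contig_length"],
            gc_fraction=g["gc_fraction"],
            n_species=g["n_species"],
            spike_length=g["spike_length"],
            seed=_child_seed(seed, "genome"),
        )
        genome.to_fasta(genome_fa)
        m = cfg["methylome"]
        methylomes, dmr_table = sim.make_methylomes(
            genome,
            [tuple(t) for t in m["type_specs"]],
            n_dmrs=m["n_dmrs"],
            dmr_length=m["dmr_length"],
            dmr_depth=m["dmr_depth"],
            seed=_child_seed(seed, "methylome"),
        )
        dmr_table.to_csv(planted_bed, sep="\t", index=False)
        design = design_from_config(cfg)
        species_by_type = None
        if g["n_species"] == 2:
            names = [t[0] for t in m["type_specs"]]
            species_by_type = {t: ("A", "B")[i % 2] for i, t in enumerate(names)}
        truth = sim.simulate_experiment(
            design,
            cfg["experiment"]["n_cells_by_type"],
            seed=_child_seed(seed, "experiment"),
            species_by_type=species_by_type,
        )
        truth.to_tsv(truth_tsv)
        r = cfg["reads"]
        sidecar = sim.simulate_reads(
            truth,
            genome,
            {mm.type_name: mm for mm in methylomes},
            r1_fq,
            r2_fq,
            layout=sim.ReadLayout(read_length=r["read_length"]),
            frag_mean=r["frag_mean"],
            frag_sd=r["frag_sd"],
            min_frag=r["min_frag"],
            conversion_rate=r["conversion_rate"],
            seq_error=r["seq_error"],
            duplication_rate=r["duplication_rate"],
            reads_per_cell=r["reads_per_cell"],
            spike_fraction=r["spike_fraction"],
            contamination_rate=r["contamination_rate"],
            seed=_child_seed(seed, "reads"),
        )
        sidecar.to_csv(sidecar_tsv, sep="\t", index=False)
    genome = sim.SyntheticGenome.from_fasta(genome_fa)
    truth_df = pd.read_csv(truth_tsv, sep="\t")
    report["stages"]["simulate"] = {
        "n_barcodes": len(truth_df),
        "n_cell_barcodes": int((truth_df["kind"] != "noise").sum()),
    }
    report["stages"]["design"] = design_table(cfg)

    # ---- demux + align --------------------------------------------------
    aln_tsv = out / "alignments.tsv"
    whitelist_tsv = out / "whitelist.tsv"
    counts, n_short_wl = dx.count_barcodes(r2_fq)
    design = design_from_config(cfg)
    # X = cells expected from the experimental parameters, not from truth
    n_input_cells = sum(cfg["experiment"]["n_cells_by_type"].values())
    n_droplets = n_input_cells / design.cell_lambda
    expected_cells = max(
        1,
        int(
            round(
                ds.expected_barcoded_cells(
                    n_droplets,
                    cfg["design"]["occupied_fraction"],
                    design.bead_occupancy,
                    design.fusion_efficiency,
                )
            )
        ),
    )
    whitelist = dx.build_whitelist(
        counts, expected_cells, cfg["cellcall"]["multiplier"]
    )
    whitelist.to_tsv(whitelist_tsv)
    result = dx.demultiplex(r1_fq, r2_fq, whitelist)
    report["stages"]["demux"] = result.qc_dict()
    if not aln_tsv.exists():
        log.info("stage align (%d barcodes)", len(result.read_sets))
        index = bsalign.ConvertedIndex(genome, k=cfg["align"]["k"])
        alns = []
        for bc in sorted(result.read_sets):
            alns.extend(
                bsalign.align_read_set(
                    result.read_sets[bc], index, max_edit=cfg["align"]["max_edit"]
                )
            )
        bsalign.alignments_to_frame(alns).to_csv(aln_tsv, sep="\t", index=False)
    aln_df = pd.read_csv(aln_tsv, sep="\t")
    alignments = bsalign.frame_to_alignments(aln_df)
    report["stages"]["align"] = {"aligned_mates": len(alignments)}

    # ---- call -----------------------------------------------------------
    allc_dir = out / "allc"
    summary_tsv = out / "summary.tsv"
    if not summary_tsv.exists():
        log.info("stage call")
        allc_dir.mkdir(exist_ok=True)
        by_bc: dict[str, list] = {}
        for a in alignments:
            by_bc.setdefault(a.barcode, []).append(a)
        rows = []
        classes = sim.methylome.site_classes(genome)
        for bc in sorted(result.read_sets):
            rs = result.read_sets[bc]
            alns = by_bc.get(bc, [])
            uniq = methcall.deduplicate(alns)
            allc = methcall.call_methylation(uniq, genome, classes)
            write_allc(allc, allc_dir / f"allc_{bc}.tsv")
            rows.append(
                methcall.cell_summary(
                    bc,
                    counts.get(bc, len(rs)),
                    len(rs.r1) + len(rs.r2),
                    alns,
                    uniq,
                    allc,
                    genome,
                    spike_contig=genome.spike_contig,
                )
            )
        pd.DataFrame(rows).to_csv(summary_tsv, sep="\t", index=False)
    summary = pd.read_csv(summary_tsv, sep="\t")
    spike_mc = spike_cov = 0
    for p in sorted(allc_dir.glob("allc_*.tsv")):
        allc = read_allc(p)
        spike_rows = allc[allc["chrom"] == genome.spike_contig]
        spike_mc += int(spike_rows["mc"].sum())
        spike_cov += int(spike_rows["cov"].sum())
    report["stages"]["call"] = {
        "mean_unique_reads": float(summary["unique_reads"].mean()),
        "pooled_conversion_rate": 1.0 - spike_mc / max(1, spike_cov),
    }

    # ---- cellcall -------------------------------------------------------
    cellcalls_tsv = out / "cellcalls.tsv"
    fit = cellqc.fit_efficiency_mixture(
        summary["mapping_efficiency"], tuple(cfg["cellcall"]["k_range"])
    )
    cells = cellqc.call_cells(summary, fit)
    summary["call"] = ["cell" if b in cells else "noise" for b in summary["barcode"]]
    summary["cutoff"] = fit.cutoff
    summary.to_csv(cellcalls_tsv, sep="\t", index=False)
    report["stages"]["cellcall"] = {
        "n_candidates": len(summary),
        "n_cells": len(cells),
        "cutoff": fit.cutoff,
        "k": fit.k,
        "top_component": {"mu": fit.selected.mu, "sigma": fit.selected.sigma},
    }
    if cfg["genome"]["n_species"] == 2:
        sp_cols = [c for c in summary.columns if c.startswith("frac_")]
        counts_df = (
            summary[summary["call"] == "cell"]
            .set_index("barcode")[sp_cols]
            .mul(summary.set_index("barcode").loc[lambda d: d["call"] == "cell", "unique_reads"], axis=0)
            .round()
        )
        counts_df.columns = [c.removeprefix("frac_") for c in sp_cols]
        calls, purity_summary = cellqc.species_purity(
            counts_df, cfg["cellcall"]["purity_threshold"]
        )
        calls.to_csv(out / "species_calls.tsv", sep="\t", index=False)
        report["stages"]["species"] = purity_summary

    # ---- cluster --------------------------------------------------------
    labels_tsv = out / "labels.tsv"
    allc_by_cell = {
        bc: read_allc(allc_dir / f"allc_{bc}.tsv") for bc in sorted(cells)
    }
    cl = cfg["cluster"]
    matrix = methcluster.build_matrix(
        allc_by_cell,
        bin_width=cl["bin_width"],
        cls=cl["cls"],
        min_sites_per_bin=cl["min_sites_per_bin"],
        min_cell_fraction_per_bin=cl["min_cell_fraction_per_bin"],
        spike_contig=genome.spike_contig,
    )
    normed = methcluster.normalize(matrix)
    annotation = methcluster.reduce_and_cluster(
        normed,
        n_pcs=cl["n_pcs"],
        knn_k=cl["knn_k"],
        resolution=cl["resolution"],
        seed=_child_seed(seed, "cluster"),
    )
    dmr_sets = pd.read_csv(planted_bed, sep="\t")
    if annotation.n_clusters >= 2:
        methcluster.annotate_clusters(
            annotation, allc_by_cell, dmr_sets, z_threshold=cl["z_threshold"]
        )
        annotation.zscores.to_csv(out / "zscores.tsv", sep="\t")
    labels = annotation.labels.to_frame()
    labels["label"] = [
        annotation.cluster_labels.get(c) or "" for c in annotation.labels
    ]
    labels.to_csv(labels_tsv, sep="\t")
    normed.values.to_csv(out / "matrix.tsv", sep="\t")
    report["stages"]["cluster"] = {
        "n_clusters": int(annotation.n_clusters),
        "sizes": annotation.labels.value_counts().to_dict(),
        "labels": {str(k): v for k, v in annotation.cluster_labels.items()},
    }

    # ---- dmr ------------------------------------------------------------
    if annotation.n_clusters >= 2:
        top2 = annotation.labels.value_counts().index[:2]
        groups = [
            dmrcall.merge_pseudobulk(
                [allc_by_cell[bc] for bc in annotation.labels.index[annotation.labels == c]]
            )
            for c in top2
        ]
        d = cfg["dmr"]
        regions = dmrcall.call_dmrs(
            groups[0],
            groups[1],
            min_cov=d["min_cov"],
            fdr=d["fdr"],
            min_delta=d["min_delta"],
            merge_dist=d["merge_dist"],
            min_cpgs=d["min_cpgs"],
        )
        dmrcall.regions_to_frame(regions).to_csv(out / "dmrs.tsv", sep="\t", index=False)
        report["stages"]["dmr"] = {
            "groups": [int(top2[0]), int(top2[1])],
            "n_regions": len(regions),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
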