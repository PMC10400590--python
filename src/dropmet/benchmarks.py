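"""Self-contained benchmark scenarios for the pipeline's headline claims.

Each function builds its inputs from the synthetic-data generator at the
study's stated conditions, runs the relevant pipeline stages, and
returns the measured quantities.  They are used both by the acceptance
test-suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from dropmet import (
    sim,
    droplet_stats as ds,
    demux as dx,
    bsalign,
    methcall,
    cellqc,
    methcluster,
    dmrcall,
)

CELL_LINE_TARGETS = [("typeA", 0.505, 0.010), ("typeB", 0.682, 0.011),
                     ("typeC", 0.630, 0.009)]


def design_numbers() -> dict:
    """Closed-form droplet-design statistics at the standard settings."""
    lam = ds.calibrate_lambda(0.10)
    return {
        "p_double_occupancy_pct": 100 * ds.poisson_occupancy(lam, "exactly_k", 2),
        "droplet_count_millions": ds.droplet_count(4.0, 10.0, 35.0) / 1e6,
        "generation_rate_per_s": ds.generation_rate(4.0, 35.0),
        "fusion_runtime_min": ds.fusion_runtime(20_000, 0.07, 132.0),
    }


def conversion_benchmark(seed: int) -> dict:
    """Spike-in conversion-rate estimation through the full read path.

    Reads are simulated at 99.0% conversion with a heavy spike-in load,
    demultiplexed, three-letter aligned, deduplicated and called; the
    estimate is pooled 1 - mc/cov on the spike contig.
    """
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    genome = sim.make_genome(n_contigs=1, contig_length=60_000,
                             spike_length=20_000, seed=rng)
    meths, _ = sim.make_methylomes(genome, [("t", 0.6, 0.01)], n_dmrs=2, seed=rng)
    truth = sim.simulate_experiment(
        ds.DropletDesign(bead_occupancy=1.0, fusion_efficiency=1.0, cell_lambda=1.0),
        {"t": 25}, seed=rng,
    )
    with tempfile.TemporaryDirectory() as td:
        r1, r2 = Path(td) / "r1.fastq", Path(td) / "r2.fastq"
        sim.simulate_reads(
            truth, genome, {"t": meths[0]}, r1, r2,
            conversion_rate=0.99, reads_per_cell=500, spike_fraction=0.25,
            noise_reads_mean=0, seed=rng,
        )
        counts, _ = dx.count_barcodes(r2)
        wl = dx.build_whitelist(counts, expected_cells=len(counts), multiplier=1.0)
        result = dx.demultiplex(r1, r2, wl)
    index = bsalign.ConvertedIndex(genome, k=24)
    spike_mc = spike_cov = 0
    for bc, rs in result.read_sets.items():
        uniq = methcall.deduplicate(bsalign.align_read_set(rs, index))
        allc = methcall.call_methylation(uniq, genome)
        spike = allc[allc["chrom"] == "spike"]
        spike_mc += int(spike["mc"].sum())
        spike_cov += int(spike["cov"].sum())
    return {
        "conversion_rate_pct": 100 * (1 - spike_mc / spike_cov),
        "n_spike_calls": spike_cov,
    }


def _sample_population(genome, meths, n_cells, reads_per_cell, rng):
    allc_by_cell, true_type = {}, {}
    for i in range(n_cells):
        m = meths[i % len(meths)]
        bc = f"cell{i:03d}"
        allc_by_cell[bc] = sim.sample_cell_allc(
            genome, m, n_reads=reads_per_cell, seed=rng
        )
        true_type[bc] = m.type_name
    return allc_by_cell, true_type


def clustering_benchmark(seed: int, n_cells: int = 90,
                         reads_per_cell: int = 15_000) -> dict:
    """Three-type clustering recovery with planted DMR annotation.

    Cells are sampled at the fragment level from three methylomes at the
    cell-line global mCG targets, binned at 100 kb, normalized, reduced
    to the top 50 PCs and Louvain-clustered; clusters are annotated by
    planted-DMR z-scores and their pseudobulk global mCG compared with
    the generating targets.
    """
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    genome = sim.make_genome(n_contigs=20, contig_length=300_000,
                             spike_length=20_000, seed=rng)
    meths, dmr_table = sim.make_methylomes(genome, CELL_LINE_TARGETS, seed=rng)
    allc_by_cell, true_type = _sample_population(
        genome, meths, n_cells, reads_per_cell, rng
    )
    mat = methcluster.build_matrix(allc_by_cell, bin_width=100_000)
    ann = methcluster.reduce_and_cluster(
        methcluster.normalize(mat), n_pcs=50, seed=int(rng.integers(2**31))
    )
    ari = adjusted_rand_score([true_type[b] for b in ann.labels.index], ann.labels)
    out = {"ari": float(ari), "n_clusters": int(ann.n_clusters)}
    if ann.n_clusters >= 2:
        ann = methcluster.annotate_clusters(ann, allc_by_cell, dmr_table)
        correct = recovered = 0
        targets = {name: t for name, t, _ in CELL_LINE_TARGETS}
        errors = {}
        for c, label in ann.cluster_labels.items():
            members = ann.labels.index[ann.labels == c]
            modal = pd.Series([true_type[b] for b in members]).mode()[0]
            if label == modal:
                correct += 1
            pseudo = dmrcall.merge_pseudobulk([allc_by_cell[b] for b in members])
            level = methcall.global_levels(pseudo, "CG")
            errors[modal] = 100 * abs(level - targets[modal])
        out["n_labels_correct"] = correct
        out["max_global_mcg_error_pct_points"] = max(errors.values())
        out["global_mcg_errors"] = errors
    return out


def annotation_stability(seed: int, n_seeds: int = 10, n_cells: int = 45,
                         reads_per_cell: int = 15_000) -> dict:
    """Fraction of seeded runs in which every cluster gets its true label."""
    base = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_seeds):
        res = clustering_benchmark(int(base.integers(2**31)), n_cells,
                                   reads_per_cell)
        if (
            res.get("n_clusters") == 3
            and res.get("n_labels_correct") == res["n_clusters"]
        ):
            ok += 1
    return {"runs_all_labels_correct": ok, "n_runs": n_seeds}


def cell_calling_benchmark(seed: int, n_cells: int = 1000) -> dict:
    """EM + mu-sigma cell calling on the bimodal efficiency population.

    Noise efficiencies ~ N(0.15, 0.08^2), cell efficiencies
    ~ N(0.65, 0.05^2); candidates are 2.5X so noise outnumbers cells
    1.5:1 among candidates.
    """
    rng = np.random.default_rng(seed)
    n_noise = int(1.5 * n_cells)
    eff = np.clip(
        np.r_[rng.normal(0.15, 0.08, n_noise), rng.normal(0.65, 0.05, n_cells)],
        0, 1,
    )
    is_cell = np.r_[np.zeros(n_noise, bool), np.ones(n_cells, bool)]
    names = np.array([f"bc{i:05d}" for i in range(eff.size)])
    fit = cellqc.fit_efficiency_mixture(eff)
    called = cellqc.call_cells(dict(zip(names, eff)), fit)
    truth = set(names[is_cell])
    tp = len(called & truth)
    return {
        "precision": tp / len(called),
        "recall": tp / len(truth),
        "mu_error": abs(fit.selected.mu - 0.65),
        "sigma_error": abs(fit.selected.sigma - 0.05),
        "cutoff": fit.cutoff,
    }


def species_purity_benchmark(seed: int, n_per_species: int = 400,
                             doublet_fraction: float = 0.02,
                             contamination: float = 0.01,
                             mean_depth: int = 2_000) -> dict:
    """Barnyard purity classification with contamination and doublets."""
    rng = np.random.default_rng(seed)
    n_doublets = int(round(doublet_fraction * 2 * n_per_species))
    rows, kinds = [], []
    for sp in ("A", "B"):
        for _ in range(n_per_species):
            d = max(10, int(rng.lognormal(math.log(mean_depth), 0.35)))
            own = rng.binomial(d, 1 - contamination)
            rows.append([own, d - own] if sp == "A" else [d - own, own])
            kinds.append("singlet")
    for _ in range(n_doublets):
        d1 = max(10, int(rng.lognormal(math.log(mean_depth), 0.35)))
        d2 = max(10, int(rng.lognormal(math.log(mean_depth), 0.35)))
        rows.append([d1, d2])
        kinds.append("doublet")
    counts = pd.DataFrame(rows, columns=["A", "B"])
    calls, summary = cellqc.species_purity(counts, threshold=0.90)
    kinds = np.array(kinds)
    pure = calls["call"].str.startswith("pure").to_numpy()
    return {
        "singlets_called_pure_pct": 100 * pure[kinds == "singlet"].mean(),
        "doublets_called_mixed_pct": 100 * (~pure[kinds == "doublet"]).mean(),
        "pure_fraction_pct": 100 * summary["pure_fraction"],
    }


def dmr_benchmark(seed: int) -> dict:
    """Planted-DMR recovery and null false-region control.

    One 2 kb region of 20 CpGs at 30x pseudobulk coverage loses 0.4 of
    its methylation in group B; the caller must recover it with high
    interval overlap.  Ten null pairs (no difference, 10^4 CpGs) probe
    the FDR control.
    """
    rng = np.random.default_rng(seed)

    def cpg_track(positions, mc, cov):
        n = len(positions)
        return pd.DataFrame(
            {
                "chrom": pd.Categorical(["chr1"] * n),
                "pos": np.asarray(positions, dtype=np.int64),
                "strand": pd.Categorical(["+"] * n, categories=["+", "-"]),
                "context": pd.Categorical(["CGA"] * n),
                "class": pd.Categorical(["CG"] * n, categories=["CG", "CH"]),
                "mc": np.asarray(mc, dtype=np.int32),
                "cov": np.asarray(cov, dtype=np.int32),
                "methylated": (np.asarray(mc) > 0).astype(np.int8),
            }
        )

    # planted region: 20 evenly spaced CpGs spanning 2 kb, background
    # CpGs every ~100 bp across a 40 kb contig
    span = (20_000, 22_000)
    background = np.arange(100, 40_000, 100)
    background = background[(background < span[0]) | (background >= span[1])]
    inside = np.linspace(span[0], span[1] - 1, 20).astype(int)
    positions = np.sort(np.r_[background, inside])
    in_dmr = (positions >= span[0]) & (positions < span[1])
    cov_a = rng.poisson(30, positions.size) + 1
    cov_b = rng.poisson(30, positions.size) + 1
    base = 0.7
    mc_a = rng.binomial(cov_a, base)
    mc_b = rng.binomial(cov_b, np.where(in_dmr, base - 0.4, base))
    regions = dmrcall.call_dmrs(
        cpg_track(positions, mc_a, cov_a), cpg_track(positions, mc_b, cov_b)
    )
    jaccard = 0.0
    for r in regions:
        inter = max(0, min(r.end, span[1]) - max(r.start, span[0]))
        union = max(r.end, span[1]) - min(r.start, span[0])
        jaccard = max(jaccard, inter / union)

    null_ok = 0
    for _ in range(10):
        pos = np.arange(1, 10_001) * 20
        ca = rng.poisson(30, pos.size) + 1
        cb = rng.poisson(30, pos.size) + 1
        null_regions = dmrcall.call_dmrs(
            cpg_track(pos, rng.binomial(ca, base), ca),
            cpg_track(pos, rng.binomial(cb, base), cb),
        )
        if len(null_regions) <= 1:
            null_ok += 1
    return {
        "planted_jaccard": jaccard,
        "n_regions": len(regions),
        "null_runs_at_most_one_false_region": null_ok,
    }
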