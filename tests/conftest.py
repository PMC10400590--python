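"""Shared fixtures: one small end-to-end simulation reused across modules.

Building the simulated experiment (genome, methylomes, droplet truth,
paired FASTQ, demultiplexing, alignment index) once per session keeps
the suite fast; tests that need different parameters build their own
small inputs locally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dropmet import sim, droplet_stats as ds, demux as dx, bsalign


@dataclass
class SimulatedRun:
    genome: sim.SyntheticGenome
    methylomes: list[sim.CellTypeMethylome]
    meth_by_type: dict[str, sim.CellTypeMethylome]
    dmr_table: object
    truth: sim.ExperimentTruth
    sidecar: object
    r1_path: str
    r2_path: str
    layout: sim.ReadLayout
    conversion_rate: float
    seq_error: float
    duplication_rate: float


@pytest.fixture(scope="session")
def small_run(tmp_path_factory) -> SimulatedRun:
    """A ~35-cell droplet experiment with reads, at modest depth."""
    out = tmp_path_factory.mktemp("simrun")
    genome = sim.make_genome(
        n_contigs=3, contig_length=80_000, spike_length=20_000, seed=11
    )
    methylomes, dmr_table = sim.make_methylomes(genome, n_dmrs=6, seed=11)
    truth = sim.simulate_experiment(
        ds.DropletDesign(), {"typeA": 200, "typeB": 200, "typeC": 200}, seed=12
    )
    layout = sim.ReadLayout()
    r1, r2 = str(out / "R1.fastq.gz"), str(out / "R2.fastq.gz")
    sidecar = sim.simulate_reads(
        truth,
        genome,
        {m.type_name: m for m in methylomes},
        r1,
        r2,
        layout=layout,
        conversion_rate=0.99,
        seq_error=0.001,
        duplication_rate=0.1,
        reads_per_cell=800,
        noise_reads_mean=30,
        seed=13,
    )
    return SimulatedRun(
        genome=genome,
        methylomes=methylomes,
        meth_by_type={m.type_name: m for m in methylomes},
        dmr_table=dmr_table,
        truth=truth,
        sidecar=sidecar,
        r1_path=r1,
        r2_path=r2,
        layout=layout,
        conversion_rate=0.99,
        seq_error=0.001,
        duplication_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_demux(small_run):
    counts, _ = dx.count_barcodes(small_run.r2_path)
    n_cells = len(small_run.truth.cell_barcodes)
    whitelist = dx.build_whitelist(counts, expected_cells=n_cells)
    result = dx.demultiplex(small_run.r1_path, small_run.r2_path, whitelist)
    return counts, whitelist, result


@pytest.fixture(scope="session")
def small_index(small_run) -> bsalign.ConvertedIndex:
    return bsalign.ConvertedIndex(small_run.genome, k=24)


@pytest.fixture(scope="session")
def small_alignments(small_run, small_demux, small_index):
    """Alignments per barcode for every whitelisted barcode."""
    _, _, result = small_demux
    return {
        bc: bsalign.align_read_set(result.read_sets[bc], small_index)
        for bc in sorted(result.read_sets)
    }


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
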