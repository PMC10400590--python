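"""Simulate a small droplet bisulfite experiment and align its reads.

Builds a toy genome with an unmethylated spike-in contig, three
cell-type methylomes, a realised droplet run, and paired FASTQ with the
ligation/barcode read architecture; then demultiplexes on the R2
barcode (bases 25-39), three-letter aligns both mates, and reports the
mapping-efficiency separation between cell and noise barcodes.
"""

import tempfile
from pathlib import Path

import numpy as np

from dropmet import sim, droplet_stats as ds, demux as dx, bsalign

genome = sim.make_genome(n_contigs=3, contig_length=80_000, spike_length=20_000,
                         seed=1)
methylomes, dmrs = sim.make_methylomes(genome, n_dmrs=6, seed=1)
truth = sim.simulate_experiment(ds.DropletDesign(),
                                {"typeA": 150, "typeB": 150, "typeC": 150}, seed=2)
print(f"{truth.n_droplets:,} droplets -> "
      f"{len(truth.cell_barcodes)} cell barcodes, "
      f"{len(truth.noise_barcodes)} noise barcodes")

with tempfile.TemporaryDirectory() as td:
    r1, r2 = Path(td) / "R1.fastq.gz", Path(td) / "R2.fastq.gz"
    sidecar = sim.simulate_reads(truth, genome,
                                 {m.type_name: m for m in methylomes},
                                 r1, r2, reads_per_cell=800, seed=3)
    print(f"{len(sidecar):,} read pairs emitted")

    counts, _ = dx.count_barcodes(r2)
    whitelist = dx.build_whitelist(counts, expected_cells=len(truth.cell_barcodes))
    result = dx.demultiplex(r1, r2, whitelist)
    print(f"demux: {result.qc_dict()}")

    index = bsalign.ConvertedIndex(genome, k=24)
    kinds = truth.barcodes.set_index("barcode")["kind"]
    eff = {"cell": [], "noise": []}
    for bc, rs in result.read_sets.items():
        if len(rs) == 0:
            continue
        alns = bsalign.align_read_set(rs, index)
        key = "noise" if kinds.get(bc) == "noise" else "cell"
        eff[key].append(bsalign.mapping_efficiency(rs, alns))
    print(f"mean mapping efficiency: cells {np.mean(eff['cell']):.3f}, "
          f"noise {np.mean(eff['noise']):.3f}")

# Cell barcodes align almost perfectly while noise barcodes (adapter
# dimers, scrambled fragments) fail -- this separation is what the
# downstream mixture-model cell caller exploits.
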