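"""Fragment-level methylome sampling straight to allc tables.

For studies of the downstream statistics (binned feature matrices,
clustering, DMR calling) the base-level FASTQ round trip adds cost but
no information: a unique read covering a cytosine contributes one
methylation call that is Bernoulli in the site's methylation
probability, inflated by bisulfite-conversion failure.  This sampler
draws per-cell coverage by placing unique reads on the genome and then
draws ``mc ~ Binomial(cov, p_eff)`` per site with

    p_eff = p + (1 - p) * (1 - conversion_rate)

which is exactly the marginal law of the full read-level simulator
after perfect alignment and deduplication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dropmet.seq import to_array, C, G
from dropmet.allctable import assemble_allc, concat_allc, empty_allc
from dropmet.sim.genome import SyntheticGenome
from dropmet.sim.methylome import CellTypeMethylome


def sample_cell_allc(
    genome: SyntheticGenome,
    methylome: CellTypeMethylome,
    n_reads: int,
    read_span: int = 100,
    conversion_rate: float = 0.99,
    spike_fraction: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample one cell's allc table from ``n_reads`` unique reads.

    Each read covers ``read_span`` bases of one template strand (the
    informative strand for methylation calls), on a contig chosen with
    probability proportional to length; a ``spike_fraction`` of reads
    lands on the unmethylated spike-in contig instead.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be positive")
    if not 0.0 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    names = genome.nonspike_contigs()
    lengths = np.array([len(genome.contigs[n]) for n in names], dtype=float)
    n_spike = int(rng.binomial(n_reads, spike_fraction)) if genome.spike_contig else 0
    reads_per_contig = rng.multinomial(n_reads - n_spike, lengths / lengths.sum())

    parts = []
    fail = 1.0 - conversion_rate
    targets = list(zip(names, reads_per_contig))
    if n_spike:
        targets.append((genome.spike_contig, n_spike))
    for name, n in targets:
        if n == 0:
            continue
        seq = genome.contigs[name]
        L = len(seq)
        span = min(read_span, L)
        arr = to_array(seq)
        cls = methylome.classes[name]
        probs = methylome.probs[name]
        starts = rng.integers(0, L - span + 1, size=n)
        on_plus = rng.random(n) < 0.5
        for strand, base in (("+", C), ("-", G)):
            ss = starts[on_plus] if strand == "+" else starts[~on_plus]
            if ss.size == 0:
                continue
            diff = np.zeros(L + 1, dtype=np.int32)
            np.add.at(diff, ss, 1)
            np.add.at(diff, ss + span, -1)
            cov = np.cumsum(diff[:-1])
            sites = np.flatnonzero((arr == base) & (cov > 0))
            if sites.size == 0:
                continue
            p_eff = probs[sites] * conversion_rate + fail
            mc = rng.binomial(cov[sites], p_eff)
            parts.append(
                assemble_allc(name, seq, sites, strand, cls[sites], mc, cov[sites])
            )
    if not parts:
        return empty_allc()
    out = concat_allc(parts)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)
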