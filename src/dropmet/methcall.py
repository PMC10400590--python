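"""Deduplication, per-cytosine methylation calling and per-cell QC.

Duplicates are PCR re-reads of the same barcoded fragment: alignments
sharing (barcode, contig, start, end, orientation mode) collapse to one
representative (lowest edit distance, then read id).  Methylation is
called per reference cytosine on its informative strand: an OT/CTOT
alignment reports top-strand cytosines (read C = methylated, read T =
unmethylated), an OB/CTOB alignment reports bottom-strand cytosines
(read G / read A in forward coordinates).  Read bases other than the
informative pair — sequencing errors — are ignored entirely rather
than counted as coverage, which keeps rates unbiased.

The spike-in contig is excluded from genome-wide levels; its calls
measure the bisulfite conversion rate, since every retained C there is
a conversion failure.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy.special import gammaln

from dropmet.seq import to_array, C, G, T, A
from dropmet.allctable import assemble_allc, concat_allc, empty_allc, collapse_cg_strands
from dropmet.bsalign import Alignment
from dropmet.sim.genome import SyntheticGenome
from dropmet.sim.methylome import site_classes

__all__ = [
    "deduplicate",
    "call_methylation",
    "conversion_rate",
    "global_levels",
    "covered_cpgs",
    "saturation_curve",
    "duplicate_multiplicities",
    "cell_summary",
]


def _fragment_key(aln: Alignment) -> tuple:
    return (aln.barcode, aln.contig, aln.start, aln.end, aln.mode)


def deduplicate(alignments: list[Alignment]) -> list[Alignment]:
    """One representative per (barcode, contig, start, end, mode).

    The representative is the lowest-edit alignment, ties broken by
    read id, so the result is independent of input order.
    """
    best: dict[tuple, Alignment] = {}
    for aln in alignments:
        key = _fragment_key(aln)
        prev = best.get(key)
        if prev is None or (aln.nm, aln.read_id) < (prev.nm, prev.read_id):
            best[key] = aln
    return sorted(best.values(), key=lambda a: (a.contig, a.start, a.end, a.mode))


def duplicate_multiplicities(alignments: list[Alignment]) -> np.ndarray:
    """Per-fragment read multiplicities (the duplicate structure)."""
    counts = Counter(_fragment_key(a) for a in alignments)
    return np.array(sorted(counts.values()), dtype=np.int64)


def call_methylation(
    alignments: list[Alignment],
    genome: SyntheticGenome,
    classes: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Build an allc table from (deduplicated) alignments.

    Each covered informative cytosine contributes cov += 1 and, when the
    read base is the retained (unconverted) base, mc += 1.
    """
    if classes is None:
        classes = site_classes(genome)
    acc: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    def arrays(contig: str, strand: str):
        key = (contig, strand)
        if key not in acc:
            L = len(genome.contigs[contig])
            acc[key] = (np.zeros(L, dtype=np.int32), np.zeros(L, dtype=np.int32))
        return acc[key]

    seq_arrays = {n: to_array(s) for n, s in genome.contigs.items()}
    for aln in alignments:
        ref = seq_arrays.get(aln.contig)
        if ref is None or aln.start < 0 or aln.end > ref.size:
            raise ValueError(f"alignment outside contig bounds: {aln}")
        read = to_array(aln.oriented_seq)
        window = ref[aln.start : aln.end]
        if aln.mode in ("OT", "CTOT"):
            strand, ref_base, meth_base, unmeth_base = "+", C, C, T
        else:
            strand, ref_base, meth_base, unmeth_base = "-", G, G, A
        sites = np.flatnonzero(window == ref_base)
        bases = read[sites]
        informative = (bases == meth_base) | (bases == unmeth_base)
        sites = sites[informative]
        bases = bases[informative]
        mc_arr, cov_arr = arrays(aln.contig, strand)
        np.add.at(cov_arr, aln.start + sites, 1)
        np.add.at(mc_arr, aln.start + sites[bases == meth_base], 1)

    parts = []
    for (contig, strand), (mc_arr, cov_arr) in sorted(acc.items()):
        pos = np.flatnonzero(cov_arr)
        if pos.size == 0:
            continue
        parts.append(
            assemble_allc(
                contig,
                genome.contigs[contig],
                pos,
                strand,
                (classes[contig][pos] == 1).astype(np.int8),
                mc_arr[pos],
                cov_arr[pos],
            )
        )
    if not parts:
        return empty_allc()
    return concat_allc(parts).sort_values(["chrom", "pos", "strand"], ignore_index=True)


def conversion_rate(
    allc: pd.DataFrame, spike_contig: str = "spike", min_calls: int = 1000
) -> float:
    """1 - (methylated calls / total calls) over the spike-in contig.

    Returns NaN (with a warning) below ``min_calls`` spike observations.
    """
    spike = allc[allc["chrom"] == spike_contig]
    total = int(spike["cov"].sum())
    if total < min_calls:
        warnings.warn(
            f"only {total} spike calls (< {min_calls}); conversion rate withheld"
        )
        return float("nan")
    return 1.0 - float(spike["mc"].sum()) / total


def global_levels(
    allc: pd.DataFrame, cls: str = "CG", spike_contig: str | None = "spike"
) -> float:
    """Pooled mc/cov over non-spike sites of one class (mCG/CG or mCH/CH)."""
    if cls not in ("CG", "CH"):
        raise ValueError("class must be 'CG' or 'CH'")
    rows = allc[allc["class"] == cls]
    if spike_contig is not None:
        rows = rows[rows["chrom"] != spike_contig]
    cov = int(rows["cov"].sum())
    if cov == 0:
        warnings.warn(f"no {cls} coverage; global level undefined")
        return float("nan")
    return float(rows["mc"].sum()) / cov


def covered_cpgs(allc: pd.DataFrame, spike_contig: str | None = "spike") -> int:
    """Number of distinct CpG dinucleotides with any coverage."""
    rows = allc if spike_contig is None else allc[allc["chrom"] != spike_contig]
    return len(collapse_cg_strands(rows))


def saturation_curve(
    fragment_multiplicities: np.ndarray, depths: list[int]
) -> pd.DataFrame:
    """Expected unique reads at each assigned depth (subsampling w/o replacement).

    For a library of N raw reads where fragment f was read m_f times,
    the expected number of distinct fragments in a uniform subsample of
    d reads is sum_f [1 - C(N - m_f, d) / C(N, d)] — computed exactly in
    log space.  The curve is monotone, concave, and plateaus at the
    library complexity (the number of distinct fragments).
    """
    m = np.asarray(fragment_multiplicities, dtype=np.int64)
    if (m < 1).any():
        raise ValueError("multiplicities must be >= 1")
    n_total = int(m.sum())
    rows = []
    for d in depths:
        if d < 0:
            raise ValueError("depths must be non-negative")
        if d > n_total:
            warnings.warn(f"depth {d} exceeds {n_total} available reads; truncated")
            d_eff = n_total
        else:
            d_eff = d
        if d_eff == 0:
            rows.append((d, 0.0))
            continue
        # log C(N-m, d) - log C(N, d) = lgamma terms; C(N-m,d)=0 when d > N-m
        nm = n_total - m
        valid = nm >= d_eff
        log_p_absent = np.full(m.shape, -np.inf)
        log_p_absent[valid] = (
            gammaln(nm[valid] + 1)
            - gammaln(nm[valid] - d_eff + 1)
            - (gammaln(n_total + 1) - gammaln(n_total - d_eff + 1))
        )
        rows.append((d, float(np.sum(1.0 - np.exp(log_p_absent)))))
    return pd.DataFrame(rows, columns=["depth", "expected_unique"])


def cell_summary(
    barcode: str,
    n_raw_reads: int,
    n_mates_submitted: int,
    alignments: list[Alignment],
    unique_alignments: list[Alignment],
    allc: pd.DataFrame,
    genome: SyntheticGenome,
    spike_contig: str | None = "spike",
    min_spike_calls: int = 1000,
) -> dict:
    """Per-barcode QC row: depth, efficiency, levels, purity fractions."""
    species_counts: Counter = Counter()
    for aln in unique_alignments:
        tag = genome.species.get(aln.contig, "A")
        if aln.contig != spike_contig:
            species_counts[tag] += 1
    n_sp = sum(species_counts.values())
    row = {
        "barcode": barcode,
        "raw_reads": n_raw_reads,
        "mates_submitted": n_mates_submitted,
        "aligned_mates": len(alignments),
        "mapping_efficiency": (
            len(alignments) / n_mates_submitted if n_mates_submitted else float("nan")
        ),
        "unique_reads": len(unique_alignments),
        "global_mcg": global_levels(allc, "CG", spike_contig) if len(allc) else float("nan"),
        "global_mch": global_levels(allc, "CH", spike_contig) if len(allc) else float("nan"),
        "covered_cpgs": covered_cpgs(allc, spike_contig),
        "conversion_rate": (
            conversion_rate(allc, spike_contig, min_spike_calls)
            if spike_contig and len(allc)
            else float("nan")
        ),
    }
    for tag in sorted(set(genome.species.values()) - {spike_contig, "spike"}):
        row[f"frac_{tag}"] = species_counts.get(tag, 0) / n_sp if n_sp else float("nan")
    return row
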