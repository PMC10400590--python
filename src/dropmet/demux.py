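"""Barcode extraction, whitelisting, error correction and read grouping.

The bead barcode occupies bases 25-39 (1-based) of R2.  Whitelisting
follows the candidate rule used for droplet bisulfite data: take the
``ceil(multiplier * expected_cells)`` barcodes with the most raw reads
(default multiplier 2.5), then accept raw barcodes at Hamming distance
<= 1 from exactly one whitelisted barcode.  Reads are stored trimmed:
the first 15 bases of R1 and the first 40 of R2 are artificial
(ligation stubs, barcode, junction) and are clipped here so downstream
modules only ever see genomic sequence.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import pysam

BARCODE_LEN = 15
BARCODE_END = 39  # 1-based inclusive end of the barcode within R2
R1_CLIP = 15
R2_CLIP = 40

_ERROR_ALPHABET = "ACGT"  # sequencing errors can introduce C into an A/T/G barcode


class ShortReadError(ValueError):
    """R2 too short to contain the barcode span."""


def extract_barcode(r2: str) -> str:
    """Barcode = R2 bases 25-39 inclusive (1-based); 0-based [24, 39)."""
    if len(r2) < BARCODE_END:
        raise ShortReadError(f"R2 length {len(r2)} < {BARCODE_END}")
    return r2[BARCODE_END - BARCODE_LEN : BARCODE_END]


def hamming1_neighbors(barcode: str) -> list[str]:
    out = []
    for i, b in enumerate(barcode):
        for a in _ERROR_ALPHABET:
            if a != b:
                out.append(barcode[:i] + a + barcode[i + 1 :])
    return out


@dataclass
class BarcodeWhitelist:
    """Accepted barcodes, their raw read counts and the correction map."""

    counts: dict[str, int]
    correction: dict[str, str] = field(repr=False, default_factory=dict)
    truncated: bool = False

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts)

    def correct(self, raw: str) -> str | None:
        """Map a raw barcode to an accepted one, or None."""
        if raw in self.counts:
            return raw
        return self.correction.get(raw)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"barcode": list(self.counts), "raw_reads": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)


def count_barcodes(r2_path) -> tuple[Counter, int]:
    """Raw barcode counts from an R2 FASTQ; returns (counts, n_short)."""
    counts: Counter = Counter()
    short = 0
    with pysam.FastxFile(str(r2_path)) as fh:
        for rec in fh:
            try:
                counts[extract_barcode(rec.sequence)] += 1
            except ShortReadError:
                short += 1
    return counts, short


def build_whitelist(
    barcode_counts: dict[str, int] | Counter,
    expected_cells: int,
    multiplier: float = 2.5,
) -> BarcodeWhitelist:
    """Top ``ceil(multiplier * expected_cells)`` barcodes by raw reads.

    Ties at the cutoff break lexicographically so the result is
    deterministic.  The correction map sends each Hamming-1 neighbor of
    exactly one accepted barcode to that barcode; neighbors shared by
    two accepted barcodes (or equal to another accepted barcode) are
    ambiguous and map to nothing.
    """
    if not barcode_counts:
        raise ValueError("barcode_counts is empty")
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    n_keep = math.ceil(multiplier * expected_cells)
    ranked = sorted(barcode_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    truncated = len(ranked) < n_keep
    if truncated:
        warnings.warn(
            f"only {len(ranked)} distinct barcodes for {n_keep} requested; keeping all"
        )
    accepted = dict(ranked[:n_keep])

    correction: dict[str, str] = {}
    ambiguous: set[str] = set()
    for bc in accepted:
        for nb in hamming1_neighbors(bc):
            if nb in accepted:
                continue
            if nb in correction and correction[nb] != bc:
                ambiguous.add(nb)
            else:
                correction[nb] = bc
    for nb in ambiguous:
        del correction[nb]
    return BarcodeWhitelist(counts=accepted, correction=correction, truncated=truncated)


@dataclass
class BarcodeReadSet:
    """Trimmed read pairs grouped under one error-corrected barcode."""

    barcode: str
    read_ids: list[str] = field(default_factory=list)
    r1: list[str] = field(default_factory=list)
    r2: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.read_ids)


@dataclass
class DemuxResult:
    read_sets: dict[str, BarcodeReadSet]
    n_assigned: int
    n_unassigned: int
    n_short: int

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_unassigned + self.n_short

    def qc_dict(self) -> dict:
        return {
            "assigned": self.n_assigned,
            "unassigned": self.n_unassigned,
            "short": self.n_short,
            "barcodes": len(self.read_sets),
        }


def demultiplex(r1_path, r2_path, whitelist: BarcodeWhitelist) -> DemuxResult:
    """Partition read pairs by corrected barcode, clipping artificial bases.

    Raises on an R1/R2 record-count mismatch.  The partition depends
    only on each read's own barcode, so it is invariant to input order.
    """
    read_sets: dict[str, BarcodeReadSet] = {
        bc: BarcodeReadSet(bc) for bc in whitelist.counts
    }
    assigned = unassigned = short = 0
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1 in f1:
            rec2 = next(iter(f2), None)
            if rec2 is None:
                raise ValueError("R1 has more records than R2")
            if rec1.name != rec2.name:
                raise ValueError(f"read pair mismatch: {rec1.name} vs {rec2.name}")
            try:
                raw = extract_barcode(rec2.sequence)
            except ShortReadError:
                short += 1
                continue
            bc = whitelist.correct(raw)
            if bc is None:
                unassigned += 1
                continue
            rs = read_sets[bc]
            rs.read_ids.append(rec1.name)
            rs.r1.append(rec1.sequence[R1_CLIP:])
            rs.r2.append(rec2.sequence[R2_CLIP:])
            assigned += 1
        if next(iter(f2), None) is not None:
            raise ValueError("R2 has more records than R1")
    return DemuxResult(read_sets, assigned, unassigned, short)
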