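"""Miniature three-letter bisulfite aligner for toy genomes.

Bisulfite conversion destroys the C/T distinction, so reads are aligned
in a reduced alphabet: the reference is indexed twice, once fully C->T
converted (for reads from the original top strand) and once fully G->A
converted (for reads from the bottom strand, represented in forward
coordinates).  Each read is tried in four orientation modes:

    OT    read C->T  vs C->T reference, forward orientation
    CTOT  revcomp(read) C->T vs C->T reference (complement of top)
    OB    revcomp(read) G->A vs G->A reference (bottom strand)
    CTOB  read G->A  vs G->A reference (complement of bottom)

Candidate loci come from exact k-mer seeds; candidates are scored by
substitution count over the full read (no indels — fragments at this
scale are co-linear) and only a unique best hit, strictly better than
the runner-up and within ``max_edit``, is reported.  This mirrors the
conservative unique-best behaviour of standard bisulfite aligners at a
size appropriate for synthetic genomes; large-genome scalability is a
non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dropmet.seq import revcomp, to_array, bisulfite_ct, bisulfite_ga
from dropmet.sim.genome import SyntheticGenome
from dropmet.demux import BarcodeReadSet

MODES = ("OT", "CTOT", "OB", "CTOB")

ALIGNMENT_COLUMNS = [
    "read_id",
    "barcode",
    "contig",
    "start",
    "end",
    "mode",
    "nm",
    "oriented_seq",
]


@dataclass(frozen=True)
class Alignment:
    """A unique-best hit; interval is 0-based half-open on the contig.

    ``oriented_seq`` is the read's original bases re-oriented to the
    forward genome strand (reverse-complemented for CTOT/OB), which is
    what the methylation caller compares against the reference.
    """

    read_id: str
    barcode: str
    contig: str
    start: int
    end: int
    mode: str
    nm: int
    oriented_seq: str


class ConvertedIndex:
    """Seed tables over the C->T and G->A converted reference."""

    def __init__(self, genome: SyntheticGenome, k: int = 24):
        if k < 12:
            raise ValueError("seed length k must be >= 12")
        self.k = k
        self.genome = genome
        self.contig_names: list[str] = []
        self.ct_arrays: list[np.ndarray] = []
        self.ga_arrays: list[np.ndarray] = []
        self._ct_seeds: dict[bytes, list[tuple[int, int]]] = {}
        self._ga_seeds: dict[bytes, list[tuple[int, int]]] = {}
        for name, seq in genome.contigs.items():
            if len(seq) < k:
                continue  # too short to seed; skipped
            ci = len(self.contig_names)
            self.contig_names.append(name)
            ct = bisulfite_ct(seq)
            ga = bisulfite_ga(seq)
            self.ct_arrays.append(to_array(ct))
            self.ga_arrays.append(to_array(ga))
            for table, conv in ((self._ct_seeds, ct), (self._ga_seeds, ga)):
                b = conv.encode("ascii")
                for i in range(len(b) - k + 1):
                    table.setdefault(b[i : i + k], []).append((ci, i))

    def lookup(self, space: str, kmer: bytes) -> list[tuple[int, int]]:
        table = self._ct_seeds if space == "CT" else self._ga_seeds
        return table.get(kmer, [])


def align_read(
    read: str,
    index: ConvertedIndex,
    max_edit: int = 3,
    read_id: str = "",
    barcode: str = "",
    mode_set: tuple[str, ...] = MODES,
) -> Alignment | None:
    """Align one read; returns None when unmapped or ambiguous."""
    k = index.k
    if len(read) < k:
        return None
    rc = revcomp(read)
    queries = [
        ("OT", bisulfite_ct(read), "CT", read),
        ("CTOB", bisulfite_ga(read), "GA", read),
        ("CTOT", bisulfite_ct(rc), "CT", rc),
        ("OB", bisulfite_ga(rc), "GA", rc),
    ]
    qlen = len(read)
    offsets = (0, (qlen - k) // 2) if qlen > k else (0,)

    best: tuple[int, Alignment] | None = None
    second = np.inf
    seen: set[tuple[int, int, int]] = set()
    for qi, (mode, query, space, oriented) in enumerate(queries):
        if mode not in mode_set:
            continue
        qb = query.encode("ascii")
        qarr = to_array(query)
        ref_arrays = index.ct_arrays if space == "CT" else index.ga_arrays
        for off in offsets:
            for ci, pos in index.lookup(space, qb[off : off + k]):
                start = pos - off
                key = (qi, ci, start)
                if key in seen:
                    continue
                seen.add(key)
                ref = ref_arrays[ci]
                if start < 0 or start + qlen > ref.size:
                    continue
                nm = int(np.count_nonzero(ref[start : start + qlen] != qarr))
                if best is None or nm < best[0]:
                    if best is not None:
                        second = min(second, best[0])
                    best = (
                        nm,
                        Alignment(
                            read_id=read_id,
                            barcode=barcode,
                            contig=index.contig_names[ci],
                            start=start,
                            end=start + qlen,
                            mode=mode,
                            nm=nm,
                            oriented_seq=oriented,
                        ),
                    )
                else:
                    second = min(second, nm)
    if best is None or best[0] > max_edit or not best[0] < second:
        return None
    return best[1]


def align_read_set(
    read_set: BarcodeReadSet, index: ConvertedIndex, max_edit: int = 3
) -> list[Alignment]:
    """Align every R1 and R2 of a barcode separately (no mate rescue)."""
    out: list[Alignment] = []
    for rid, r1, r2 in zip(read_set.read_ids, read_set.r1, read_set.r2):
        for mate, seq in (("1", r1), ("2", r2)):
            aln = align_read(
                seq,
                index,
                max_edit=max_edit,
                read_id=f"{rid}/{mate}",
                barcode=read_set.barcode,
            )
            if aln is not None:
                out.append(aln)
    return out


def mapping_efficiency(read_set: BarcodeReadSet, alignments: list[Alignment]) -> float:
    """Uniquely aligned mates / mates submitted (R1 and R2 counted apart)."""
    submitted = len(read_set.r1) + len(read_set.r2)
    if submitted == 0:
        raise ValueError(f"barcode {read_set.barcode} has no reads")
    return len(alignments) / submitted


def alignments_to_frame(alignments: list[Alignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(a, c) for c in ALIGNMENT_COLUMNS] for a in alignments],
        columns=ALIGNMENT_COLUMNS,
    )


def frame_to_alignments(df: pd.DataFrame) -> list[Alignment]:
    return [Alignment(**row) for row in df[ALIGNMENT_COLUMNS].to_dict("records")]
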