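"""Paired-FASTQ bisulfite read simulation with the droplet read layout.

Read architecture (all artificial bases regenerated per read):

* R2 = 24-base ligation/adapter stub + 15-nt A/T/G bead barcode
  (bases 25-39, 1-based) + 1 junction base + genomic sequence.  Clipping
  the first 40 bases leaves pure genomic sequence.
* R1 = 15-base random-priming stub + genomic sequence; clipping 15
  bases leaves genomic sequence.

Each fragment is sequenced from one bisulfite-converted template strand
(top or bottom, equiprobable).  R2 reads the template directly, R1 reads
its complement — so R1 carries the opposite conversion pattern and the
aligner must handle all four orientations.  Unmethylated cytosines on
the template convert to T with probability ``conversion_rate``;
methylated cytosines are protected.  PCR duplicates re-emit the same
converted template under the same barcode (conversion precedes
amplification), with independent sequencing errors.  Noise barcodes
receive adapter-dimer-like or base-shuffled genomic reads that should
fail alignment.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dropmet.seq import revcomp, to_array, from_array, C, G
from dropmet.sim.genome import SyntheticGenome
from dropmet.sim.methylome import CellTypeMethylome
from dropmet.sim.experiment import ExperimentTruth

_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadLayout:
    """Coordinates of the artificial read segments."""

    r2_prefix_len: int = 24
    barcode_len: int = 15
    r2_junction_len: int = 1
    r1_artificial_len: int = 15
    read_length: int = 150

    def __post_init__(self) -> None:
        if self.barcode_len != 15:
            raise ValueError("bead barcodes are 15-nt by design")
        if self.read_length <= self.r2_clip:
            raise ValueError("read_length must exceed the R2 artificial span")

    @property
    def r2_clip(self) -> int:
        return self.r2_prefix_len + self.barcode_len + self.r2_junction_len

    @property
    def r1_clip(self) -> int:
        return self.r1_artificial_len

    @property
    def barcode_span(self) -> tuple[int, int]:
        """0-based half-open span of the barcode within R2."""
        return (self.r2_prefix_len, self.r2_prefix_len + self.barcode_len)


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt", compresslevel=2)
    return open(path, "w")


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASE_CODES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _apply_seq_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = to_array(seq).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # shift by 1-3 in base space guarantees a different base
        codes = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)
        idx = np.searchsorted(codes, arr[hits])
        arr[hits] = codes[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return from_array(arr)


def _convert_fragment(
    frag: str,
    probs: np.ndarray,
    strand: str,
    conversion_rate: float,
    rng: np.random.Generator,
) -> str:
    """Bisulfite-convert one template strand, returned in forward coords.

    ``probs`` are per-position methylation probabilities over the
    fragment (forward coordinates).  For the top template, unmethylated
    Cs become T; for the bottom template, the bottom-strand Cs sit at
    forward G positions and read as A in forward representation.
    """
    arr = to_array(frag).copy()
    base, repl = (C, ord("T")) if strand == "+" else (G, ord("A"))
    mask = arr == base
    n = int(mask.sum())
    if n:
        meth = rng.random(n) < probs[mask]
        converted = (~meth) & (rng.random(n) < conversion_rate)
        idx = np.flatnonzero(mask)[converted]
        arr[idx] = repl
    return from_array(arr)


def _sample_fragment_length(
    rng: np.random.Generator, mean: float, sd: float, min_frag: int, max_len: int
) -> int:
    for _ in range(100):
        ln = int(round(rng.normal(mean, sd)))
        if min_frag <= ln <= max_len:
            return ln
    return min(max(min_frag, int(mean)), max_len)


def simulate_reads(
    truth: ExperimentTruth,
    genome: SyntheticGenome,
    methylomes: dict[str, CellTypeMethylome],
    out_r1,
    out_r2,
    layout: ReadLayout = ReadLayout(),
    frag_mean: float = 300.0,
    frag_sd: float = 80.0,
    min_frag: int = 150,
    conversion_rate: float = 0.99,
    seq_error: float = 0.001,
    duplication_rate: float = 0.1,
    reads_per_cell: int = 2_000,
    depth_cv_sigma: float = 0.35,
    spike_fraction: float = 0.05,
    contamination_rate: float = 0.01,
    noise_reads_mean: float | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Emit paired FASTQ for a realised experiment; return the truth sidecar.

    The sidecar has one row per read pair: read id, barcode, cell id,
    origin ("cell", "spike", "contam", "noise"), contig, fragment start
    and end (0-based half-open), template strand, duplicate flag.
    """
    if truth.barcodes.empty:
        raise ValueError("experiment truth contains no barcodes")
    for name, frac in (
        ("conversion_rate", conversion_rate),
        ("seq_error", seq_error),
        ("duplication_rate", duplication_rate),
        ("spike_fraction", spike_fraction),
        ("contamination_rate", contamination_rate),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if min_frag < 1:
        raise ValueError("min_frag must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_reads_mean is None:
        noise_reads_mean = max(10.0, 0.03 * reads_per_cell)

    spike = genome.spike_contig
    contig_names = list(genome.contigs)
    contig_lengths = {n: len(s) for n, s in genome.contigs.items()}
    by_species: dict[str, list[str]] = {}
    for n in genome.nonspike_contigs():
        by_species.setdefault(genome.species.get(n, "A"), []).append(n)
    all_species = sorted(by_species)

    _cumw: dict[tuple, np.ndarray] = {}

    def pick_contig(names: list[str]) -> str:
        key = tuple(names)
        cw = _cumw.get(key)
        if cw is None:
            w = np.array([contig_lengths[n] for n in names], dtype=float)
            cw = _cumw[key] = np.cumsum(w / w.sum())
        return names[int(np.searchsorted(cw, rng.random()))]

    glen1 = layout.read_length - layout.r1_clip
    glen2 = layout.read_length - layout.r2_clip

    sidecar_rows = []
    serial = 0

    with _open_out(out_r1) as f1, _open_out(out_r2) as f2:

        def emit(barcode: str, genomic_template: str, meta: dict) -> None:
            nonlocal serial
            rid = f"sim:{serial:08d}"
            serial += 1
            r1_gen = revcomp(genomic_template)[:glen1]
            r2_gen = genomic_template[:glen2]
            r1 = _random_bases(rng, layout.r1_artificial_len) + r1_gen
            r2 = (
                _random_bases(rng, layout.r2_prefix_len)
                + barcode
                + _random_bases(rng, layout.r2_junction_len)
                + r2_gen
            )
            r1 = _apply_seq_error(r1, seq_error, rng)
            r2 = _apply_seq_error(r2, seq_error, rng)
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
            sidecar_rows.append({"read_id": rid, "barcode": barcode, **meta})

        captured = truth.cells[truth.cells["barcode"] != ""]
        for _, cell in captured.iterrows():
            barcode = cell["barcode"]
            cell_id = cell["cell_id"]
            meth = methylomes[cell["cell_type"]]
            own = by_species.get(cell["species"], genome.nonspike_contigs())
            others = [
                c
                for sp in all_species
                if sp != cell["species"]
                for c in by_species[sp]
            ]
            n_reads = max(
                1,
                int(
                    round(
                        reads_per_cell
                        * rng.lognormal(-0.5 * depth_cv_sigma**2, depth_cv_sigma)
                    )
                ),
            )
            fragments: list[tuple[str, int, int, str, str, str]] = []
            for j in range(n_reads):
                if j > 0 and rng.random() < duplication_rate:
                    contig, s, e, strand, template, origin = fragments[
                        rng.integers(0, len(fragments))
                    ]
                    emit(
                        barcode,
                        template,
                        dict(
                            cell_id=cell_id,
                            origin=origin,
                            contig=contig,
                            start=s,
                            end=e,
                            template_strand=strand,
                            duplicate=True,
                        ),
                    )
                    continue
                u = rng.random()
                if u < spike_fraction:
                    contig, origin = spike, "spike"
                elif others and u < spike_fraction + contamination_rate:
                    contig, origin = pick_contig(others), "contam"
                else:
                    contig, origin = pick_contig(own), "cell"
                L = contig_lengths[contig]
                ln = _sample_fragment_length(rng, frag_mean, frag_sd, min_frag, L)
                s = int(rng.integers(0, L - ln + 1))
                e = s + ln
                strand = "+" if rng.random() < 0.5 else "-"
                frag = genome.contigs[contig][s:e]
                conv_fwd = _convert_fragment(
                    frag, meth.probs[contig][s:e], strand, conversion_rate, rng
                )
                # template 5'->3': top strand reads forward, bottom reads the
                # reverse complement of the forward representation
                template = conv_fwd if strand == "+" else revcomp(conv_fwd)
                fragments.append((contig, s, e, strand, template, origin))
                emit(
                    barcode,
                    template,
                    dict(
                        cell_id=cell_id,
                        origin=origin,
                        contig=contig,
                        start=s,
                        end=e,
                        template_strand=strand,
                        duplicate=False,
                    ),
                )

        for _, row in truth.noise_barcodes.iterrows():
            n_reads = int(rng.poisson(noise_reads_mean))
            for _ in range(n_reads):
                if rng.random() < 0.5:
                    tmpl = (_ADAPTER * 10)[: glen2 + 40]
                else:
                    contig = pick_contig(contig_names)
                    L = contig_lengths[contig]
                    ln = _sample_fragment_length(rng, frag_mean, frag_sd, min_frag, L)
                    s = int(rng.integers(0, L - ln + 1))
                    arr = to_array(genome.contigs[contig][s : s + ln]).copy()
                    rng.shuffle(arr)
                    tmpl = from_array(arr)
                emit(
                    row["barcode"],
                    tmpl,
                    dict(
                        cell_id="",
                        origin="noise",
                        contig="",
                        start=-1,
                        end=-1,
                        template_strand="",
                        duplicate=False,
                    ),
                )

    return pd.DataFrame(sidecar_rows)
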