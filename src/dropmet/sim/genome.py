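"""Toy reference genomes with an unmethylated spike-in contig."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPIKE_TAG = "spike"


@dataclass
class SyntheticGenome:
    """Named contigs with species tags and one spike-in control contig.

    The spike contig mimics the unmethylated phage DNA used to measure
    bisulfite conversion efficiency: the methylome generator assigns it
    methylation probability zero everywhere.
    """

    contigs: dict[str, str]
    species: dict[str, str] = field(default_factory=dict)
    spike_contig: str | None = None

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")
        if self.spike_contig is not None and self.spike_contig not in self.contigs:
            raise ValueError(f"spike contig {self.spike_contig!r} not in genome")

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def nonspike_contigs(self) -> list[str]:
        return [n for n in self.contigs if n != self.spike_contig]

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description=self.species.get(name, ""))
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, spike_contig: str | None = None) -> "SyntheticGenome":
        contigs: dict[str, str] = {}
        species: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
            if rec.description and rec.description != rec.id:
                species[rec.id] = rec.description.split()[-1]
        if spike_contig is None and SPIKE_TAG in contigs:
            spike_contig = SPIKE_TAG
        return cls(contigs=contigs, species=species, spike_contig=spike_contig)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def make_genome(
    n_contigs: int = 4,
    contig_length: int = 150_000,
    gc_fraction: float = 0.42,
    n_species: int = 1,
    seed: int | np.random.Generator = 0,
    spike_length: int = 48_000,
) -> SyntheticGenome:
    """Generate a random genome plus one spike-in contig.

    Contigs are i.i.d. base draws at the requested GC content, so CpG
    density is close to ``(gc/2)**2`` per base.  With ``n_species=2``
    contigs alternate between species tags ``"A"`` and ``"B"`` (disjoint
    contig sets, emulating a two-species mixing reference).  The spike
    contig (default 48 kb, phage-sized) belongs to neither species.

    Reproducible: a fixed integer seed yields a byte-identical genome.
    """
    if contig_length < 10_000:
        raise ValueError("contig_length must be at least 10 kb")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    if n_contigs < 1 or (n_species == 2 and n_contigs < 2):
        raise ValueError("need at least one contig per species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    contigs: dict[str, str] = {}
    species: dict[str, str] = {}
    for i in range(n_contigs):
        tag = "A" if n_species == 1 else ("A", "B")[i % 2]
        name = f"chr{tag}{i // n_species + 1}" if n_species == 2 else f"chr{i + 1}"
        contigs[name] = _random_seq(rng, contig_length, gc_fraction)
        species[name] = tag
    contigs[SPIKE_TAG] = _random_seq(rng, spike_length, gc_fraction)
    species[SPIKE_TAG] = SPIKE_TAG
    return SyntheticGenome(contigs=contigs, species=species, spike_contig=SPIKE_TAG)
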