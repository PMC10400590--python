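"""Per-cell-type methylomes with planted hypomethylated regions.

A methylome assigns every cytosine in the genome (on both strands) a
methylation probability.  CpG sites are modelled as bimodal, the way
mammalian methylomes are: a CpG pair is either "methylated" (probability
``p_high``) or "unmethylated" (``p_low``), both strands of the pair
sharing the state.  The fraction of methylated pairs is chosen so the
genome-wide mean probability hits the requested global mCG/CG target.
Non-CpG (CH) cytosines get a flat low probability equal to the global
mCH/CH target.  Type-specific differentially methylated regions (DMRs)
are planted by lowering CpG probabilities inside disjoint intervals for
the owning type only — mirroring the convention that a type-specific
CG-DMR is hypomethylated in that type relative to all others.

The spike-in contig is fully unmethylated in every type, so reads from
it measure bisulfite conversion efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dropmet.seq import to_array, C, G
from dropmet.sim.genome import SyntheticGenome

P_HIGH = 0.97
P_LOW = 0.02

SITE_NONE, SITE_CG, SITE_CH = 0, 1, 2


def site_classes(genome: SyntheticGenome) -> dict[str, np.ndarray]:
    """Per-contig int8 array: 0 = not a cytosine, 1 = CpG, 2 = CH.

    Position ``i`` is a plus-strand cytosine when the base is C and a
    minus-strand cytosine when the base is G.  A plus-strand C is CpG
    context when followed by G; a minus-strand C when preceded by C.
    """
    out: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        arr = to_array(seq)
        is_c = arr == C
        is_g = arr == G
        cg_plus = is_c.copy()
        cg_plus[:-1] &= is_g[1:]
        cg_plus[-1] = False
        cg_minus = is_g.copy()
        cg_minus[1:] &= is_c[:-1]
        cg_minus[0] = False
        cls = np.zeros(arr.shape, dtype=np.int8)
        cls[(is_c | is_g)] = SITE_CH
        cls[cg_plus | cg_minus] = SITE_CG
        out[name] = cls
    return out


@dataclass
class CellTypeMethylome:
    """Methylation probabilities for one cell type.

    ``probs[contig][i]`` is the methylation probability of the cytosine
    at position ``i`` on its own strand; entries at non-cytosine
    positions are zero and never read.
    """

    type_name: str
    probs: dict[str, np.ndarray]
    classes: dict[str, np.ndarray]
    target_global_mcg: float
    target_global_mch: float
    planted_dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "name"])
    )
    spike_contig: str | None = None

    def global_mean_probability(self, site_class: int = SITE_CG) -> float:
        """Mean assigned probability over non-spike sites of a class."""
        num = 0.0
        den = 0
        for name, cls in self.classes.items():
            if name == self.spike_contig:
                continue
            mask = cls == site_class
            num += float(self.probs[name][mask].sum())
            den += int(mask.sum())
        return num / den

    def validate(self, tol: float = 0.01) -> None:
        for name in self.probs:
            p = self.probs[name]
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"probabilities outside [0,1] on {name}")
        if self.spike_contig is not None:
            if self.probs[self.spike_contig].any():
                raise ValueError("spike contig must be fully unmethylated")
        realized = self.global_mean_probability(SITE_CG)
        if abs(realized - self.target_global_mcg) > tol:
            raise ValueError(
                f"realized global mCG {realized:.4f} deviates from target "
                f"{self.target_global_mcg:.4f} by more than {tol}"
            )


def _plant_dmr_intervals(
    genome: SyntheticGenome,
    n_total: int,
    dmr_length: int,
    rng: np.random.Generator,
    margin: int = 2,
) -> list[tuple[str, int, int]]:
    """Disjoint candidate intervals on non-spike contigs, round-robin slots."""
    slots: list[tuple[str, int, int]] = []
    stride = dmr_length * (margin + 1)
    for name in genome.nonspike_contigs():
        length = len(genome.contigs[name])
        for start in range(stride // 2, length - dmr_length, stride):
            slots.append((name, start, start + dmr_length))
    if len(slots) < n_total:
        raise ValueError(
            f"genome holds only {len(slots)} candidate DMR slots, need {n_total}"
        )
    idx = rng.choice(len(slots), size=n_total, replace=False)
    return [slots[i] for i in sorted(idx)]


def make_methylomes(
    genome: SyntheticGenome,
    type_specs: list[tuple[str, float, float]] | None = None,
    n_dmrs: int = 8,
    dmr_length: int = 2_000,
    dmr_depth: float = 0.4,
    domain_length: int = 50_000,
    shared_domain_sd: float = 0.03,
    type_domain_sd: float = 0.04,
    seed: int | np.random.Generator = 0,
) -> tuple[list[CellTypeMethylome], pd.DataFrame]:
    """Build one methylome per cell type plus the planted-DMR table.

    Parameters
    ----------
    type_specs : list of (name, target_mCG, target_mCH)
        Defaults to three cell-line-like types at global mCG 50.5%,
        68.2% and 63.0% with ~1% mCH.
    n_dmrs : int
        Type-specific hypomethylated regions planted per type.
    dmr_depth : float
        Amount subtracted from CpG probabilities inside a type's own
        DMRs (floored at zero).
    domain_length, shared_domain_sd, type_domain_sd : regional structure
        Methylomes are not i.i.d. over CpGs: the methylated fraction
        wanders regionally.  Each ``domain_length`` window gets a random
        offset on the methylated-fraction scale — one component shared
        by all types (conserved domain structure) and one drawn per
        type (regional cell-type identity, the signal that survives
        global-level normalization).  Set ``type_domain_sd=0`` to build
        types that differ only by their global level (plus DMRs).

    CpG-pair states are drawn with one shared uniform per pair across
    types ("nested" draws), so types with close targets share most of
    their methylome, as real related cell types do.

    Returns the methylomes and a BED-like frame (chrom, start, end,
    name) where ``name`` is the owning type.
    """
    if type_specs is None:
        type_specs = [
            ("typeA", 0.505, 0.010),
            ("typeB", 0.682, 0.011),
            ("typeC", 0.630, 0.009),
        ]
    for name, mcg, mch in type_specs:
        if not (P_LOW <= mcg <= P_HIGH and 0.0 <= mch <= 0.5):
            raise ValueError(f"targets for {name} out of supported range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = site_classes(genome)
    spike = genome.spike_contig

    # CpG pairs: plus-strand C positions in CG context, shared state with i+1
    pair_positions: list[tuple[str, np.ndarray]] = []
    n_pairs = 0
    for name in genome.nonspike_contigs():
        arr = to_array(genome.contigs[name])
        cg_plus = (arr == C)
        cg_plus[:-1] &= arr[1:] == G
        cg_plus[-1] = False
        pos = np.flatnonzero(cg_plus)
        pair_positions.append((name, pos))
        n_pairs += len(pos)

    dmr_rows: list[tuple[str, int, int, str]] = []
    intervals = _plant_dmr_intervals(genome, n_dmrs * len(type_specs), dmr_length, rng)
    owners = rng.permutation(np.repeat(np.arange(len(type_specs)), n_dmrs))

    # shared randomness across types: per-pair uniforms and domain field
    u_pair = rng.random(n_pairs)
    pair_domain: list[np.ndarray] = []
    shared_field: list[np.ndarray] = []
    for name, pos in pair_positions:
        n_dom = len(genome.contigs[name]) // domain_length + 1
        shared_field.append(rng.normal(0.0, shared_domain_sd, size=n_dom))
        pair_domain.append(pos // domain_length)

    # type-specific randomness is keyed on the type's targets, so two
    # types specified identically realise identical methylomes
    base_seed = int(rng.integers(2**31))

    methylomes: list[CellTypeMethylome] = []
    for t, (tname, mcg, mch) in enumerate(type_specs):
        w = (mcg - P_LOW) / (P_HIGH - P_LOW)
        trng = np.random.default_rng(
            [base_seed, int(round(mcg * 1e9)), int(round(mch * 1e9))]
        )
        w_site = np.empty(n_pairs)
        off = 0
        for ci, (name, pos) in enumerate(pair_positions):
            n_dom = len(shared_field[ci])
            type_field = trng.normal(0.0, type_domain_sd, size=n_dom)
            dom = pair_domain[ci]
            w_site[off : off + len(pos)] = np.clip(
                w + shared_field[ci][dom] + type_field[dom], 0.0, 1.0
            )
            off += len(pos)
        # clipping biases the mean off the target; rescale back
        for _ in range(3):
            m_ws = w_site.mean()
            if m_ws <= 0 or abs(m_ws - w) < 1e-6:
                break
            w_site = np.clip(w_site * (w / m_ws), 0.0, 1.0)
        meth_mask = u_pair < w_site

        probs: dict[str, np.ndarray] = {}
        offset = 0
        for name, seq in genome.contigs.items():
            cls = classes[name]
            p = np.zeros(len(seq), dtype=np.float32)
            if name == spike:
                probs[name] = p
                continue
            p[cls == SITE_CH] = mch
            probs[name] = p
        for name, pos in pair_positions:
            states = meth_mask[offset : offset + len(pos)]
            offset += len(pos)
            vals = np.where(states, P_HIGH, P_LOW).astype(np.float32)
            probs[name][pos] = vals
            probs[name][pos + 1] = vals

        own = [iv for iv, o in zip(intervals, owners) if o == t]
        for chrom, start, end in own:
            cg = classes[chrom][start:end] == SITE_CG
            seg = probs[chrom][start:end]
            seg[cg] = np.maximum(seg[cg] - dmr_depth, 0.0)
            probs[chrom][start:end] = seg
            dmr_rows.append((chrom, start, end, tname))

        # domain noise and DMR planting perturb the global mean; nudge it
        # back onto the target by flipping CpG pairs outside any DMR
        n_cg_sites = sum(
            int((classes[n] == SITE_CG).sum()) for n in genome.nonspike_contigs()
        )
        deficit = mcg * n_cg_sites - sum(
            float(probs[n][classes[n] == SITE_CG].sum())
            for n in genome.nonspike_contigs()
        )
        n_flip = int(round(abs(deficit) / (2 * (P_HIGH - P_LOW))))
        if n_flip:
            in_dmr = np.zeros(n_pairs, dtype=bool)
            off = 0
            for name, pos in pair_positions:
                for chrom, start, end in intervals:
                    if chrom == name:
                        in_dmr[off : off + len(pos)] |= (pos >= start) & (pos < end)
                off += len(pos)
            flip_up = deficit > 0
            pool = ~meth_mask & ~in_dmr if flip_up else meth_mask & ~in_dmr
            candidates = np.flatnonzero(pool)
            flips = trng.choice(
                candidates, size=min(n_flip, candidates.size), replace=False
            )
            new_p = P_HIGH if flip_up else P_LOW
            off = 0
            for name, pos in pair_positions:
                sel = flips[(flips >= off) & (flips < off + len(pos))] - off
                probs[name][pos[sel]] = new_p
                probs[name][pos[sel] + 1] = new_p
                off += len(pos)

        m = CellTypeMethylome(
            type_name=tname,
            probs=probs,
            classes=classes,
            target_global_mcg=mcg,
            target_global_mch=mch,
            spike_contig=spike,
        )
        methylomes.append(m)

    dmr_table = (
        pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    for m in methylomes:
        m.planted_dmrs = dmr_table[dmr_table["name"] == m.type_name].reset_index(
            drop=True
        )
        m.validate(tol=0.01)
    return methylomes, dmr_table
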