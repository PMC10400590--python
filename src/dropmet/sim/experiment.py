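"""Realise a droplet experiment: cells into droplets, beads onto barcodes.

The generative model mirrors the physical workflow:

1. ``N`` input cells are thrown independently and uniformly into
   ``round(N / lambda)`` cell-suspension droplets, so droplet occupancy
   is Poisson(``lambda``) to excellent approximation.
2. Each cell droplet is paired with one barcode droplet on the fusion
   device.  The barcode droplet carries a bead (hence a unique 15-nt
   A/T/G barcode) with probability ``bead_occupancy`` and the fusion
   succeeds with probability ``fusion_efficiency``.
3. A bead whose fusion partner held at least one cell becomes a cell
   barcode (a doublet barcode when >= 2 cells); every other bead becomes
   a noise barcode that will only ever receive background reads.

Everything is recorded as ground truth for downstream benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dropmet.droplet_stats import DropletDesign

BARCODE_ALPHABET = "ATG"
BARCODE_LENGTH = 15


def random_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct 15-mers over {A, T, G} (bead barcodes are unique)."""
    # collision probability over 3^15 ~ 14M space is tiny; retry on clash
    out: set[str] = set()
    letters = np.array(list(BARCODE_ALPHABET))
    while len(out) < n:
        block = rng.integers(0, 3, size=(n - len(out), BARCODE_LENGTH))
        for row in block:
            out.add("".join(letters[row]))
    return sorted(out)[:n] if len(out) > n else sorted(out)


@dataclass
class ExperimentTruth:
    """Ground truth of one simulated droplet run.

    ``barcodes`` has one row per bead barcode: barcode, kind
    ("cell", "doublet" or "noise"), n_cells, cell_ids (comma-joined),
    cell_types, species.  ``cells`` has one row per input cell with its
    type, species, droplet and capturing barcode (empty if lost).
    """

    barcodes: pd.DataFrame
    cells: pd.DataFrame
    design: DropletDesign
    n_droplets: int
    params: dict = field(default_factory=dict)

    @property
    def cell_barcodes(self) -> pd.DataFrame:
        return self.barcodes[self.barcodes["kind"] != "noise"]

    @property
    def noise_barcodes(self) -> pd.DataFrame:
        return self.barcodes[self.barcodes["kind"] == "noise"]

    def to_tsv(self, path) -> None:
        self.barcodes.to_csv(path, sep="\t", index=False)


def simulate_experiment(
    design: DropletDesign,
    n_cells_by_type: dict[str, int],
    seed: int | np.random.Generator = 0,
    species_by_type: dict[str, str] | None = None,
) -> ExperimentTruth:
    """Simulate encapsulation, bead loading and fusion with ground truth."""
    if not n_cells_by_type or any(v <= 0 for v in n_cells_by_type.values()):
        raise ValueError("n_cells_by_type must map types to positive counts")
    if design.cell_lambda <= 0:
        raise ValueError("cell_lambda must be positive to place cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    types = [t for t, c in n_cells_by_type.items() for _ in range(c)]
    n_cells = len(types)
    order = rng.permutation(n_cells)
    types = [types[i] for i in order]
    species_by_type = species_by_type or {}

    n_droplets = max(1, int(round(n_cells / design.cell_lambda)))
    droplet_of_cell = rng.integers(0, n_droplets, size=n_cells)

    has_bead = rng.random(n_droplets) < design.bead_occupancy
    fused = rng.random(n_droplets) < design.fusion_efficiency
    bead_droplets = np.flatnonzero(has_bead)
    barcodes = random_barcodes(len(bead_droplets), rng)
    # shuffle so lexicographic order carries no information
    barcodes = [barcodes[i] for i in rng.permutation(len(barcodes))]

    cells_in_droplet: dict[int, list[int]] = {}
    for cell_idx, d in enumerate(droplet_of_cell):
        cells_in_droplet.setdefault(int(d), []).append(cell_idx)

    bc_rows = []
    capture: dict[int, str] = {}
    for bc, d in zip(barcodes, bead_droplets):
        members = cells_in_droplet.get(int(d), []) if fused[d] else []
        if members:
            kind = "cell" if len(members) == 1 else "doublet"
            for m in members:
                capture[m] = bc
        else:
            kind = "noise"
        bc_rows.append(
            {
                "barcode": bc,
                "kind": kind,
                "n_cells": len(members),
                "cell_ids": ",".join(f"cell{m:05d}" for m in members),
                "cell_types": ",".join(types[m] for m in members),
                "species": ",".join(
                    sorted({species_by_type.get(types[m], "A") for m in members})
                ),
            }
        )

    cell_rows = [
        {
            "cell_id": f"cell{i:05d}",
            "cell_type": types[i],
            "species": species_by_type.get(types[i], "A"),
            "droplet": int(droplet_of_cell[i]),
            "barcode": capture.get(i, ""),
        }
        for i in range(n_cells)
    ]

    return ExperimentTruth(
        barcodes=pd.DataFrame(
            bc_rows,
            columns=["barcode", "kind", "n_cells", "cell_ids", "cell_types", "species"],
        ),
        cells=pd.DataFrame(cell_rows),
        design=design,
        n_droplets=n_droplets,
        params={
            "cell_lambda": design.cell_lambda,
            "bead_occupancy": design.bead_occupancy,
            "fusion_efficiency": design.fusion_efficiency,
            "n_cells": n_cells,
        },
    )
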