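"""Closed-form design calculators for droplet encapsulation experiments.

Cell loading into droplets follows a Poisson model: if cells arrive at a
mean rate of ``lambda_`` per droplet, the number of cells in a droplet is
Poisson distributed, so dilution controls the trade-off between capture
rate (droplets with one cell) and the doublet rate (droplets with two or
more).  Droplet counts follow from volumetric arithmetic: a spherical
droplet of diameter ``d`` micrometres has volume ``(pi/6) d**3`` cubic
micrometres, so an aqueous flow rate and a run time determine how many
droplets are produced.  Bead pairing adds two thinning factors: the
fraction of barcode droplets that actually contain a bead, and the
fraction successfully fused with a cell-bearing droplet.

All lengths are micrometres, volumes picolitres, flows microlitres per
minute, times minutes.  Unit conversions are centralised in
:func:`droplet_volume_pl`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy import stats

__all__ = [
    "Occupancy",
    "DropletDesign",
    "droplet_volume_pl",
    "poisson_occupancy",
    "calibrate_lambda",
    "droplet_count",
    "generation_rate",
    "fusion_runtime",
    "expected_barcoded_cells",
]


class Occupancy(str, Enum):
    """Occupancy class for :func:`poisson_occupancy`."""

    EXACTLY = "exactly_k"
    AT_LEAST = "at_least_k"


@dataclass(frozen=True)
class DropletDesign:
    """Parameters of a droplet encapsulation / bead-fusion experiment.

    Parameters
    ----------
    droplet_diameter : float
        Droplet diameter in micrometres.
    aqueous_flow : float
        Total aqueous flow rate in microlitres per minute.
    run_time : float
        Droplet-generation run time in minutes.
    cell_lambda : float
        Mean number of cells per droplet (Poisson loading rate).
    bead_occupancy : float
        Fraction of barcode droplets that contain a bead.
    fusion_efficiency : float
        Fraction of barcode droplets fused with a cell-suspension droplet.
    barcode_droplet_rate : float
        Barcode-droplet generation/fusion rate, droplets per second.
    n_beads : int
        Number of barcode beads loaded.
    """

    droplet_diameter: float = 35.0
    aqueous_flow: float = 4.0
    run_time: float = 10.0
    cell_lambda: float = -math.log(0.9)
    bead_occupancy: float = 0.07
    fusion_efficiency: float = 0.80
    barcode_droplet_rate: float = 132.0
    n_beads: int = 20_000

    def __post_init__(self) -> None:
        if self.droplet_diameter <= 0:
            raise ValueError("droplet_diameter must be positive")
        for name in ("bead_occupancy", "fusion_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("aqueous_flow", "run_time", "cell_lambda",
                     "barcode_droplet_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_beads < 0:
            raise ValueError("n_beads must be non-negative")


def droplet_volume_pl(diameter_um: float) -> float:
    """Volume of a spherical droplet, in picolitres.

    1 um^3 = 1 fL, so V[pL] = (pi/6) d^3 / 1000 for d in micrometres.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi / 6.0 * diameter_um**3 / 1000.0


def poisson_occupancy(
    lambda_: float,
    k: Occupancy | str = Occupancy.EXACTLY,
    n: int = 1,
) -> float:
    """Probability that a droplet holds exactly (or at least) ``n`` cells.

    Parameters
    ----------
    lambda_ : float
        Mean cells per droplet.
    k : {"exactly_k", "at_least_k"}
        Whether to return P(N == n) or P(N >= n).
    n : int
        Occupancy count, >= 0.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be non-negative")
    if n < 0:
        raise ValueError("n must be non-negative")
    k = Occupancy(k)
    if k is Occupancy.EXACTLY:
        return float(stats.poisson.pmf(n, lambda_))
    # P(N >= n) = 1 - CDF(n - 1)
    if n == 0:
        return 1.0
    return float(stats.poisson.sf(n - 1, lambda_))


def calibrate_lambda(occupied_fraction: float) -> float:
    """Loading rate lambda such that P(>=1 cell) equals ``occupied_fraction``.

    Inverts the Poisson zero class: P(N >= 1) = 1 - exp(-lambda).
    """
    if not 0.0 < occupied_fraction < 1.0:
        raise ValueError("occupied_fraction must lie strictly in (0, 1)")
    return -math.log1p(-occupied_fraction)


def droplet_count(aqueous_flow: float, run_time: float, diameter: float) -> float:
    """Number of droplets produced by ``aqueous_flow`` ul/min over ``run_time`` min.

    The dispersed (aqueous) phase is divided into spheres of the given
    diameter; the oil carrier phase does not count toward droplet volume.
    """
    if aqueous_flow <= 0 or run_time <= 0 or diameter <= 0:
        raise ValueError("flow, time and diameter must all be positive")
    total_pl = aqueous_flow * run_time * 1e6  # 1 ul = 1e6 pL
    return total_pl / droplet_volume_pl(diameter)


def generation_rate(aqueous_flow: float, diameter: float) -> float:
    """Droplet generation rate in droplets per second."""
    return droplet_count(aqueous_flow, 1.0, diameter) / 60.0


def fusion_runtime(
    n_beads: float, bead_occupancy: float, barcode_droplet_rate: float
) -> float:
    """Minutes of fusion-device operation needed to process ``n_beads`` beads.

    Beads ride in barcode droplets at the given occupancy, so
    ``n_beads / bead_occupancy`` droplets must pass at
    ``barcode_droplet_rate`` droplets per second.
    """
    if n_beads <= 0 or bead_occupancy <= 0 or barcode_droplet_rate <= 0:
        raise ValueError("n_beads, bead_occupancy and rate must be positive")
    return n_beads / bead_occupancy / barcode_droplet_rate / 60.0


def expected_barcoded_cells(
    n_pairings: float,
    cell_occupied_fraction: float,
    bead_occupancy: float,
    fusion_efficiency: float,
) -> float:
    """Expected number of barcodes that end up attached to a cell.

    Each droplet pairing yields a barcoded cell only when the barcode
    droplet carries a bead, the fusion succeeds, and the partner droplet
    holds at least one cell; the factors are independent thinnings.
    """
    for name, v in (
        ("cell_occupied_fraction", cell_occupied_fraction),
        ("bead_occupancy", bead_occupancy),
        ("fusion_efficiency", fusion_efficiency),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if n_pairings < 0:
        raise ValueError("n_pairings must be non-negative")
    return n_pairings * cell_occupied_fraction * bead_occupancy * fusion_efficiency
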