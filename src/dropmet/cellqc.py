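"""Cell calling from the mapping-efficiency distribution; species purity.

Cell-associated barcodes are separated from ambient/noise barcodes by
their mapping efficiency: candidate barcodes (the ``2.5 X`` with the
most raw reads, X the expected cell number) show a multimodal
efficiency distribution, and the mode with the highest mean holds the
real cells.  A univariate normal mixture is fitted by
expectation-maximization, the component count chosen by BIC, and the
cell cutoff set one standard deviation below the top component's mean
(the "mu - sigma" rule); barcodes at or above the cutoff are cells.

In a two-species mixing experiment, per-barcode aligned-read fractions
classify each barcode as pure for one species (fraction > 0.90 by
default) or mixed — mixed calls flag droplet doublets and crosstalk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "select_candidates",
    "GaussianComponent",
    "EfficiencyMixtureFit",
    "fit_efficiency_mixture",
    "call_cells",
    "species_purity",
]

_VAR_FLOOR = 1e-6
_TOL = 1e-8
_MAX_ITER = 500


def select_candidates(
    raw_read_counts: dict[str, int] | pd.Series,
    expected_cells: int,
    multiplier: float = 2.5,
) -> list[str]:
    """Top ``ceil(multiplier * expected_cells)`` barcodes by raw reads."""
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    items = (
        list(raw_read_counts.items())
        if isinstance(raw_read_counts, dict)
        else list(raw_read_counts.to_dict().items())
    )
    n_keep = math.ceil(multiplier * expected_cells)
    if len(items) < n_keep:
        warnings.warn(
            f"only {len(items)} distinct barcodes for {n_keep} requested candidates"
        )
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [bc for bc, _ in items[:n_keep]]


@dataclass(frozen=True)
class GaussianComponent:
    weight: float
    mu: float
    sigma: float


@dataclass
class EfficiencyMixtureFit:
    """A fitted 1-D normal mixture with the top-mean component marked."""

    components: list[GaussianComponent]
    log_likelihood: float
    bic: float
    n_iter: int
    converged: bool

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def selected(self) -> GaussianComponent:
        """The component with the highest mean (the cell component)."""
        return max(self.components, key=lambda c: c.mu)

    @property
    def cutoff(self) -> float:
        """The mu - sigma cell-calling threshold."""
        sel = self.selected
        return sel.mu - sel.sigma


def _em_fit(x: np.ndarray, k: int) -> EfficiencyMixtureFit:
    n = x.size
    # quantile initialization: split the sorted sample into k blocks
    order = np.sort(x)
    blocks = np.array_split(order, k)
    mu = np.array([b.mean() for b in blocks])
    var = np.array([max(b.var(), _VAR_FLOOR) for b in blocks])
    w = np.array([b.size / n for b in blocks])

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        logp = norm.logpdf(x[:, None], mu[None, :], np.sqrt(var)[None, :]) + np.log(w)[
            None, :
        ]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        # EM guarantees monotone likelihood; a violation means a numerical bug
        assert ll >= ll_prev - 1e-7, "EM log-likelihood decreased"
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-12).any():
            raise FloatingPointError("a mixture component collapsed to zero weight")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, _VAR_FLOOR)
        if ll - ll_prev < _TOL * max(1.0, abs(ll)):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    n_params = 3 * k - 1
    bic = -2.0 * ll_prev + n_params * math.log(n)
    comps = [
        GaussianComponent(float(w[j]), float(mu[j]), float(math.sqrt(var[j])))
        for j in range(k)
    ]
    return EfficiencyMixtureFit(comps, ll_prev, bic, it, converged)


def fit_efficiency_mixture(
    efficiencies,
    k_range: tuple[int, ...] = (2, 3, 4),
    seed: int | None = None,
) -> EfficiencyMixtureFit:
    """EM fit of a normal mixture to mapping efficiencies; k chosen by BIC.

    Initialization is quantile-based and therefore deterministic; the
    ``seed`` argument is accepted for interface stability but unused.
    """
    x = np.asarray(efficiencies, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError(f"need >= 50 candidate efficiencies, got {x.size}")
    fits = []
    errors = []
    for k in k_range:
        if k < 1 or k > x.size:
            continue
        try:
            fits.append(_em_fit(x, k))
        except FloatingPointError as exc:  # collapsed component at this k
            errors.append(f"k={k}: {exc}")
    fits = [f for f in fits if f.converged] or fits
    if not fits:
        raise RuntimeError("mixture fit failed at every k: " + "; ".join(errors))
    return min(fits, key=lambda f: f.bic)


def call_cells(
    candidates: pd.DataFrame | dict[str, float], fit: EfficiencyMixtureFit
) -> set[str]:
    """Barcodes whose efficiency is at or above the mu - sigma cutoff.

    ``candidates`` maps barcode -> mapping efficiency (dict or a frame
    with 'barcode' and 'mapping_efficiency' columns).
    """
    if not fit.converged:
        warnings.warn("mixture fit did not converge; calls may be unstable")
    if isinstance(candidates, pd.DataFrame):
        eff = dict(zip(candidates["barcode"], candidates["mapping_efficiency"]))
    else:
        eff = dict(candidates)
    cutoff = fit.cutoff
    cells = {bc for bc, e in eff.items() if e >= cutoff}
    if not cells:
        warnings.warn("no candidate barcode above the cell-calling cutoff")
    return cells


def species_purity(
    species_read_counts: pd.DataFrame,
    threshold: float = 0.90,
) -> tuple[pd.DataFrame, dict]:
    """Classify barcodes as pure for one species or mixed.

    ``species_read_counts`` is indexed by barcode with one column of
    uniquely aligned read counts per species.  A barcode is pure for
    species s when its fraction to s exceeds ``threshold`` (strictly);
    otherwise it is mixed.  Barcodes with zero aligned reads are
    excluded and tallied in the summary.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if species_read_counts.shape[1] < 2:
        raise ValueError("need counts for at least two species")
    totals = species_read_counts.sum(axis=1)
    empty = totals == 0
    frac = species_read_counts[~empty].div(totals[~empty], axis=0)
    top = frac.max(axis=1)
    top_species = frac.idxmax(axis=1)
    call = np.where(top > threshold, "pure_" + top_species.astype(str), "mixed")
    calls = pd.DataFrame(
        {
            "barcode": frac.index,
            **{f"frac_{c}": frac[c].to_numpy() for c in frac.columns},
            "call": call,
        }
    ).reset_index(drop=True)
    n = len(calls)
    counts = calls["call"].value_counts().to_dict()
    summary = {
        "n_classified": n,
        "n_zero_aligned": int(empty.sum()),
        "calls": counts,
        "pure_fraction": (n - counts.get("mixed", 0)) / n if n else float("nan"),
    }
    return calls, summary
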