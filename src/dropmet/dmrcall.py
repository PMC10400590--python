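"""Pseudobulk merging and two-group CG-DMR calling with gene annotation.

Cluster pseudobulks are exact sums: for each cytosine, the methylated
and total call counts over all member cells.  DMRs between two
pseudobulks are called with a self-contained procedure: per CpG
(strand-collapsed), a two-proportion z-test on the pooled counts;
Benjamini-Hochberg FDR across CpGs; significant CpGs merged into
regions when within ``merge_dist`` of each other; regions kept when
they span at least ``min_cpgs`` significant CpGs and the pooled
methylation difference exceeds ``min_delta``.  This is a deliberately
simple stand-in for smoothing/dispersion-based DMR callers; every
threshold is a parameter and recovery of planted regions is the
benchmark, not concordance with any particular external caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from dropmet.allctable import collapse_cg_strands

__all__ = ["merge_pseudobulk", "call_dmrs", "annotate_genes", "DmrRegion"]


def merge_pseudobulk(allc_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum per-site counts over member cells; site set is the union.

    Raises when the same (chrom, pos, strand) appears with conflicting
    context annotations — that indicates corrupt input.
    """
    if not allc_tables:
        raise ValueError("need at least one member allc table")
    from dropmet.allctable import concat_allc

    cat = concat_allc(list(allc_tables))
    if cat.empty:
        return cat
    key = ["chrom", "pos", "strand"]
    ctx = cat.drop_duplicates(key + ["context", "class"])
    if ctx.duplicated(key).any():
        bad = ctx[ctx.duplicated(key, keep=False)].head()
        raise ValueError(f"conflicting context annotations at sites:\n{bad}")
    merged = cat.groupby(key, as_index=False, sort=True, observed=True).agg(
        context=("context", "first"),
        **{"class": ("class", "first")},
        mc=("mc", "sum"),
        cov=("cov", "sum"),
    )
    merged["methylated"] = (merged["mc"] > 0).astype(np.int8)
    return merged[
        ["chrom", "pos", "strand", "context", "class", "mc", "cov", "methylated"]
    ]


@dataclass(frozen=True)
class DmrRegion:
    chrom: str
    start: int  # 0-based
    end: int
    n_cpgs: int
    mean_a: float
    mean_b: float
    difference: float  # mean_a - mean_b
    q: float
    gene: str | None = None


def _two_proportion_pvals(
    mc1: np.ndarray, cov1: np.ndarray, mc2: np.ndarray, cov2: np.ndarray
) -> np.ndarray:
    p1 = mc1 / cov1
    p2 = mc2 / cov2
    pooled = (mc1 + mc2) / (cov1 + cov2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / cov1 + 1 / cov2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / se
    pvals = 2.0 * norm.sf(np.abs(z))
    pvals[se == 0] = np.nan  # rate 0 or 1 in both groups: no information
    return pvals


def call_dmrs(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    min_cov: int = 5,
    fdr: float = 0.05,
    min_delta: float = 0.1,
    merge_dist: int = 500,
    min_cpgs: int = 3,
    extend_p: float = 0.05,
    smooth_window: int = 300,
) -> list[DmrRegion]:
    """CG-DMRs between two pseudobulk allc tables.

    The per-CpG statistic is a two-proportion z-test on counts pooled
    over a ``smooth_window``-bp window centred on the CpG (0 disables
    smoothing).  Windowed counts borrow strength from neighbours the
    way smoothing-based DMR callers do; at single-CpG coverage of a few
    tens of reads the unsmoothed test has little power and clips true
    regions.  The smoothing correlates neighbouring tests, so the BH
    step controls the FDR approximately rather than exactly.

    Candidate regions are seeded by BH-significant CpGs merged within
    ``merge_dist``; each seed region is then grown outward over
    consecutive CpGs that are nominally significant (unadjusted
    p < ``extend_p``) with the same sign of difference — the usual
    two-stage trick that keeps region boundaries from being clipped by
    the multiplicity correction.  A region must hold at least
    ``min_cpgs`` BH-significant CpGs and a pooled |difference| of at
    least ``min_delta`` (differences always computed from raw, not
    smoothed, counts).  Regions are reported 0-based half-open, sorted
    by coordinate, with the pooled within-region rate of each group,
    their difference (A - B), and the minimum BH q among member CpGs.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both pseudobulk groups must be non-empty")
    a = collapse_cg_strands(group_a)
    b = collapse_cg_strands(group_b)
    m = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    m = m[(m["cov_a"] >= min_cov) & (m["cov_b"] >= min_cov)]
    if m.empty:
        warnings.warn("no CpG passed min_cov in both groups")
        return []
    m = m.sort_values(["chrom", "pos"])
    cols = ["mc_a", "cov_a", "mc_b", "cov_b"]
    if smooth_window > 0:
        smoothed = []
        for _, grp in m.groupby("chrom", sort=True, observed=True):
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, pos - smooth_window // 2, side="left")
            hi = np.searchsorted(pos, pos + smooth_window // 2, side="right")
            cum = {c: np.r_[0, np.cumsum(grp[c].to_numpy(np.float64))] for c in cols}
            smoothed.append(
                pd.DataFrame({c: cum[c][hi] - cum[c][lo] for c in cols},
                             index=grp.index)
            )
        sm = pd.concat(smoothed)
    else:
        sm = m[cols].astype(float)
    pvals = _two_proportion_pvals(
        sm["mc_a"].to_numpy(),
        sm["cov_a"].to_numpy(),
        sm["mc_b"].to_numpy(),
        sm["cov_b"].to_numpy(),
    )
    m = m.assign(
        p=pvals,
        sm_rate_diff=sm["mc_a"].to_numpy() / sm["cov_a"].to_numpy()
        - sm["mc_b"].to_numpy() / sm["cov_b"].to_numpy(),
    ).dropna(subset=["p"])
    if m.empty:
        return []
    m["q"] = multipletests(m["p"].to_numpy(), method="fdr_bh")[1]
    regions: list[DmrRegion] = []
    for chrom, grp in m.groupby("chrom", sort=True, observed=True):
        grp = grp.reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        sign = np.sign(grp["sm_rate_diff"].to_numpy())
        sig_idx = np.flatnonzero((grp["q"] <= fdr).to_numpy())
        if sig_idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos[sig_idx]) > merge_dist)
        seed_starts = np.r_[0, breaks + 1]
        seed_ends = np.r_[breaks, sig_idx.size - 1]
        for si, ei in zip(seed_starts, seed_ends):
            lo, hi = sig_idx[si], sig_idx[ei]
            if ei - si + 1 < min_cpgs:
                continue
            region_sign = np.sign(sign[lo:hi + 1].sum()) or 1.0
            # grow outward over nominally significant, same-sign CpGs
            j = lo
            while (
                j > 0
                and pos[j] - pos[j - 1] <= merge_dist
                and grp["p"].iloc[j - 1] < extend_p
                and sign[j - 1] == region_sign
            ):
                j -= 1
            k = hi
            while (
                k < len(grp) - 1
                and pos[k + 1] - pos[k] <= merge_dist
                and grp["p"].iloc[k + 1] < extend_p
                and sign[k + 1] == region_sign
            ):
                k += 1
            block = grp.iloc[j : k + 1]
            mean_a = block["mc_a"].sum() / block["cov_a"].sum()
            mean_b = block["mc_b"].sum() / block["cov_b"].sum()
            diff = mean_a - mean_b
            if abs(diff) < min_delta:
                continue
            regions.append(
                DmrRegion(
                    chrom=chrom,
                    start=int(block["pos"].iloc[0]) - 1,
                    end=int(block["pos"].iloc[-1]) + 1,  # include the CpG dinucleotide
                    n_cpgs=int(ei - si + 1),
                    mean_a=float(mean_a),
                    mean_b=float(mean_b),
                    difference=float(diff),
                    q=float(block["q"].min()),
                )
            )
    # growth can make neighbouring seed regions touch; merge overlaps
    merged: list[DmrRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if merged and merged[-1].chrom == r.chrom and r.start < merged[-1].end:
            prev = merged.pop()
            merged.append(
                DmrRegion(
                    chrom=r.chrom,
                    start=prev.start,
                    end=max(prev.end, r.end),
                    n_cpgs=prev.n_cpgs + r.n_cpgs,
                    mean_a=(prev.mean_a + r.mean_a) / 2,
                    mean_b=(prev.mean_b + r.mean_b) / 2,
                    difference=(prev.difference + r.difference) / 2,
                    q=min(prev.q, r.q),
                )
            )
        else:
            merged.append(r)
    return merged


def regions_to_frame(regions: list[DmrRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_cpgs": r.n_cpgs,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "difference": r.difference,
                "q": r.q,
                "gene": r.gene or "",
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpgs",
            "mean_a",
            "mean_b",
            "difference",
            "q",
            "gene",
        ],
    )


def annotate_genes(
    regions: list[DmrRegion],
    genes: pd.DataFrame,
    promoter_window: int = 2_000,
) -> list[DmrRegion]:
    """Assign each region at most one gene.

    ``genes`` is BED6-like: chrom, start, end, name, (score), strand;
    the TSS is ``start`` on + genes and ``end`` on - genes.  Priority:
    overlap with the promoter (TSS +/- window), then gene-body overlap,
    then nearest TSS; ties break by TSS distance then gene name.
    """
    if genes.empty:
        raise ValueError("gene annotation is empty")
    g = genes.copy()
    g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"])
    out = []
    for r in regions:
        cand = g[g["chrom"] == r.chrom]
        if cand.empty:
            out.append(r)
            continue
        mid_dist = np.minimum(
            np.abs(cand["tss"] - r.start), np.abs(cand["tss"] - r.end)
        )
        inside = (cand["tss"] >= r.start) & (cand["tss"] < r.end)
        tss_dist = np.where(inside, 0, mid_dist)
        promoter = tss_dist <= promoter_window
        body = (cand["start"] < r.end) & (cand["end"] > r.start)
        ranked = cand.assign(tss_dist=tss_dist, promoter=promoter, body=body)
        for mask in (ranked["promoter"], ranked["body"], ranked["tss_dist"] >= 0):
            sub = ranked[mask]
            if not sub.empty:
                sub = sub.sort_values(["tss_dist", "name"])
                out.append(
                    DmrRegion(**{**r.__dict__, "gene": str(sub["name"].iloc[0])})
                )
                break
    return out
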