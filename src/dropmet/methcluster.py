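"""Binned methylome feature matrix, clustering and DMR-based annotation.

Cells are summarised as methylation rates (pooled mc/cov of one
context class) over fixed-width genome-tiling bins.  Bins with too few
covered sites in a cell are missing, not zero.  Each cell's row is then
divided by that cell's global level — methylomes differ in overall
level, and without this normalization cells would cluster by global
methylation depth rather than by regional pattern; missing bins are
imputed with the neutral normalized value 1.  The normalized matrix is
reduced to its top principal components (centering only, no per-bin
scaling) and clustered with Louvain community detection on a k-nearest-
neighbour graph.  Clusters are annotated by their pooled CG methylation
over named DMR sets: within each set, per-cluster levels are z-scored
across clusters and a cluster is labelled with the set in which it is
most hypomethylated (minimum z, required below -1), matching the logic
that a type-specific DMR set is lowest in its own type.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from dropmet.methcall import global_levels
from dropmet.dmrcall import merge_pseudobulk

__all__ = [
    "MethFeatureMatrix",
    "build_matrix",
    "normalize",
    "reduce_and_cluster",
    "annotate_clusters",
    "ClusterAnnotation",
]


@dataclass
class MethFeatureMatrix:
    """Cells x bins methylation-rate matrix with an explicit missing mask."""

    values: pd.DataFrame  # index = barcode, columns = "contig:start-end"
    missing: pd.DataFrame  # same shape, True where the bin had no data
    cell_global: pd.Series  # per-cell global level of the chosen class
    bin_width: int
    cls: str
    normalized: bool = False

    @property
    def barcodes(self) -> list[str]:
        return list(self.values.index)


def _bin_label(contig: str, b: int, width: int) -> str:
    return f"{contig}:{b * width}-{(b + 1) * width}"


def build_matrix(
    allc_by_cell: dict[str, pd.DataFrame],
    bin_width: int = 100_000,
    cls: str = "CG",
    min_sites_per_bin: int = 20,
    min_cell_fraction_per_bin: float = 0.5,
    spike_contig: str | None = "spike",
) -> MethFeatureMatrix:
    """Pooled mc/cov per cell per genome bin for one context class.

    A cell's bin is missing when fewer than ``min_sites_per_bin`` sites
    are covered there; bins missing in more than
    ``1 - min_cell_fraction_per_bin`` of cells are dropped.
    """
    if len(allc_by_cell) < 2:
        raise ValueError("need at least two cells to build a feature matrix")
    rate_rows = {}
    glob = {}
    for bc, allc in allc_by_cell.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glob[bc] = global_levels(allc, cls, spike_contig)
        rows = allc[allc["class"] == cls]
        if spike_contig is not None:
            rows = rows[rows["chrom"] != spike_contig]
        if rows.empty:
            rate_rows[bc] = pd.Series(dtype=float)
            continue
        binned = rows.assign(bin=(rows["pos"] - 1) // bin_width)
        agg = binned.groupby(["chrom", "bin"], observed=True).agg(
            mc=("mc", "sum"), cov=("cov", "sum"), sites=("pos", "size")
        )
        agg = agg[agg["sites"] >= min_sites_per_bin]
        rate_rows[bc] = pd.Series(
            (agg["mc"] / agg["cov"]).to_numpy(),
            index=[_bin_label(c, b, bin_width) for c, b in agg.index],
        )
    values = pd.DataFrame(rate_rows).T  # cells x bins
    present = values.notna()
    keep = present.mean(axis=0) >= min_cell_fraction_per_bin
    values = values.loc[:, keep]
    if values.shape[1] == 0:
        raise ValueError(
            "no bin passed the coverage filters; lower min_sites_per_bin or "
            "min_cell_fraction_per_bin, or use wider bins"
        )
    values = values[sorted(values.columns)]
    return MethFeatureMatrix(
        values=values,
        missing=values.isna(),
        cell_global=pd.Series(glob).loc[values.index],
        bin_width=bin_width,
        cls=cls,
    )


def normalize(matrix: MethFeatureMatrix) -> MethFeatureMatrix:
    """Divide each cell's bins by its global level; impute missing with 1.

    Cells with zero (or undefined) global level are dropped with a
    warning.  The operation is scale-invariant per cell: multiplying a
    cell's bins and its global level by one factor leaves its row
    unchanged.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    ok = (matrix.cell_global > 0) & matrix.cell_global.notna()
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} cells with zero global level")
    vals = matrix.values.loc[ok].div(matrix.cell_global.loc[ok], axis=0)
    vals = vals.fillna(1.0)
    return MethFeatureMatrix(
        values=vals,
        missing=matrix.missing.loc[ok],
        cell_global=matrix.cell_global.loc[ok],
        bin_width=matrix.bin_width,
        cls=matrix.cls,
        normalized=True,
    )


@dataclass
class ClusterAnnotation:
    """Cluster memberships with optional DMR-based labels."""

    labels: pd.Series  # index = barcode, value = cluster id (int)
    umap: pd.DataFrame | None = None
    dmr_levels: pd.DataFrame | None = None  # clusters x DMR sets
    zscores: pd.DataFrame | None = None
    cluster_labels: dict[int, str | None] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()


def reduce_and_cluster(
    matrix: MethFeatureMatrix,
    n_pcs: int = 50,
    knn_k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    compute_umap: bool = False,
) -> ClusterAnnotation:
    """Top-PCs + kNN-graph Louvain clustering of the normalized matrix."""
    if not matrix.normalized:
        raise ValueError("cluster on the normalized matrix (call normalize first)")
    x = matrix.values.to_numpy(dtype=float)
    n_cells, n_bins = x.shape
    if np.allclose(x, x[0]):
        raise ValueError("degenerate feature matrix: all cells identical")
    max_pcs = min(n_cells - 1, n_bins)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs lowered from {n_pcs} to {max_pcs}")
        n_pcs = max_pcs
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)

    k = min(knn_k, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = ig.Graph(n=n_cells, edges=sorted(edges))
    ig.set_random_number_generator(random.Random(seed))
    try:
        membership = graph.community_multilevel(resolution=resolution).membership
    finally:
        ig.set_random_number_generator(random)
    labels = pd.Series(membership, index=matrix.values.index, name="cluster")

    umap_df = None
    if compute_umap:
        import umap  # heavy import, presentation-only

        emb = umap.UMAP(random_state=seed).fit_transform(pcs)
        umap_df = pd.DataFrame(emb, index=labels.index, columns=["umap1", "umap2"])
    return ClusterAnnotation(labels=labels, umap=umap_df)


def _interval_subset(allc: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """CG rows falling inside disjoint BED-style intervals (vectorised)."""
    cg = allc[allc["class"] == "CG"]
    keep = []
    for chrom, grp in cg.groupby("chrom", sort=False, observed=True):
        ivs = intervals[intervals["chrom"] == chrom].sort_values("start")
        if ivs.empty:
            continue
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        pos0 = grp["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        keep.append(grp[hit])
    if not keep:
        return cg.iloc[:0]
    return pd.concat(keep)


def _pooled_level_in_intervals(allc: pd.DataFrame, intervals: pd.DataFrame) -> float:
    """Pooled CG mc/cov over BED-style (chrom, start, end) intervals."""
    sub = _interval_subset(allc, intervals)
    cov = int(sub["cov"].sum())
    return int(sub["mc"].sum()) / cov if cov else float("nan")


def annotate_clusters(
    annotation: ClusterAnnotation,
    allc_by_cell: dict[str, pd.DataFrame],
    dmr_sets: pd.DataFrame,
    z_threshold: float = -1.0,
    normalize_by_global: bool = True,
    spike_contig: str | None = "spike",
) -> ClusterAnnotation:
    """Label clusters by hypomethylation over named DMR sets.

    ``dmr_sets`` is BED-like with columns (chrom, start, end, name),
    ``name`` giving set membership.  Per cluster and set, member-cell
    allc tables are merged into a pseudobulk and the pooled CG level
    computed; levels are z-scored across clusters within each set
    (sample sd), and each cluster is labelled with its minimum-z set
    provided that z is below ``z_threshold`` (no-call otherwise).
    Labels attach to membership sets, so they are invariant to cluster
    id permutation.

    With ``normalize_by_global`` (default) each cluster's level is
    divided by that cluster's global CG level first, so a cluster that
    is globally hypomethylated does not read as "low" in every set:
    the z-scores then measure set-specific hypomethylation.
    """
    if dmr_sets.empty:
        raise ValueError("dmr_sets is empty")
    clusters = sorted(annotation.labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for z-scoring")
    set_names = sorted(dmr_sets["name"].unique())
    levels = pd.DataFrame(index=clusters, columns=set_names, dtype=float)
    cluster_global = pd.Series(index=clusters, dtype=float)
    for c in clusters:
        members = annotation.labels.index[annotation.labels == c]
        # restrict member tables to the DMR intervals before merging —
        # identical pooled counts, far smaller tables
        pseudo = merge_pseudobulk(
            [_interval_subset(allc_by_cell[bc], dmr_sets) for bc in members]
        )
        for s in set_names:
            levels.loc[c, s] = _pooled_level_in_intervals(
                pseudo, dmr_sets[dmr_sets["name"] == s]
            )
        mc = cov = 0
        for bc in members:
            allc = allc_by_cell[bc]
            rows = allc[allc["class"] == "CG"]
            if spike_contig is not None:
                rows = rows[rows["chrom"] != spike_contig]
            mc += int(rows["mc"].sum())
            cov += int(rows["cov"].sum())
        cluster_global[c] = mc / cov if cov else float("nan")
    scored = levels.div(cluster_global, axis=0) if normalize_by_global else levels
    z = (scored - scored.mean(axis=0)) / scored.std(axis=0, ddof=1)
    cluster_labels: dict[int, str | None] = {}
    for c in clusters:
        zr = z.loc[c].dropna()
        if zr.empty:
            cluster_labels[c] = None
            continue
        best = zr.idxmin()
        cluster_labels[c] = best if zr[best] < z_threshold else None
    annotation.dmr_levels = levels
    annotation.zscores = z
    annotation.cluster_labels = cluster_labels
    return annotation
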