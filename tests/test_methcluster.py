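"""Feature matrix construction, normalization, clustering, annotation."""

import numpy as np
import pandas as pd
import pytest

from dropmet import sim, methcluster
from dropmet.dmrcall import merge_pseudobulk


@pytest.fixture(scope="module")
def cluster_sim():
    """Three types, 45 cells, fragment-level sampling on a 3 Mb genome."""
    genome = sim.make_genome(n_contigs=10, contig_length=300_000,
                             spike_length=20_000, seed=101)
    meths, dmr_table = sim.make_methylomes(genome, seed=101)
    rng = np.random.default_rng(102)
    allc_by_cell, true_type = {}, {}
    for i in range(45):
        m = meths[i % 3]
        bc = f"cell{i:03d}"
        allc_by_cell[bc] = sim.sample_cell_allc(genome, m, n_reads=8_000, seed=rng)
        true_type[bc] = m.type_name
    return genome, meths, dmr_table, allc_by_cell, true_type


class TestBuildMatrix:
    def test_bin_values_near_uniform_rate(self, cluster_sim):
        genome, meths, _, allc_by_cell, _ = cluster_sim
        mat = methcluster.build_matrix(allc_by_cell, bin_width=100_000)
        # pooled bin rates stay within [0,1] and track the global level
        vals = mat.values.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_missing_bins_are_masked_not_zero(self):
        # cell "b" has no coverage on chr2: that bin must be missing
        a = _uniform_allc(rate=0.5, seed=141)
        b = _uniform_allc(rate=0.5, seed=142)
        a2 = _uniform_allc(rate=0.5, seed=143)
        a2["chrom"] = pd.Categorical(["chr2"] * len(a2))
        cells = {"a": pd.concat([a, a2], ignore_index=True), "b": b}
        mat = methcluster.build_matrix(
            cells, bin_width=100_000, min_sites_per_bin=1,
            min_cell_fraction_per_bin=0.5,
        )
        chr2_bin = [c for c in mat.values.columns if c.startswith("chr2")]
        assert chr2_bin
        assert mat.missing.loc["b", chr2_bin[0]]
        assert np.isnan(mat.values.loc["b", chr2_bin[0]])

    def test_pseudobulk_row_equals_weighted_mean_of_cells(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        cells = dict(list(allc_by_cell.items())[:4])
        mat = methcluster.build_matrix(
            cells, bin_width=100_000, min_sites_per_bin=1,
            min_cell_fraction_per_bin=1.0,
        )
        merged = {"pb": merge_pseudobulk(list(cells.values())),
                  "pb2": merge_pseudobulk(list(cells.values()))}
        pb = methcluster.build_matrix(
            merged, bin_width=100_000, min_sites_per_bin=1,
            min_cell_fraction_per_bin=1.0,
        )
        common = [b for b in mat.values.columns if b in pb.values.columns]
        for b in common[:10]:
            num = den = 0.0
            for bc, allc in cells.items():
                rows = allc[(allc["class"] == "CG") & (allc["chrom"] != "spike")]
                contig, span = b.split(":")
                s, e = map(int, span.split("-"))
                sel = rows[(rows["chrom"] == contig) & (rows["pos"] > s)
                           & (rows["pos"] <= e)]
                num += sel["mc"].sum()
                den += sel["cov"].sum()
            assert pb.values.loc["pb", b] == pytest.approx(num / den, abs=1e-12)

    def test_too_few_cells_rejected(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        only = dict(list(allc_by_cell.items())[:1])
        with pytest.raises(ValueError):
            methcluster.build_matrix(only)

    def test_no_retained_bins_is_an_error(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        with pytest.raises(ValueError):
            methcluster.build_matrix(
                dict(list(allc_by_cell.items())[:3]),
                bin_width=100_000, min_sites_per_bin=10**6,
            )


class TestNormalize:
    def test_uniform_cell_becomes_all_ones(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        mat = methcluster.build_matrix(dict(list(allc_by_cell.items())[:3]),
                                       bin_width=100_000)
        forced = methcluster.MethFeatureMatrix(
            values=pd.DataFrame(
                0.42, index=mat.values.index, columns=mat.values.columns
            ),
            missing=mat.missing,
            cell_global=pd.Series(0.42, index=mat.values.index),
            bin_width=mat.bin_width,
            cls="CG",
        )
        normed = methcluster.normalize(forced)
        assert np.allclose(normed.values.to_numpy(), 1.0)

    def test_scale_invariance_per_cell(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        mat = methcluster.build_matrix(dict(list(allc_by_cell.items())[:3]),
                                       bin_width=100_000)
        doubled = methcluster.MethFeatureMatrix(
            values=mat.values * 2,
            missing=mat.missing,
            cell_global=mat.cell_global * 2,
            bin_width=mat.bin_width,
            cls="CG",
        )
        a = methcluster.normalize(mat).values
        b = methcluster.normalize(doubled).values
        pd.testing.assert_frame_equal(a, b)

    def test_global_shift_only_types_become_indistinguishable(self):
        # two types whose methylomes differ only via their global target
        # (no type-specific domains, no DMRs, nested state draws)
        genome = sim.make_genome(n_contigs=6, contig_length=150_000,
                                 spike_length=20_000, seed=111)
        meths, _ = sim.make_methylomes(
            genome,
            [("lo", 0.45, 0.01), ("hi", 0.65, 0.01)],
            n_dmrs=1, dmr_depth=0.0, type_domain_sd=0.0, seed=111,
        )
        rng = np.random.default_rng(112)
        allc, types = {}, {}
        for i in range(24):
            m = meths[i % 2]
            bc = f"c{i:02d}"
            allc[bc] = sim.sample_cell_allc(genome, m, n_reads=6_000, seed=rng)
            types[bc] = m.type_name
        mat = methcluster.build_matrix(allc, bin_width=100_000)
        labels = pd.Series(types)

        def between_type_var(values):
            grp = values.groupby(labels.loc[values.index]).mean()
            return float(((grp.iloc[0] - grp.iloc[1]) ** 2).mean())

        raw_var = between_type_var(mat.values)
        norm_var = between_type_var(methcluster.normalize(mat).values)
        assert raw_var / norm_var >= 10

    def test_zero_global_cell_dropped(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        mat = methcluster.build_matrix(dict(list(allc_by_cell.items())[:3]),
                                       bin_width=100_000)
        mat.cell_global.iloc[0] = 0.0
        with pytest.warns(UserWarning):
            normed = methcluster.normalize(mat)
        assert len(normed.values) == 2


class TestReduceAndCluster:
    def test_three_types_recovered(self, cluster_sim):
        from sklearn.metrics import adjusted_rand_score

        _, _, _, allc_by_cell, true_type = cluster_sim
        mat = methcluster.build_matrix(allc_by_cell, bin_width=100_000)
        ann = methcluster.reduce_and_cluster(
            methcluster.normalize(mat), n_pcs=50, seed=7
        )
        ari = adjusted_rand_score(
            [true_type[b] for b in ann.labels.index], ann.labels
        )
        assert ari >= 0.9

    def test_deterministic_given_seed(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        mat = methcluster.normalize(
            methcluster.build_matrix(allc_by_cell, bin_width=100_000)
        )
        a = methcluster.reduce_and_cluster(mat, seed=3).labels
        b = methcluster.reduce_and_cluster(mat, seed=3).labels
        pd.testing.assert_series_equal(a, b)

    def test_duplicating_cells_preserves_co_membership(self, cluster_sim):
        _, _, _, allc_by_cell, _ = cluster_sim
        doubled = dict(allc_by_cell)
        doubled.update({f"{k}_copy": v for k, v in allc_by_cell.items()})
        mat1 = methcluster.normalize(
            methcluster.build_matrix(allc_by_cell, bin_width=100_000)
        )
        mat2 = methcluster.normalize(
            methcluster.build_matrix(doubled, bin_width=100_000)
        )
        l1 = methcluster.reduce_and_cluster(mat1, seed=5).labels
        l2 = methcluster.reduce_and_cluster(mat2, seed=5).labels
        cells = list(allc_by_cell)
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                assert (l1[a] == l1[b]) == (l2[a] == l2[b])

    def test_homogeneous_population_has_no_reproducible_structure(
        self, cluster_sim
    ):
        # modularity clustering always partitions a kNN graph, even of
        # i.i.d. noise; the signature of a truly homogeneous population
        # is that those partitions do not reproduce across seeds, while
        # real structure is found identically by every seed
        from sklearn.metrics import adjusted_rand_score

        genome = sim.make_genome(n_contigs=6, contig_length=150_000,
                                 spike_length=20_000, seed=121)
        meths, _ = sim.make_methylomes(genome, [("t", 0.6, 0.01)], n_dmrs=2,
                                       seed=121)
        rng = np.random.default_rng(122)
        allc = {
            f"c{i:02d}": sim.sample_cell_allc(genome, meths[0], n_reads=6_000,
                                              seed=rng)
            for i in range(20)
        }
        mat = methcluster.normalize(methcluster.build_matrix(allc, bin_width=100_000))
        labs = [methcluster.reduce_and_cluster(mat, seed=s).labels
                for s in range(6)]
        aris = [adjusted_rand_score(labs[i], labs[j])
                for i in range(6) for j in range(i + 1, 6)]
        assert np.mean(aris) < 0.7

        _, _, _, allc_by_cell, _ = cluster_sim
        mat3 = methcluster.normalize(
            methcluster.build_matrix(allc_by_cell, bin_width=100_000)
        )
        labs3 = [methcluster.reduce_and_cluster(mat3, seed=s).labels
                 for s in range(6)]
        aris3 = [adjusted_rand_score(labs3[i], labs3[j])
                 for i in range(6) for j in range(i + 1, 6)]
        assert np.mean(aris3) > 0.9

    def test_degenerate_matrix_rejected(self):
        values = pd.DataFrame(1.0, index=[f"c{i}" for i in range(5)],
                              columns=["b1", "b2"])
        mat = methcluster.MethFeatureMatrix(
            values=values, missing=values.isna(),
            cell_global=pd.Series(0.5, index=values.index),
            bin_width=100_000, cls="CG", normalized=True,
        )
        with pytest.raises(ValueError):
            methcluster.reduce_and_cluster(mat)


class TestAnnotateClusters:
    def test_hand_computed_two_cluster_zscores(self):
        # two clusters, one set, raw levels 0.2 and 0.8: z = -/+ 1/sqrt(2)
        allc_a = _uniform_allc(rate=0.2, seed=131)
        allc_b = _uniform_allc(rate=0.8, seed=132)
        labels = pd.Series([0, 1], index=["a", "b"], name="cluster")
        ann = methcluster.ClusterAnnotation(labels=labels)
        sets = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10_000], "name": ["s"]}
        )
        ann = methcluster.annotate_clusters(
            ann, {"a": allc_a, "b": allc_b}, sets, normalize_by_global=False
        )
        assert ann.zscores.loc[0, "s"] == pytest.approx(-1 / np.sqrt(2), abs=1e-6)
        assert ann.zscores.loc[1, "s"] == pytest.approx(+1 / np.sqrt(2), abs=1e-6)

    def test_z_columns_standardised(self, cluster_sim):
        _, _, dmr_table, allc_by_cell, true_type = cluster_sim
        labels = pd.Series(
            {bc: {"typeA": 0, "typeB": 1, "typeC": 2}[t]
             for bc, t in true_type.items()},
            name="cluster",
        )
        ann = methcluster.ClusterAnnotation(labels=labels)
        ann = methcluster.annotate_clusters(ann, allc_by_cell, dmr_table)
        z = ann.zscores
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_true_partition_labelled_with_true_types(self, cluster_sim):
        _, _, dmr_table, allc_by_cell, true_type = cluster_sim
        labels = pd.Series(
            {bc: {"typeA": 0, "typeB": 1, "typeC": 2}[t]
             for bc, t in true_type.items()},
            name="cluster",
        )
        ann = methcluster.ClusterAnnotation(labels=labels)
        ann = methcluster.annotate_clusters(ann, allc_by_cell, dmr_table)
        assert ann.cluster_labels == {0: "typeA", 1: "typeB", 2: "typeC"}

    def test_label_invariant_under_cluster_id_permutation(self, cluster_sim):
        _, _, dmr_table, allc_by_cell, true_type = cluster_sim
        mapping = {"typeA": 0, "typeB": 1, "typeC": 2}
        permuted = {"typeA": 2, "typeB": 0, "typeC": 1}
        out = {}
        for mp in (mapping, permuted):
            labels = pd.Series({bc: mp[t] for bc, t in true_type.items()},
                               name="cluster")
            ann = methcluster.annotate_clusters(
                methcluster.ClusterAnnotation(labels=labels), allc_by_cell,
                dmr_table,
            )
            out[tuple(sorted(mp.items()))] = {
                t: ann.cluster_labels[mp[t]] for t in mapping
            }
        a, b = out.values()
        assert a == b

    def test_single_cluster_rejected(self, cluster_sim):
        _, _, dmr_table, allc_by_cell, _ = cluster_sim
        labels = pd.Series(0, index=list(allc_by_cell), name="cluster")
        with pytest.raises(ValueError):
            methcluster.annotate_clusters(
                methcluster.ClusterAnnotation(labels=labels), allc_by_cell,
                dmr_table,
            )


def _uniform_allc(rate: float, seed: int, n_sites: int = 2_000):
    rng = np.random.default_rng(seed)
    cov = np.full(n_sites, 20, dtype=np.int32)
    mc = rng.binomial(cov, rate).astype(np.int32)
    return pd.DataFrame(
        {
            "chrom": pd.Categorical(["chr1"] * n_sites),
            "pos": np.arange(1, n_sites + 1),
            "strand": pd.Categorical(["+"] * n_sites, categories=["+", "-"]),
            "context": pd.Categorical(["CGA"] * n_sites),
            "class": pd.Categorical(["CG"] * n_sites, categories=["CG", "CH"]),
            "mc": mc,
            "cov": cov,
            "methylated": (mc > 0).astype(np.int8),
        }
    )
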