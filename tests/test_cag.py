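import numpy as np
import pandas as pd
import pytest
import skbio

from cagmicro import (
    AbundanceTable,
    DataError,
    SimulationConfig,
    build_cag_model,
    cag_correlation,
    cag_profiles,
    cluster_samples,
    compare_cag_abundance,
    cut_tree,
    exclude_group_and_recompute,
    filter_genera,
    genus_distance,
    pick_dominant_group,
    simulate,
    to_relative,
    ward_cluster,
)
from cagmicro.cag import CagModel, SampleGrouping
from cagmicro.diversity import DistanceMatrix

from conftest import make_meta


def brute_force_ward(d: np.ndarray):
    """Independent Ward oracle: recompute each merge cost from the ORIGINAL
    squared dissimilarities via the centroid identity
    cost(A,B) = 2 nA nB/(nA+nB) * (cross - V_A - V_B)."""
    d2 = d ** 2
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    ids = list(range(n))
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A, B = clusters[a], clusters[b]
                na, nb = len(A), len(B)
                cross = d2[np.ix_(A, B)].sum() / (na * nb)
                va = d2[np.ix_(A, A)].sum() / (2 * na ** 2)
                vb = d2[np.ix_(B, B)].sum() / (2 * nb ** 2)
                cost = 2 * na * nb / (na + nb) * (cross - va - vb)
                key = (cost, min(A), min(B))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (cost, _, _), a, b = best
        merges.append((ids[a], ids[b], np.sqrt(max(cost, 0.0)),
                       len(clusters[a]) + len(clusters[b])))
        clusters[a] = clusters[a] + clusters[b]
        ids[a] = next_id
        next_id += 1
        del clusters[b], ids[b]
    return np.asarray(merges)


class TestFilterGenera:
    @staticmethod
    def _toy():
        # hand table: means TT/NT per genus computed directly
        df = pd.DataFrame({
            "s1": [0.0004, 0.003, 0.9966],   # TT
            "s2": [0.0006, 0.001, 0.9984],   # TT
            "s3": [0.0005, 0.0004, 0.9991],  # NT
            "s4": [0.0005, 0.0006, 0.9989],  # NT
        }, index=["low_both", "tt_only", "high"])
        t = AbundanceTable(df, kind="relative")
        meta = make_meta(["s1", "s2", "s3", "s4"], ["TT", "TT", "NT", "NT"],
                         patients=["p1", "p2", "p1", "p2"])
        return t, meta

    def test_threshold_is_strict_and_mode_dependent(self):
        t, meta = self._toy()
        # low_both: mean 0.05% in both -> out; tt_only: 0.2% TT / 0.05% NT
        both = filter_genera(t, meta, threshold=0.001, mode="both_groups")
        assert both.retained == ("high",)
        either = filter_genera(t, meta, threshold=0.001, mode="either_group")
        assert set(either.retained) == {"tt_only", "high"}

    def test_missing_tissue_group_rejected(self):
        t, meta = self._toy()
        with pytest.raises(DataError):
            filter_genera(t, meta.assign(tissue="TT"))


class TestGenusDistance:
    def test_self_distance_zero_and_anticorrelation_two(self):
        df = pd.DataFrame({"s1": [1, 3, 1], "s2": [2, 2, 2], "s3": [3, 1, 3]},
                          index=["up", "down", "up2"], dtype=float)
        t = AbundanceTable(df / df.sum(axis=0), kind="fraction")
        dm = genus_distance(t, ["up", "down", "up2"], mode="spearman")
        f = dm.to_frame()
        assert f.loc["up", "up"] == 0.0
        assert f.loc["up", "down"] == pytest.approx(2.0)
        assert f.loc["up", "up2"] == pytest.approx(0.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((3, 8))
        t = AbundanceTable(pd.DataFrame(x, index=["a", "b", "c"],
                                        columns=[f"s{i}" for i in range(8)]),
                           kind="fraction")
        dm = genus_distance(t, ["a", "b", "c"], mode="spearman").to_frame()
        for g, h in [("a", "b"), ("a", "c"), ("b", "c")]:
            rg = pd.Series(x[{"a": 0, "b": 1, "c": 2}[g]]).rank()
            rh = pd.Series(x[{"a": 0, "b": 1, "c": 2}[h]]).rank()
            n = 8
            rho = 1 - 6 * ((rg - rh) ** 2).sum() / (n * (n ** 2 - 1))
            assert dm.loc[g, h] == pytest.approx(1 - rho, abs=1e-12)

    def test_constant_genus_named_in_error(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [1, 3], "s3": [1, 4]},
                          index=["flat", "ok"], dtype=float)
        t = AbundanceTable(df, kind="fraction")
        with pytest.raises(DataError, match="flat"):
            genus_distance(t, ["flat", "ok"], mode="spearman")


class TestWardCluster:
    def test_nearest_pair_merges_first(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], float)
        dn = ward_cluster(DistanceMatrix(("A", "B", "C"), d))
        assert tuple(dn.merges[0, :2]) == (0, 1)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            dn = ward_cluster(DistanceMatrix(tuple(map(str, range(n))), d))
            oracle = brute_force_ward(d)
            np.testing.assert_array_equal(dn.merges[:, :2], oracle[:, :2])
            np.testing.assert_allclose(dn.merges[:, 2], oracle[:, 2], atol=1e-10)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(2)
        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dn = ward_cluster(DistanceMatrix(tuple(map(str, range(12))), d))
        assert (np.diff(dn.merges[:, 2]) >= -1e-12).all()

    def test_ultrametric_topology_recovered(self):
        # 2-level ultrametric: pairs at 1, across at 3; ward.D2 recovers the
        # grouping (heights beyond the first level inflate with cluster size)
        d = np.array([[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 1], [3, 3, 1, 0]], float)
        dn = ward_cluster(DistanceMatrix(("a", "b", "c", "d"), d))
        assert cut_tree(dn, 2) == {"a": 1, "b": 1, "c": 2, "d": 2}
        np.testing.assert_allclose(dn.merges[:2, 2], 1.0)

    def test_newick_export_round_trips_through_skbio(self):
        rng = np.random.default_rng(3)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = tuple(f"g{i}" for i in range(6))
        dn = ward_cluster(DistanceMatrix(labels, d))
        tree = skbio.TreeNode.read([dn.to_newick()])
        assert sorted(t.name for t in tree.tips()) == sorted(labels)
        root_height = dn.merges[-1, 2]
        for tip in tree.tips():
            assert tip.distance(tree) == pytest.approx(root_height, abs=1e-6)


class TestCutTree:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(4)
        d = rng.random((5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dn = ward_cluster(DistanceMatrix(tuple("abcde"), d))
        assert set(cut_tree(dn, 1).values()) == {1}
        assert sorted(cut_tree(dn, 5).values()) == [1, 2, 3, 4, 5]
        with pytest.raises(DataError):
            cut_tree(dn, 6)

    def test_recovers_planted_blocks_at_strong_signal(self, default_dataset):
        from sklearn.metrics import adjusted_rand_score
        ds = default_dataset
        rel = to_relative(ds.table)
        model = build_cag_model(rel, ds.meta, k=4)
        planted = ds.truth["genus_block"]
        common = [g for g in model.assignment if g in planted]
        ari = adjusted_rand_score([planted[g] for g in common],
                                  [model.assignment[g] for g in common])
        assert ari == pytest.approx(1.0)


def _profiles_fixture():
    """Hand-built 2-CAG profile table over 6 samples (3 patients x 2 tissues)."""
    df = pd.DataFrame({
        "p1_TT": [0.30, 0.10], "p1_NT": [0.20, 0.25],
        "p2_TT": [0.35, 0.05], "p2_NT": [0.15, 0.30],
        "p3_TT": [0.40, 0.00], "p3_NT": [0.10, 0.35],
    }, index=["CAG1", "CAG2"])
    profiles = AbundanceTable(df, kind="fraction")
    meta = make_meta(list(df.columns), ["TT", "NT"] * 3)
    return profiles, meta


class TestCagProfiles:
    def test_singleton_and_total_sums(self, tiny_counts, tiny_meta):
        rel = to_relative(tiny_counts)
        dn = ward_cluster(genus_distance(rel, rel.taxa, mode="spearman"))
        single = CagModel({"gA": "CAG1", "gB": "CAG2", "gC": "CAG2"}, 2, dn, "spearman")
        prof = cag_profiles(rel, single)
        np.testing.assert_allclose(prof.data.loc["CAG1"], rel.data.loc["gA"])
        one = CagModel({g: "CAG1" for g in rel.taxa}, 1, dn, "spearman")
        prof_all = cag_profiles(rel, one)
        np.testing.assert_allclose(prof_all.data.loc["CAG1"], rel.values().sum(axis=0))

    def test_mass_conservation_is_exact(self, default_dataset):
        rel = to_relative(default_dataset.table)
        model = build_cag_model(rel, default_dataset.meta)
        prof = cag_profiles(rel, model)
        retained = list(model.assignment)
        np.testing.assert_allclose(prof.values().sum(axis=0),
                                   rel.data.loc[retained].sum(axis=0), atol=1e-12)

    def test_empty_cag_rejected(self, tiny_counts, tiny_meta):
        rel = to_relative(tiny_counts)
        dn = ward_cluster(genus_distance(rel, rel.taxa, mode="spearman"))
        model = CagModel({"gA": "CAG1", "gB": "CAG1", "gC": "CAG1"}, 2, dn, "spearman")
        with pytest.raises(DataError):
            cag_profiles(rel, model)


class TestClusterSamples:
    def test_duplicate_samples_coassigned(self):
        base = np.array([[0.5, 0.1], [0.2, 0.6], [0.1, 0.1]])
        cols = {name: base[:, i % 2]
                for i, name in enumerate(["a1", "a2", "b1", "b2", "c1", "c2"])}
        df = pd.DataFrame(cols, index=["CAG1", "CAG2", "CAG3"])
        profiles = AbundanceTable(df, kind="fraction")
        meta = make_meta(list(df.columns), ["TT", "NT"] * 3)
        grouping = cluster_samples(profiles, 2, meta)
        a = grouping.assignment
        assert a["a1"] == a["b1"] == a["c1"]
        assert a["a2"] == a["b2"] == a["c2"]
        assert a["a1"] != a["a2"]

    def test_composition_counts_sum_to_group_sizes(self, default_dataset):
        rel = to_relative(default_dataset.table)
        model = build_cag_model(rel, default_dataset.meta)
        prof = cag_profiles(rel, model)
        grouping = cluster_samples(prof, 6, default_dataset.meta)
        sizes = pd.Series(grouping.assignment).value_counts().sort_index()
        totals = grouping.composition.sum(axis=1)
        assert (totals.loc[sizes.index] == sizes).all()
        assert totals.sum() == len(prof.samples)

    def test_two_regimes_recovered(self):
        rng = np.random.default_rng(6)
        regime = np.array([0] * 10 + [1] * 10)
        base = np.array([[0.7, 0.05], [0.1, 0.6], [0.2, 0.35]])
        cols = {f"s{i}": base[:, r] * rng.uniform(0.95, 1.05, 3) for i, r in enumerate(regime)}
        df = pd.DataFrame(cols, index=["CAG1", "CAG2", "CAG3"])
        meta = make_meta(list(df.columns), ["TT"] * 10 + ["NT"] * 10)
        grouping = cluster_samples(AbundanceTable(df, kind="fraction"), 2, meta)
        got = np.array([grouping.assignment[f"s{i}"] for i in range(20)])
        assert len(set(got[:10])) == 1 and len(set(got[10:])) == 1
        assert got[0] != got[-1]


class TestCompareCagAbundance:
    def test_medians_over_all_samples_and_percent_scale(self):
        profiles, meta = _profiles_fixture()
        res = {r.feature: r for r in compare_cag_abundance(profiles, meta)}
        # CAG2 TT values (0.10, 0.05, 0.00): median 5% including the zero
        assert res["CAG2"].group_medians["TT"] == pytest.approx(5.0)
        assert res["CAG2"].group_medians["NT"] == pytest.approx(30.0)

    def test_identical_distributions_give_high_p(self):
        df = pd.DataFrame(np.tile([[0.4], [0.2]], (1, 8)),
                          index=["CAG1", "CAG2"],
                          columns=[f"s{i}" for i in range(8)])
        meta = make_meta(list(df.columns), ["TT", "NT"] * 4)
        res = compare_cag_abundance(AbundanceTable(df, kind="fraction"), meta)
        assert all(r.p_value > 0.9 for r in res)

    def test_paired_mode_uses_within_patient_differences(self):
        profiles, meta = _profiles_fixture()
        res = {r.feature: r for r in compare_cag_abundance(profiles, meta, paired=True)}
        assert res["CAG1"].test == "wilcoxon_signed_rank"
        # all three TT-NT differences positive for CAG1 -> one-sided extreme
        assert res["CAG1"].p_value == pytest.approx(2 / 8)


class TestExclusion:
    def test_excluding_empty_group_is_identity(self):
        profiles, meta = _profiles_fixture()
        grouping = SampleGrouping(
            {s: 1 for s in profiles.samples}, 2,
            pd.DataFrame({"TT": [3, 0], "NT": [3, 0]}, index=[1, 2]),
            cluster_samples(profiles, 1, meta).dendrogram)
        full = compare_cag_abundance(profiles, meta)
        post, corr = exclude_group_and_recompute(profiles, grouping, 2, meta)
        for a, b in zip(full, post):
            assert a.p_value == b.p_value and a.group_medians == b.group_medians
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_two_regime_design_unmasks_secondary_contrast(self):
        # regime 1: CAG1 ~ everything, masking; regime 2: CAG3 enriched in NT
        rng = np.random.default_rng(7)
        cols, tissues = {}, []
        for i in range(20):  # regime-1 patients, both tissues ~ pure CAG1
            for tis in ("TT", "NT"):
                noise = rng.uniform(0.0, 0.004, 3)
                cols[f"r1p{i}_{tis}"] = [1 - noise.sum(), *noise[:2]]
                tissues.append(tis)
        for i in range(20):  # regime-2: CAG3 higher in NT, CAG1 moderate
            for tis in ("TT", "NT"):
                cag3 = rng.uniform(0.25, 0.35) if tis == "NT" else rng.uniform(0.02, 0.08)
                cag1 = rng.uniform(0.3, 0.4)
                cols[f"r2p{i}_{tis}"] = [cag1, rng.uniform(0.09, 0.11), cag3]
                tissues.append(tis)
        df = pd.DataFrame(cols, index=["CAG1", "CAG2", "CAG3"])
        profiles = AbundanceTable(df, kind="fraction")
        meta = make_meta(list(df.columns), tissues)
        grouping = cluster_samples(profiles, 2, meta)
        excl = pick_dominant_group(profiles, grouping, cag="CAG1", share=0.9)
        assert excl is not None
        full = {r.feature: r for r in compare_cag_abundance(profiles, meta)}
        post, corr = exclude_group_and_recompute(profiles, grouping, excl, meta)
        post = {r.feature: r for r in post}
        assert post["CAG3"].p_value < 0.001
        assert post["CAG3"].group_medians["NT"] > post["CAG3"].group_medians["TT"]
        # the dominant-regime masking kept CAG1's full-cohort contrast mild
        assert full["CAG1"].p_value > post["CAG3"].p_value

    def test_correlation_matrix_identity(self, default_dataset):
        rel = to_relative(default_dataset.table)
        model = build_cag_model(rel, default_dataset.meta)
        prof = cag_profiles(rel, model)
        corr = cag_correlation(prof)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
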