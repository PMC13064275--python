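"""Alpha diversity, distance kernels, restricted-permutation PERMANOVA,
individuality, recovery trajectories, and log-fold baselines."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as skbio_permanova

from airway_recovery import diversity as dv
from airway_recovery import synthetic_cohort as sc
from airway_recovery.experiments import brute_weighted_unifrac


class TestAlpha:
    @pytest.mark.parametrize("counts, expected", [
        ((0, 0, 0), 0), ((1, 0, 7), 2), ((1, 1, 1, 1), 4)])
    def test_observed_richness(self, counts, expected):
        assert dv.observed_richness(counts) == expected

    def test_richness_permutation_invariant(self, rng):
        x = rng.integers(0, 5, size=30)
        assert dv.observed_richness(x) == dv.observed_richness(rng.permutation(x))

    @pytest.mark.parametrize("counts, expected", [
        ((5, 5, 5, 5), 1.0),
        ((10, 0, 0), 1.0),  # single-taxon convention
        ((8, 2), -(0.8 * np.log(0.8) + 0.2 * np.log(0.2)) / np.log(2)),
    ])
    def test_pielou(self, counts, expected):
        assert dv.pielou_evenness(counts) == pytest.approx(expected)

    def test_pielou_all_zero_errors(self):
        with pytest.raises(ValueError):
            dv.pielou_evenness((0, 0))


class TestBrayCurtis:
    def test_examples(self):
        tab = pd.DataFrame([[1, 2, 3], [3, 2, 1], [1, 2, 3], [0, 0, 0], [0, 0, 0]],
                           index=list("abcde"), columns=list("xyz"))
        bc = dv.bray_curtis(tab)
        assert bc["a", "b"] == pytest.approx(1 / 3)
        assert bc["a", "c"] == 0.0
        assert bc["d", "e"] == 0.0  # all-zero pair convention

    def test_disjoint_supports(self):
        tab = pd.DataFrame([[5, 0], [0, 3]], index=["a", "b"], columns=["x", "y"])
        assert dv.bray_curtis(tab)["a", "b"] == 1.0

    def test_matches_scipy_on_positive_data(self, rng):
        from scipy.spatial.distance import braycurtis
        tab = pd.DataFrame(rng.integers(1, 50, size=(6, 10)),
                           index=[f"s{i}" for i in range(6)])
        bc = dv.bray_curtis(tab)
        for i in range(6):
            for j in range(i + 1, 6):
                assert bc[f"s{i}", f"s{j}"] == pytest.approx(
                    braycurtis(tab.iloc[i], tab.iloc[j]), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_range_zero_diagonal(self, seed):
        r = np.random.default_rng(seed)
        tab = pd.DataFrame(r.integers(0, 30, size=(4, 6)))
        tab.iloc[:, 0] += 1
        d = dv.bray_curtis(tab).data
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()
        assert ((d >= 0) & (d <= 1)).all()


class TestWeightedUnifrac:
    def test_two_tip_split(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1)root;"))
        tab = pd.DataFrame([[10, 0], [0, 4]], index=["x", "y"], columns=["A", "B"])
        raw = dv.weighted_unifrac(tab, tree, normalized=False)
        norm = dv.weighted_unifrac(tab, tree, normalized=True)
        assert raw["x", "y"] == pytest.approx(2.0)
        assert norm["x", "y"] == pytest.approx(1.0)

    def test_identical_samples_zero(self, tree20):
        taxa = [t.name for t in tree20.tips()]
        tab = pd.DataFrame([np.arange(20), np.arange(20)],
                           index=["a", "b"], columns=taxa)
        tab += 1
        assert dv.weighted_unifrac(tab, tree20)["a", "b"] == 0.0

    def test_missing_taxon_listed(self, tree20):
        tab = pd.DataFrame([[1, 2]], index=["s"], columns=["ASV_0001", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            dv.weighted_unifrac(tab, tree20)

    def test_agrees_with_bruteforce_and_skbio(self, rng):
        from skbio.diversity.beta import weighted_unifrac as sk_wu
        for rep in range(10):
            tree = sc.simulate_tree(8, seed=rep)
            taxa = [t.name for t in tree.tips()]
            tab = pd.DataFrame(rng.integers(0, 15, size=(4, 8)), columns=taxa,
                               index=[f"s{i}" for i in range(4)])
            tab.iloc[:, 0] += 1
            dm = dv.weighted_unifrac(tab, tree, normalized=True)
            for i in range(4):
                for j in range(i + 1, 4):
                    brute = brute_weighted_unifrac(dict(tab.iloc[i]), dict(tab.iloc[j]), tree)
                    theirs = sk_wu(tab.iloc[i].values, tab.iloc[j].values,
                                   taxa=taxa, tree=tree, normalized=True)
                    assert dm[f"s{i}", f"s{j}"] == pytest.approx(brute, abs=1e-10)
                    assert dm[f"s{i}", f"s{j}"] == pytest.approx(theirs, abs=1e-10)


class TestPermanova:
    @pytest.fixture()
    def separated(self):
        r = np.random.default_rng(3)
        pts = np.vstack([r.normal(0, 0.01, (8, 2)), r.normal(10, 0.01, (8, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix(d, ids=[str(i) for i in range(16)])

    def test_maximal_separation_minimal_p(self, separated):
        res = dv.permanova(separated, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.r2 > 0.9

    def test_pseudo_f_matches_hand_partition(self):
        """6 points, 2 groups: SS terms computed by hand from the Anderson
        decomposition of squared distances."""
        d = np.array([
            [0, 1, 2, 5, 5, 5],
            [1, 0, 1, 5, 5, 5],
            [2, 1, 0, 5, 5, 5],
            [5, 5, 5, 0, 1, 2],
            [5, 5, 5, 1, 0, 1],
            [5, 5, 5, 2, 1, 0]], float)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        labels = ["g1"] * 3 + ["g2"] * 3
        # SS_total = sum of squared distances over all pairs / n
        ss_t = (d[np.triu_indices(6, 1)] ** 2).sum() / 6
        ss_w = 2 * ((1 + 1 + 4) / 3)  # two identical groups
        f_hand = (ss_t - ss_w) / 1 / (ss_w / 4)
        res = dv.permanova(dm, labels, n_perm=99, seed=0)
        assert res.pseudo_F == pytest.approx(f_hand)

    def test_matches_skbio_without_strata(self, rng):
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        mine = dv.permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, list(labels), permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_constant_factor_within_strata_rejected(self, separated):
        labels = ["a"] * 8 + ["b"] * 8
        strata = list(np.repeat(np.arange(8), 2))
        # factor constant within every stratum -> no admissible permutations
        with pytest.raises(ValueError, match="stratum|strata|admissible"):
            dv.permanova(separated, labels, strata=strata, n_perm=99, seed=0)

    def test_stratified_permutation_never_crosses_subjects(self, rng):
        labels = np.array(["x", "y", "z"] * 5)
        strata = np.repeat(np.arange(5), 3)
        groups = [np.flatnonzero(strata == s) for s in range(5)]
        for _ in range(50):
            perm = dv._stratified_permutation(labels, groups, rng)
            for g in groups:
                assert sorted(perm[g]) == sorted(labels[g])


class TestIndividuality:
    def _dm(self, d):
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(len(d))])

    def _meta(self, n, site="nose", group="NS"):
        return pd.DataFrame({"subject_id": [f"p{i}" for i in range(n)],
                             "site": site, "group": group},
                            index=[f"s{i}" for i in range(n)])

    def test_identical_samples_score_zero(self):
        dm = self._dm(np.zeros((4, 4)))
        scores, _ = dv.individuality(dm, self._meta(4))
        assert (scores["score"] == 0).all()

    def test_two_samples_midpoint(self):
        dm = self._dm(np.array([[0, 3.0], [3.0, 0]]))
        scores, _ = dv.individuality(dm, self._meta(2))
        assert scores["score"].values == pytest.approx([1.5, 1.5])

    def test_constant_taxon_invariance(self, rng):
        """Adding a constant taxon to every sample leaves Euclidean distances
        unchanged, hence the scores are unchanged too."""
        pts = rng.normal(size=(6, 5))
        aug = np.hstack([pts, np.full((6, 1), 3.0)])

        def euclid_dm(x):
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            return self._dm(d)

        meta = self._meta(6)
        base, _ = dv.individuality(euclid_dm(pts), meta)
        augd, _ = dv.individuality(euclid_dm(aug), meta)
        pd.testing.assert_frame_equal(base, augd)

    def test_singleton_group_skipped_with_warning(self):
        dm = self._dm(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        meta = self._meta(3)
        meta.loc["s2", "group"] = "AS"
        scores, warnings = dv.individuality(dm, meta)
        assert len(warnings) == 1 and "skipped" in warnings[0]
        assert set(scores["sample_id"]) == {"s0", "s1"}

    def test_monotone_in_subject_sd(self):
        """Parameter recovery: higher subject random-effect SD gives larger
        mean distance-to-centroid (two generator levels, one seed)."""
        means = []
        for sd in (0.0, 1.5):
            cfg = sc.SimConfig(n_taxa_pool=80, depth_mean=1500.0,
                               sites=("oropharynx",), n_subjects_per_group={"NS": 8},
                               contaminant_fraction=0.0, n_blanks=0,
                               subject_sd=sd, seed=5)
            counts, meta, tree, *_ = sc.simulate_cohort(cfg)
            bio = meta[meta["group"] != "blank"]
            scores, _ = dv.individuality(dv.weighted_unifrac(counts.loc[bio.index], tree), bio)
            means.append(scores["score"].mean())
        assert means[0] < means[1]


class TestRecoveryTrajectory:
    @pytest.fixture()
    def cohort_dm(self):
        tab = pd.DataFrame([[5, 5, 0], [5, 5, 0], [5, 5, 0], [0, 0, 9]],
                           index=["ns1", "ns2", "as_same", "as_far"],
                           columns=list("xyz"))
        meta = pd.DataFrame({"subject_id": ["a", "b", "c", "d"],
                             "site": "nose",
                             "group": ["NS", "NS", "AS", "AS"]}, index=tab.index)
        return dv.bray_curtis(tab), meta

    def test_identical_to_baseline_scores_one(self, cohort_dm):
        traj, _ = dv.recovery_trajectory(*cohort_dm)
        assert traj.set_index("sample_id").loc["as_same", "similarity"] == 1.0

    def test_disjoint_support_scores_zero(self, cohort_dm):
        traj, _ = dv.recovery_trajectory(*cohort_dm)
        assert traj.set_index("sample_id").loc["as_far", "similarity"] == 0.0

    def test_missing_baseline_site_warns(self, cohort_dm):
        dm, meta = cohort_dm
        meta = meta.copy()
        meta.loc[["ns1", "ns2"], "group"] = "AS"
        traj, warnings = dv.recovery_trajectory(dm, meta)
        assert traj.empty and len(warnings) == 1


class TestSitePairDistance:
    def test_within_subject_pairing(self):
        tab = pd.DataFrame([[1, 0], [1, 0], [1, 0], [0, 1]],
                           index=["p1_op", "p1_bal", "p2_op", "p2_bal"],
                           columns=["x", "y"])
        meta = pd.DataFrame({
            "subject_id": ["p1", "p1", "p2", "p2"],
            "site": ["oropharynx", "BAL", "oropharynx", "BAL"],
            "group": "NS", "timepoint": "baseline"}, index=tab.index)
        out, info = dv.site_pair_distance(dv.bray_curtis(tab), meta, "oropharynx", "BAL")
        vals = out.set_index("subject_id")["distance"]
        assert vals["p1"] == 0.0 and vals["p2"] == 1.0
        assert info["excluded_subject_timepoints"] == 0

    def test_missing_site_excluded_and_counted(self):
        tab = pd.DataFrame([[1, 0], [1, 0], [2, 1]],
                           index=["p1_op", "p1_bal", "p2_op"], columns=["x", "y"])
        meta = pd.DataFrame({
            "subject_id": ["p1", "p1", "p2"],
            "site": ["oropharynx", "BAL", "oropharynx"],
            "group": "NS", "timepoint": "baseline"}, index=tab.index)
        out, info = dv.site_pair_distance(dv.bray_curtis(tab), meta, "oropharynx", "BAL")
        assert len(out) == 1 and info["excluded_subject_timepoints"] == 1


class TestLogfoldToBaseline:
    @pytest.fixture()
    def genus_setup(self):
        vals = pd.DataFrame(
            {"g1": [10.0, 10.0, 10.0], "g2": [4.0, 4.0, 16.0], "g3": [0.0, 0.0, 0.0]},
            index=["ns1", "ns2", "as1"])
        meta = pd.DataFrame({"subject_id": list("abc"), "site": "nose",
                             "group": ["NS", "NS", "AS"]}, index=vals.index)
        return vals, meta

    def test_equal_to_baseline_is_zero(self, genus_setup):
        lf = dv.logfold_to_baseline(*genus_setup, pseudo=1e-6)
        assert lf.loc["as1", "g1"] == pytest.approx(0.0)

    def test_fourfold_is_two(self, genus_setup):
        lf = dv.logfold_to_baseline(*genus_setup, pseudo=1e-9)
        assert lf.loc["as1", "g2"] == pytest.approx(2.0, abs=1e-6)

    def test_absent_everywhere_is_zero(self, genus_setup):
        lf = dv.logfold_to_baseline(*genus_setup)
        assert lf.loc["as1", "g3"] == 0.0
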