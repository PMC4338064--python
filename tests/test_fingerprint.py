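"""Fingerprint chain: filtering, alignment, normalisation, similarity,
diversity, ANOSIM/SIMPER/SIMPROF and Local Southern sizing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import biofilmdia as b
from biofilmdia import fingerprint as fp
from biofilmdia.errors import DataError


def profile(sample_id, rows, marker="T-RF"):
    return fp.FingerprintProfile(
        sample_id=sample_id,
        peaks=pd.DataFrame(rows, columns=["size_nt", "height", "area"]),
        marker=marker)


class TestFilterPeaks:
    def test_strictly_greater_than_cutoff(self):
        p = profile("s1", [(100.0, 49.0, 5.0), (110.0, 50.0, 6.0),
                           (120.0, 51.0, 7.0)])
        out = fp.filter_peaks(p)
        assert list(out.peaks["size_nt"]) == [120.0]

    def test_size_window(self):
        p = profile("s1", [(45.0, 100.0, 5.0), (50.0, 100.0, 5.0),
                           (500.0, 100.0, 5.0), (501.0, 100.0, 5.0)])
        out = fp.filter_peaks(p)
        assert list(out.peaks["size_nt"]) == [50.0, 500.0]

    def test_arisa_window(self):
        p = profile("s1", [(93.0, 100.0, 5.0), (94.0, 100.0, 5.0),
                           (827.0, 100.0, 5.0)], marker="ARISA")
        out = fp.filter_peaks(p)
        assert list(out.peaks["size_nt"]) == [94.0, 827.0]

    def test_empty_result_warns(self):
        p = profile("s1", [(100.0, 10.0, 5.0)])
        with pytest.warns(UserWarning, match="no peaks"):
            out = fp.filter_peaks(p)
        assert out.peaks.empty


class TestAlignFragments:
    def test_close_sizes_share_a_bin(self):
        a = profile("s1", [(100.2, 100.0, 5.0)])
        c = profile("s2", [(100.5, 100.0, 7.0)])
        table = fp.align_fragments([a, c])
        assert table.shape[1] == 1  # delta 0.3 < 0.5
        assert table.iloc[:, 0].tolist() == [5.0, 7.0]

    def test_distant_sizes_split(self):
        a = profile("s1", [(100.2, 100.0, 5.0)])
        c = profile("s2", [(100.8, 100.0, 7.0)])
        table = fp.align_fragments([a, c])
        assert table.shape[1] == 2  # delta 0.6 >= 0.5

    def test_within_sample_merge_sums_areas(self):
        a = profile("s1", [(100.0, 100.0, 5.0), (100.3, 100.0, 3.0)])
        c = profile("s2", [(100.1, 100.0, 2.0)])
        table = fp.align_fragments([a, c])
        assert table.shape[1] == 1
        assert table.loc["s1"].iloc[0] == 8.0

    def test_idempotent(self):
        rng = np.random.default_rng(17)
        profiles = [profile(f"s{i}",
                            [(s + rng.normal(0, 0.05), 100.0, rng.uniform(1, 9))
                             for s in (100.0, 150.0, 200.0)])
                    for i in range(4)]
        table = fp.align_fragments(profiles)
        rebuilt = [profile(sid, [(sz, 100.0, ar)
                                 for sz, ar in zip(table.columns, row)
                                 if ar > 0])
                   for sid, row in table.iterrows()]
        again = fp.align_fragments(rebuilt)
        assert list(again.columns) == list(table.columns)
        np.testing.assert_allclose(again.to_numpy(), table.to_numpy())

    def test_jittered_dataset_recovers_true_bin_count(self):
        params = b.FingerprintParams(size_jitter_sd_nt=0.1, n_noise_peaks=0)
        profiles, truth = b.generate_fingerprint_dataset(params, seed=18)
        filtered = [fp.filter_peaks(p) for p in profiles]
        table = fp.align_fragments(filtered)
        n_true = len(set(np.concatenate(
            [v for v in truth["group_sizes"].values()])))
        assert table.shape[1] == n_true


class TestNormalise:
    def test_sub_half_percent_removed(self):
        m = pd.DataFrame([[99.6, 0.4]], index=["s1"], columns=[100.0, 200.0])
        out = fp.normalise(m)
        assert out.shape[1] == 1
        assert out.iloc[0, 0] == pytest.approx(1.0)

    def test_exactly_half_percent_retained(self):
        m = pd.DataFrame([[99.5, 0.5]], index=["s1"], columns=[100.0, 200.0])
        out = fp.normalise(m)
        assert out.shape[1] == 2
        assert out.iloc[0, 1] == pytest.approx(0.005)

    def test_three_sample_hand_table(self):
        m = pd.DataFrame([[80.0, 19.9, 0.1],
                          [50.0, 50.0, 0.0],
                          [10.0, 30.0, 60.0]],
                         index=["s1", "s2", "s3"],
                         columns=[100.0, 200.0, 300.0])
        out = fp.normalise(m)
        # s1: 0.1% entry removed then renormalised over 99.9
        np.testing.assert_allclose(out.loc["s1"],
                                   [80.0 / 99.9, 19.9 / 99.9, 0.0])
        np.testing.assert_allclose(out.loc["s2"], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(out.loc["s3"], [0.1, 0.3, 0.6])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(19)
        m = pd.DataFrame(rng.random((5, 12)) ** 3,
                         index=[f"s{i}" for i in range(5)],
                         columns=np.arange(12, dtype=float))
        out = fp.normalise(m)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_no_renormalise_flag(self):
        m = pd.DataFrame([[99.6, 0.4]], index=["s1"], columns=[100.0, 200.0])
        out = fp.normalise(m, renormalise=False)
        assert out.iloc[0, 0] == pytest.approx(0.996)

    def test_empty_sample_rejected(self):
        m = pd.DataFrame([[0.0, 0.0]], index=["s1"], columns=[100.0, 200.0])
        with pytest.raises(DataError, match="empty"):
            fp.normalise(m)


class TestBrayCurtis:
    def test_identical_samples_score_100(self):
        m = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]], index=["a", "b"])
        sim = fp.bray_curtis(m)
        assert sim.loc["a", "b"] == pytest.approx(100.0)

    def test_disjoint_samples_score_0(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert fp.bray_curtis(m).loc["a", "b"] == pytest.approx(0.0)

    def test_hand_example_is_50(self):
        """x=(0.5,0.5,0), y=(0.5,0,0.5): after sqrt the shared terms cancel
        symmetrically and the similarity is exactly 50%."""
        m = pd.DataFrame([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]], index=["x", "y"])
        assert fp.bray_curtis(m).loc["x", "y"] == pytest.approx(50.0)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(20)
        m = pd.DataFrame(rng.random((6, 9)), index=[f"s{i}" for i in range(6)])
        sim = fp.bray_curtis(m)
        np.testing.assert_allclose(sim, sim.T)
        np.testing.assert_allclose(np.diag(sim), 100.0)
        assert sim.to_numpy().min() >= 0.0
        assert sim.to_numpy().max() <= 100.0 + 1e-9


class TestDiversity:
    def test_equal_bins(self):
        m = pd.DataFrame([[0.25] * 4], index=["s1"])
        out = fp.diversity(m)
        assert out.loc["s1", "richness"] == 4
        assert out.loc["s1", "shannon"] == pytest.approx(np.log(4))
        assert out.loc["s1", "pielou"] == pytest.approx(1.0)

    def test_single_bin_flagged(self):
        m = pd.DataFrame([[1.0, 0.0]], index=["s1"])
        out = fp.diversity(m)
        assert out.loc["s1", "shannon"] == 0.0
        assert np.isnan(out.loc["s1", "pielou"])

    def test_direct_evaluation(self):
        m = pd.DataFrame([[0.5, 0.25, 0.25]], index=["s1"])
        h = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert fp.diversity(m).loc["s1", "shannon"] == pytest.approx(h)
        assert h == pytest.approx(1.0397, abs=1e-4)


class TestAnosim:
    def two_group_matrix(self, sep=1.0, n=4, seed=21):
        rng = np.random.default_rng(seed)
        base = rng.random(6) + 0.5
        rows = []
        for i in range(n):
            g = i >= n // 2
            rows.append(base + g * sep * np.arange(1, 7) + rng.normal(0, 0.01, 6))
        m = pd.DataFrame(np.abs(rows), index=[f"s{i}" for i in range(n)])
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        return fp.bray_curtis(m), labels

    def test_perfect_separation_gives_r_1(self):
        sim, labels = self.two_group_matrix(sep=5.0, n=8)
        res = fp.anosim(sim, labels, permutations=99, seed=0)
        assert res["R"] == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        """n=4 split 2+2: p from the exhaustive relabelling set matches an
        independent enumeration of all label permutations."""
        sim, labels = self.two_group_matrix(sep=5.0, n=4)
        res = fp.anosim(sim, labels, permutations="exhaustive")

        # independent oracle: enumerate permutations, recompute R from ranks
        d = 100.0 - sim.to_numpy()
        iu = np.triu_indices(4, k=1)
        ranks = rankdata(d[iu])

        def r_of(lab):
            lab = np.asarray(lab)
            within = lab[iu[0]] == lab[iu[1]]
            return (ranks[~within].mean() - ranks[within].mean()) / (4 * 3 / 4)

        perms = set(itertools.permutations(labels))
        r_obs = r_of(labels)
        p_oracle = sum(r_of(p) >= r_obs - 1e-12 for p in perms) / len(perms)
        assert res["p"] == pytest.approx(p_oracle)
        assert p_oracle == pytest.approx(1.0 / 3.0)  # 2 of 6 labellings tie R=1

    def test_r_bounded(self):
        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.random((8, 5)), index=[f"s{i}" for i in range(8)])
        sim = fp.bray_curtis(m)
        labels = np.array(["a", "b"] * 4)
        res = fp.anosim(sim, labels, permutations=199, seed=1)
        assert -1.0 <= res["R"] <= 1.0

    def test_matches_scikit_bio(self):
        """Independent cross-check of R against scikit-bio's ANOSIM."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(23)
        m = pd.DataFrame(rng.random((10, 8)),
                         index=[f"s{i}" for i in range(10)])
        sim = fp.bray_curtis(m)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        ours = fp.anosim(sim, labels, permutations=999, seed=2)
        dm = skbio.DistanceMatrix((100.0 - sim.to_numpy()) / 100.0,
                                  ids=list(sim.index))
        theirs = sk_anosim(dm, grouping=list(labels), permutations=999)
        assert ours["R"] == pytest.approx(theirs["test statistic"], abs=1e-9)
        assert ours["p"] == pytest.approx(theirs["p-value"], abs=0.05)

    def test_degenerate_grouping_rejected(self):
        sim, _ = self.two_group_matrix(n=4)
        with pytest.raises(DataError, match="groups"):
            fp.anosim(sim, ["a", "a", "a", "b"], permutations=9)


class TestSimper:
    def test_single_differing_bin_contributes_everything(self):
        m = pd.DataFrame([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0],
                          [0.5, 0.4, 0.1], [0.5, 0.4, 0.1]],
                         index=list("abcd"), columns=[1.0, 2.0, 3.0])
        res = fp.simper(m, ["g1", "g1", "g2", "g2"])
        contrib = res["contributions"]["contribution_pct"]
        assert contrib.sum() == pytest.approx(res["average_dissimilarity"])
        assert contrib.loc[1.0] == pytest.approx(0.0)

    def test_identical_groups_zero_dissimilarity(self):
        m = pd.DataFrame([[0.5, 0.5]] * 4, index=list("abcd"))
        res = fp.simper(m, ["g1", "g1", "g2", "g2"])
        assert res["average_dissimilarity"] == pytest.approx(0.0)
        assert res["within_group_similarity"]["g1"] == pytest.approx(100.0)

    def test_two_by_two_hand_expansion(self):
        m = pd.DataFrame([[0.8, 0.2], [0.6, 0.4],
                          [0.3, 0.7], [0.1, 0.9]],
                         index=list("abcd"), columns=[1.0, 2.0])
        labels = ["g1", "g1", "g2", "g2"]
        res = fp.simper(m, labels)
        x = np.sqrt(m.to_numpy())
        terms = np.zeros(2)
        for i in (0, 1):
            for j in (2, 3):
                denom = (x[i] + x[j]).sum()
                terms += 100.0 * np.abs(x[i] - x[j]) / denom
        terms /= 4.0
        np.testing.assert_allclose(
            res["contributions"]["contribution_pct"].sort_index(), terms,
            atol=1e-12)

    def test_contributions_sum_to_mean_between_group_dissimilarity(self):
        rng = np.random.default_rng(24)
        m = pd.DataFrame(rng.random((8, 10)),
                         index=[f"s{i}" for i in range(8)])
        m = m.div(m.sum(axis=1), axis=0)
        labels = np.array(["g1"] * 4 + ["g2"] * 4)
        res = fp.simper(m, labels)
        sim = fp.bray_curtis(m)
        between = []
        for i in range(4):
            for j in range(4, 8):
                between.append(100.0 - sim.iloc[i, j])
        assert res["contributions"]["contribution_pct"].sum() == \
            pytest.approx(np.mean(between), abs=1e-9)


class TestSimprof:
    def test_two_separated_groups_single_root_split(self):
        rng = np.random.default_rng(25)
        g1 = rng.dirichlet(np.r_[np.full(5, 5.0), np.full(5, 0.1)], size=5)
        g2 = rng.dirichlet(np.r_[np.full(5, 0.1), np.full(5, 5.0)], size=5)
        m = pd.DataFrame(np.vstack([g1, g2]),
                         index=[f"s{i}" for i in range(10)])
        res = fp.simprof_cluster(m, n_perm=1000, seed=3)
        sig = [n for n in res.nodes if n.significant]
        assert len(sig) == 1
        assert len(sig[0].samples) == 10  # the root
        assert "[&simprof=" in res.newick

    def test_root_rarely_significant_without_structure(self):
        """Type-I control: with exchangeable bins the root rejects in well
        under 10% of seeded runs at alpha = 0.05."""
        rng = np.random.default_rng(26)
        rejections = 0
        for i in range(40):
            m = pd.DataFrame(rng.lognormal(0, 1, size=(8, 12)),
                             index=[f"s{i}" for i in range(8)])
            res = fp.simprof_test(m, n_perm=1000,
                                  seed=int(rng.integers(2**31)))
            rejections += res["p"] < 0.05
        assert rejections <= 4  # 10% of 40

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame([[0.5, 0.5], [0.4, 0.6]], index=["a", "b"])
        with pytest.raises(DataError, match=">= 3"):
            fp.simprof_cluster(m, n_perm=100, seed=0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(27)
        m = pd.DataFrame(rng.random((6, 8)), index=[f"s{i}" for i in range(6)])
        r1 = fp.simprof_cluster(m, n_perm=500, seed=7)
        r2 = fp.simprof_cluster(m, n_perm=500, seed=7)
        assert r1.newick == r2.newick
        assert [(n.pi, n.p) for n in r1.nodes] == [(n.pi, n.p) for n in r2.nodes]


class TestCompareIndices:
    def test_equal_groups_p_one(self):
        idx = pd.DataFrame({"richness": [3, 4, 5, 6, 3, 4, 5, 6]},
                           dtype=float)
        out = fp.compare_indices(idx, ["a"] * 4 + ["b"] * 4)
        assert out.loc["richness", "p"] == pytest.approx(1.0)

    def test_balanced_equal_variance_df_is_pooled(self):
        idx = pd.DataFrame({"shannon": [1.0, 2, 3, 4, 5, 2.0, 3, 4, 5, 6]})
        out = fp.compare_indices(idx, ["a"] * 5 + ["b"] * 5)
        assert out.loc["shannon", "df"] == pytest.approx(8.0)

    def test_welch_satterthwaite_hand_formula(self):
        a = np.array([0.0, -1.0, 1.0, 0.5, -0.5])
        c = np.array([1.0, 0.2, 1.8, 2.4, -0.4, 1.0, 1.0])
        idx = pd.DataFrame({"v": np.concatenate([a, c])})
        out = fp.compare_indices(idx, ["a"] * 5 + ["c"] * 7)
        va, vc = a.var(ddof=1) / 5, c.var(ddof=1) / 7
        df = (va + vc) ** 2 / (va ** 2 / 4 + vc ** 2 / 6)
        assert out.loc["v", "df"] == pytest.approx(df)


class TestLocalSouthern:
    def standards(self):
        # migration m(L) follows the reciprocal model exactly
        c, m0, l0 = 5000.0, 2.0, 10.0
        sizes = np.array([50.0, 100, 150, 200, 300, 400, 500])
        migs = m0 + c / (sizes - l0)
        return list(zip(migs, sizes)), (c, m0, l0)

    def test_recovers_model_generated_sizes(self):
        std, (c, m0, l0) = self.standards()
        queries_l = np.array([120.0, 260.0, 340.0])
        queries_m = m0 + c / (queries_l - l0)
        out = b.size_fragments_local_southern(queries_m, std)
        np.testing.assert_allclose(out, queries_l, atol=0.01)

    def test_query_at_standard_returns_its_size(self):
        std, _ = self.standards()
        migs = [m for m, _ in sorted(std)]
        out = b.size_fragments_local_southern([migs[3]], std)
        sizes_sorted = [s for _, s in sorted(std)]
        assert out[0] == pytest.approx(sizes_sorted[3], abs=1e-6)

    def test_unbracketed_query_rejected(self):
        std, (c, m0, l0) = self.standards()
        with pytest.raises(DataError, match="bracketed"):
            b.size_fragments_local_southern([m0 + c / (40.0 - l0)], std)
        with pytest.raises(DataError, match="standard"):
            b.size_fragments_local_southern([5.0], std[:3])


def test_peak_table_round_trip(tmp_path):
    profiles, _ = b.generate_fingerprint_dataset(
        b.FingerprintParams(samples_per_group=2), seed=28)
    path = tmp_path / "peaks.tsv"
    fp.write_peak_table(profiles, path)
    back = fp.read_peak_table(path)
    assert [p.sample_id for p in back] == sorted(p.sample_id for p in profiles)
    orig = {p.sample_id: p for p in profiles}
    for p in back:
        np.testing.assert_allclose(
            np.sort(p.peaks["size_nt"]), np.sort(orig[p.sample_id].peaks["size_nt"]))
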