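"""Cluster permutation statistics: t-test, mixed ANOVA, post hoc tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from silenttrack.clusterstats import (_paired_t, chain_adjacency,
                                      cluster_perm_mixed_anova,
                                      cluster_perm_ttest,
                                      grid_product_adjacency, point_anova,
                                      posthoc_tests)

# Worked mixed-design dataset: 6 subjects x 2 modalities, 3 groups of 2.
WORKED_Y = np.array([[4.0, 2.0], [6.0, 3.0],      # group a: d = 2, 3
                     [5.0, 1.0], [7.0, 4.0],      # group b: d = 4, 3
                     [3.0, 2.0], [5.0, 3.0]])     # group c: d = 1, 2
WORKED_GROUPS = np.array(["a", "a", "b", "b", "c", "c"])


def worked_anova_oracle():
    """Hand-computed split-plot sums of squares for WORKED_Y."""
    y = WORKED_Y
    s = y.mean(axis=1)                      # [3, 4.5, 3, 5.5, 2.5, 4]
    d = y[:, 0] - y[:, 1]                   # [2, 3, 4, 3, 1, 2]
    mu = s.mean()                           # 45/12
    gmeans = np.array([s[:2].mean(), s[2:4].mean(), s[4:].mean()])
    ss_group = 2 * 2 * np.sum((gmeans - mu) ** 2)
    ss_subj = 2 * np.sum((s - np.repeat(gmeans, 2)) ** 2)
    dbar = d.mean()                         # 15/6
    dbar_g = np.array([2.5, 3.5, 1.5])
    ss_mod = 6 * dbar ** 2 / 2
    ss_int = np.sum(2 * (dbar_g - dbar) ** 2) / 2
    ss_ew = np.sum((d - np.repeat(dbar_g, 2)) ** 2) / 2
    return {
        "group": (ss_group / 2) / (ss_subj / 3),
        "modality": ss_mod / (ss_ew / 3),
        "interaction": (ss_int / 2) / (ss_ew / 3),
    }


class TestClusterPermTtest:
    def test_single_bin_matches_exact_enumeration(self):
        """On one bin the cluster test must reduce to an exact paired
        permutation test (all 2^n sign flips)."""
        rng = np.random.default_rng(5)
        d = rng.normal(0.9, 1.0, size=(10, 1))
        t_obs = _paired_t(d, np.ones((1, 10)))[0][0]
        null = np.array([
            abs(_paired_t(d, np.array([signs], float))[0][0])
            for signs in itertools.product([-1, 1], repeat=10)])
        p_exact = np.mean(null >= abs(t_obs))
        res = cluster_perm_ttest(d, cluster_alpha=0.05, n_perm=4000, seed=0)
        assert len(res.clusters) == 1
        assert res.clusters[0].p == pytest.approx(p_exact, abs=0.02)

    def test_effect_cluster_found_in_right_bins(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(14, 2, 30))
        data[:, 0, 10:16] += 1.0
        res = cluster_perm_ttest(data, n_perm=500, seed=1)
        sig = res.significant(0.05)
        assert sig and sig[0].sign == 1
        assert set(sig[0].members) <= set(range(9, 17))

    def test_matches_mne_implementation(self):
        """Independent toolbox oracle: same clusters, close p-values."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(3)
        d = rng.normal(0, 1, size=(14, 30))
        d[:, 10:16] += 0.9
        thr = stats.t.ppf(1 - 0.01 / 2, df=13)
        _, clusters, pv, _ = mne_stats.permutation_cluster_1samp_test(
            d, threshold=thr, n_permutations=2000, tail=0, adjacency=None,
            out_type="indices", seed=1, verbose=False)
        res = cluster_perm_ttest(d, cluster_alpha=0.01, n_perm=2000, seed=2)
        ours = sorted((c.members.min(), c.members.max())
                      for c in res.clusters)
        mne_sets = sorted((int(c[0].min()), int(c[0].max()))
                          for c in clusters)
        assert ours == mne_sets
        for (lo, hi), p_mne in zip(mne_sets, pv):
            ours_p = [c.p for c in res.clusters
                      if (c.members.min(), c.members.max()) == (lo, hi)]
            assert ours_p[0] == pytest.approx(p_mne, abs=0.01)

    def test_minimum_p_includes_observed(self):
        data = np.tile([[1.0], [1.1], [0.9], [1.05]], (1, 1))
        res = cluster_perm_ttest(data.reshape(4, 1), n_perm=200, seed=0)
        assert all(c.p >= 1 / 201 for c in res.clusters)

    def test_seeded_determinism(self):
        data = np.random.default_rng(9).normal(size=(12, 2, 20))
        a = cluster_perm_ttest(data, n_perm=300, seed=4)
        b = cluster_perm_ttest(data, n_perm=300, seed=4)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]

    def test_spatial_adjacency_keeps_channels_apart(self):
        """With a freq x channel grid, suprathreshold bins on neighbouring
        channels merge only through the spatial graph."""
        rng = np.random.default_rng(8)
        n_freq, n_ch = 10, 3
        data = rng.normal(size=(14, n_freq * n_ch))
        data[:, 2:5] += 1.5            # channel 0, bins 2-4
        data[:, n_freq + 2:n_freq + 5] += 1.5  # channel 1, same bins
        adj = grid_product_adjacency(n_freq, n_space=n_ch)
        res = cluster_perm_ttest(data, adjacency=adj, n_perm=300, seed=0)
        big = max(res.clusters, key=lambda c: c.mass)
        # the two channel-wise blobs are adjacent through the channel graph
        assert {m // n_freq for m in big.members} == {0, 1}

    def test_too_few_subjects_and_warning(self):
        with pytest.raises(ValueError):
            cluster_perm_ttest(np.zeros((1, 2, 5)))
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_perm_ttest(np.random.default_rng(0)
                               .normal(size=(6, 2, 5)), n_perm=50, seed=0)


class TestMixedAnova:
    def test_worked_dataset_matches_hand_computation(self):
        oracle = worked_anova_oracle()
        res = point_anova(WORKED_Y, WORKED_GROUPS)
        for eff in ("group", "modality", "interaction"):
            assert res.effects[eff]["F"] == pytest.approx(oracle[eff])
        assert res.effects["group"]["dfn"] == 2
        assert res.effects["group"]["dfd"] == 3
        assert res.effects["modality"]["dfn"] == 1

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(42)
        y = rng.normal(size=(12, 2))
        groups = np.repeat(["a", "b", "c"], 4)
        res = point_anova(y, groups)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(12), 2),
            "mod": ["m0", "m1"] * 12,
            "grp": np.repeat(groups, 2),
            "y": y.ravel()})
        tab = pg.mixed_anova(df, dv="y", within="mod", subject="subj",
                             between="grp")
        by = {"grp": "group", "mod": "modality",
              "Interaction": "interaction"}
        for src, eff in by.items():
            f_pg = float(tab.loc[tab.Source == src, "F"].iloc[0])
            assert res.effects[eff]["F"] == pytest.approx(f_pg, rel=1e-9)

    def test_cluster_version_shares_f_with_point(self):
        res_c = cluster_perm_mixed_anova(WORKED_Y[:, :, None],
                                         WORKED_GROUPS, n_perm=100, seed=0)
        res_p = point_anova(WORKED_Y, WORKED_GROUPS)
        for eff in ("group", "modality", "interaction"):
            assert res_c.effects[eff]["F"][0] == pytest.approx(
                res_p.effects[eff]["F"])

    def test_identical_modalities_zero_modality_f(self):
        y = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 2))
        res = point_anova(y, WORKED_GROUPS)
        assert res.effects["modality"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_group_shift_detected_at_large_n(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(60, 2))
        groups = np.repeat(["a", "b", "c"], 20)
        y[40:] += 1.0  # group c shifted
        res = point_anova(y, groups)
        assert res.effects["group"]["p"] < 0.01

    def test_group_effect_cluster_detected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(24, 2, 30))
        groups = np.repeat(["a", "b", "c"], 8)
        y[16:, :, 5:12] += 0.8
        res = cluster_perm_mixed_anova(y, groups, n_perm=300, seed=0)
        sig = res.effects["group"]["result"].significant(0.05)
        assert sig
        assert set(sig[0].members) & set(range(5, 12))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            point_anova(WORKED_Y, np.array(["a"] * 5 + ["b"]))


class TestPosthoc:
    def test_identical_samples_null(self):
        y = np.tile([[1.0, 1.0]], (6, 1))
        with pytest.warns(UserWarning, match="zero-variance"):
            tab = posthoc_tests(y, WORKED_GROUPS)
        row = tab[tab.variant == "paired"].iloc[0]
        assert row.t == 0.0 and row.p == 1.0

    def test_welch_matches_satterthwaite_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        vx, vz = x.var(ddof=1), z.var(ddof=1)
        nx, nz = len(x), len(z)
        t_hand = (x.mean() - z.mean()) / np.sqrt(vx / nx + vz / nz)
        df_hand = (vx / nx + vz / nz) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vz / nz) ** 2 / (nz - 1))
        y = np.zeros((9, 2))
        y[:, 0] = np.concatenate([x, z])
        y[:, 1] = y[:, 0]  # degenerate second modality, ignored here
        groups = np.array(["a"] * 4 + ["b"] * 5)
        tab = posthoc_tests(y, groups, modality_names=("m0", "m1"))
        row = tab[(tab.comparison == "a vs b")
                  & (tab.variant == "welch")].iloc[0]
        assert row.t == pytest.approx(t_hand)
        assert row.df == pytest.approx(df_hand)

    def test_equal_variance_equal_n_df_limit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        z = x + 0.01 * rng.normal(size=10)  # near-identical spread
        y = np.zeros((20, 2))
        y[:, 0] = np.concatenate([x, z])
        y[:, 1] = y[:, 0] + rng.normal(size=20)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        tab = posthoc_tests(y, groups)
        row = tab[(tab.comparison == "a vs b")
                  & (tab.variant == "welch")].iloc[0]
        assert row.df == pytest.approx(18, abs=0.5)
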