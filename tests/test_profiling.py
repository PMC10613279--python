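import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibscluster import (cliffs_delta, cluster_z_profiles, conover_posthoc_holm,
                        holm_adjust, kruskal_wallis_epsilon2,
                        mwu_cliffs_one_vs_rest, qualitative_labels,
                        radar_export, radar_records, run_battery)
from ibscluster.profiling import ClusterProfile, TestResults

from conftest import toy_mixed


class TestKruskalWallis:
    def test_three_group_hand_example(self):
        # ranks are 1..9 with no ties: H = 7.2, eps2 = 7.2/8 = 0.9
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        H, p, eps2 = kruskal_wallis_epsilon2(values, groups)
        assert H == pytest.approx(7.2)
        assert eps2 == pytest.approx(0.9)

    def test_matches_reference_implementation_with_ties(self):
        rng = np.random.default_rng(0)
        values = rng.integers(0, 5, 60).astype(float)
        groups = rng.integers(0, 3, 60)
        H, p, _ = kruskal_wallis_epsilon2(values, groups)
        ref = stats.kruskal(*[values[groups == g] for g in range(3)])
        assert H == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_epsilon_squared_near_zero(self):
        # nine groups from one distribution: eps2 < 0.05 across seeds
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=900)
            groups = np.repeat(np.arange(9), 100)
            _, _, eps2 = kruskal_wallis_epsilon2(values, groups)
            assert eps2 < 0.05

    def test_constant_values_give_zero(self):
        H, p, eps2 = kruskal_wallis_epsilon2([5.0] * 12, [0, 1, 2] * 4)
        assert H == 0.0 and eps2 == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_epsilon2([1, 2, 3], [0, 0, 0])


def conover_oracle(values, groups):
    """Direct transcription of the Conover-Iman statistic, via explicit loops."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    uniq = sorted(set(groups))
    k = len(uniq)
    H = stats.kruskal(*[values[groups == g] for g in uniq]).statistic
    S2 = (sum(r * r for r in ranks) - n * (n + 1) ** 2 / 4) / (n - 1)
    out = {}
    for a, b in itertools.combinations(uniq, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        se = np.sqrt(S2 * (n - 1 - H) / (n - k) * (1 / len(ra) + 1 / len(rb)))
        t = (ra.mean() - rb.mean()) / se
        out[(a, b)] = (t, 2 * stats.t.sf(abs(t), n - k))
    return out


class TestConoverHolm:
    def test_two_groups_holm_is_identity(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        groups = np.repeat([0, 1], 10)
        table = conover_posthoc_holm(values, groups)
        assert len(table) == 1
        assert table["p_holm"].iloc[0] == pytest.approx(table["p_raw"].iloc[0])

    def test_holm_stepdown_arithmetic(self):
        adj = holm_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_holm_monotone_in_sorted_raw_order(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 12)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 6, 30).astype(float)
        groups = rng.integers(0, 3, 30)
        table = conover_posthoc_holm(values, groups).set_index(
            ["group_a", "group_b"])
        oracle = conover_oracle(values, groups)
        for (a, b), (t, p) in oracle.items():
            assert table.loc[(a, b), "statistic"] == pytest.approx(t, abs=1e-8)
            assert table.loc[(a, b), "p_raw"] == pytest.approx(p, abs=1e-8)


def delta_oracle(a, b):
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


class TestMWUCliffs:
    def test_hand_example(self):
        # cluster [1,2,3] vs rest [2,3,4]: delta = (1 - 6)/9
        assert cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    def test_complete_dominance(self):
        assert cliffs_delta([10, 11], [1, 2, 3]) == 1.0

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 5, 17).astype(float)
        b = rng.integers(0, 5, 23).astype(float)
        assert cliffs_delta(a, b) == pytest.approx(delta_oracle(a, b), abs=1e-12)

    def test_no_tie_identity_with_u(self):
        rng = np.random.default_rng(5)
        a = rng.permutation(40)[:15].astype(float)
        b = np.asarray(sorted(set(range(100)) - set(a.astype(int))))[:20] + 0.5
        u = sum(1 for x in a for y in b if x > y)
        assert cliffs_delta(a, b) == pytest.approx(2 * u / (15 * 20) - 1)

    def test_one_vs_rest_table(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=60)
        labels = rng.integers(0, 3, 60)
        table = mwu_cliffs_one_vs_rest(values, labels).set_index("cluster")
        for c in range(3):
            a, b = values[labels == c], values[labels != c]
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
            assert table.loc[c, "U"] == pytest.approx(ref.statistic)
            assert table.loc[c, "p"] == pytest.approx(ref.pvalue, abs=1e-12)
            assert table.loc[c, "delta"] == pytest.approx(delta_oracle(a, b))


class TestZProfiles:
    def test_formula_and_zero_cases(self, toy_mixed_factory):
        data = toy_mixed_factory(60, seed=7)
        labels = np.zeros(60, dtype=int)
        prof = cluster_z_profiles(data, labels)
        assert np.allclose(prof.z.to_numpy(float), 0.0)  # whole-cohort cluster

    def test_hand_value(self):
        from ibscluster import MixedDataMatrix, VariableSchema

        schema = [VariableSchema("C", "c", "continuous", range=(0, 100))]
        x = np.array([13.0, 13.0, 10.0, 10.0, 7.0, 7.0])
        frame = pd.DataFrame({"C": x})
        data = MixedDataMatrix(schema=schema, frame=frame)
        labels = np.array([1, 1, 0, 0, 0, 0])
        prof = cluster_z_profiles(data, labels)
        sd = x.std(ddof=1)
        assert prof.z.loc[1, "C"] == pytest.approx((13 - 10) / sd)

    def test_size_weighted_mean_z_is_zero(self, toy_mixed_factory):
        data = toy_mixed_factory(80, seed=8)
        labels = np.random.default_rng(0).integers(0, 4, 80)
        prof = cluster_z_profiles(data, labels)
        sizes = prof.cluster_sizes.reindex(prof.z.index).to_numpy(float)
        weighted = (prof.z.to_numpy(float) * sizes[:, None]).sum(axis=0)
        assert np.allclose(weighted, 0.0, atol=1e-8)


def profile_with(z_value, p, delta):
    z = pd.DataFrame({"V": [z_value]}, index=pd.Index([0], name="cluster"))
    q = z.copy().astype(str)
    prof = ClusterProfile(z=z, qualitative=q,
                          population_mean=pd.Series({"V": 0.0}),
                          population_sd=pd.Series({"V": 1.0}),
                          cluster_sizes=pd.Series({0: 10}))
    ovr = pd.DataFrame({"code": ["V"], "cluster": [0], "U": [0.0],
                        "p": [p], "delta": [delta]})
    tests = TestResults(kruskal=pd.DataFrame(), conover=pd.DataFrame(),
                        one_vs_rest=ovr)
    return qualitative_labels(prof, tests).loc[0, "V"]


class TestQualitativeRule:
    @pytest.mark.parametrize("z,p,delta,expected", [
        (0.6, 0.5, 0.0, "high"),            # > 0.5 sigma from the centre
        (0.3, 1e-4, 0.35, "high"),          # significant with large delta
        (-0.2, 0.5, 0.0, "low"),            # inside the central circle
        (0.3, 0.01, 0.1, "moderate"),       # in between
        (0.3, 1e-4, 0.2, "moderate"),       # significant but small delta
        (0.0, 0.5, 0.0, "low"),             # boundary: at the mean is low
    ])
    def test_rule(self, z, p, delta, expected):
        assert profile_with(z, p, delta) == expected


class TestRadar:
    def test_record_count_and_roundtrip(self, toy_mixed_factory, tmp_path):
        data = toy_mixed_factory(90, seed=9)
        labels = np.random.default_rng(1).integers(0, 3, 90)
        prof = cluster_z_profiles(data, labels)
        tests = run_battery(data, labels)
        qualitative_labels(prof, tests)
        records = radar_records(prof)
        assert len(records) == 3 * data.n_variables
        paths = radar_export(prof, tmp_path / "radar.csv")
        back = pd.read_csv(paths["records"])
        assert np.allclose(back["z"], records["z"])
        assert (back["label"] == records["label"]).all()
        circles = pd.read_csv(paths["circles"])
        assert np.allclose(np.diff(circles["z"]), 0.5)
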