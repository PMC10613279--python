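import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ibscluster import (MixedDataMatrix, VariableSchema, dependency_weights,
                        fit_distributions, pairwise_distance_matrix,
                        per_variable_distance)
from ibscluster.distance import DependencyWeights

from conftest import LIKERT, toy_mixed


def ordinal_matrix(counts, seed=0):
    """Matrix with one ordinal column realising the given level counts."""
    values = np.repeat(np.arange(len(counts)), counts)
    schema = [VariableSchema("O", "item", "ordinal", levels=LIKERT)]
    frame = pd.DataFrame({"O": values}, index=pd.RangeIndex(len(values)))
    return MixedDataMatrix(schema=schema, frame=frame)


class TestDistributions:
    def test_ordinal_frequencies_and_cdf(self):
        data = ordinal_matrix((40, 30, 20, 10))
        dist = fit_distributions(data)[0]
        assert np.allclose(dist.frequencies, (0.4, 0.3, 0.2, 0.1))
        assert np.allclose(dist.cdf, (0.4, 0.7, 0.9, 1.0))

    def test_constant_variable_flagged_degenerate(self):
        data = ordinal_matrix((5, 0, 0, 0))
        dist = fit_distributions(data)[0]
        assert dist.degenerate
        assert dist.frequencies[0] == 1.0

    def test_continuous_records_observed_and_schema_range(self):
        schema = [VariableSchema("C", "c", "continuous", range=(0, 21))]
        frame = pd.DataFrame({"C": [3.0, 10.0, 18.0]})
        data = MixedDataMatrix(schema=schema, frame=frame)
        dist = fit_distributions(data)[0]
        assert dist.schema_range == (0, 21)
        assert dist.observed_range == (3.0, 18.0)


class TestPerVariableDistance:
    def test_ordinal_cdf_distance_hand_values(self):
        dist = fit_distributions(ordinal_matrix((40, 30, 20, 10)))[0]
        # extremes at distance 1; middle levels at 0.2/0.6
        assert per_variable_distance(0, 3, dist) == pytest.approx(1.0)
        assert per_variable_distance(1, 2, dist) == pytest.approx(0.2 / 0.6)

    @pytest.mark.parametrize("kind,a", [("ordinal", 2), ("continuous", 7.3)])
    def test_identity_is_zero(self, kind, a):
        if kind == "ordinal":
            dist = fit_distributions(ordinal_matrix((10, 10, 10, 10)))[0]
        else:
            schema = [VariableSchema("C", "c", "continuous", range=(0, 21))]
            frame = pd.DataFrame({"C": [1.0, 2.0]})
            dist = fit_distributions(MixedDataMatrix(schema=schema, frame=frame))[0]
        assert per_variable_distance(a, a, dist) == 0.0

    def test_continuous_range_normalised(self):
        schema = [VariableSchema("C", "c", "continuous", range=(0, 21))]
        frame = pd.DataFrame({"C": [7.0, 14.0]})
        dist = fit_distributions(MixedDataMatrix(schema=schema, frame=frame))[0]
        assert per_variable_distance(7.0, 14.0, dist) == pytest.approx(7 / 21)


def naive_distance_matrix(data, weights):
    """Brute-force double-loop oracle for the weighted mixed distance."""
    dists = fit_distributions(data)
    n, p = data.n_samples, data.n_variables
    w = np.asarray(weights, float)
    out = np.zeros((n, n))
    vals = data.frame.to_numpy()
    for i in range(n):
        for k in range(n):
            acc = sum(w[j] * per_variable_distance(vals[i, j], vals[k, j], dists[j])
                      for j in range(p))
            out[i, k] = acc / w.sum()
    return out


class TestPairwiseMatrix:
    def test_matches_double_loop_oracle(self):
        data = toy_mixed(20, seed=3, p_ord=3, p_cont=2)
        D = pairwise_distance_matrix(data)
        oracle = naive_distance_matrix(data, np.ones(5))
        np.fill_diagonal(oracle, 0.0)
        assert np.allclose(D.values, oracle, atol=1e-8)

    def test_identical_rows_distance_zero(self):
        data = toy_mixed(4, seed=1)
        dup = data.frame.copy()
        dup.iloc[1] = dup.iloc[0]
        data2 = MixedDataMatrix(schema=data.schema, frame=dup)
        D = pairwise_distance_matrix(data2)
        assert D.values[0, 1] == pytest.approx(0.0)

    def test_maximally_different_rows_distance_one(self):
        schema = [VariableSchema("O", "o", "ordinal", levels=LIKERT),
                  VariableSchema("C", "c", "continuous", range=(0, 1))]
        frame = pd.DataFrame({"O": [0, 3, 0, 3], "C": [0.0, 1.0, 0.0, 1.0]})
        data = MixedDataMatrix(schema=schema, frame=frame)
        D = pairwise_distance_matrix(data)
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_metric_axioms_and_bounds(self):
        data = toy_mixed(15, seed=9)
        D = pairwise_distance_matrix(data).values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert D.min() >= 0 and D.max() <= 1

    def test_variable_permutation_leaves_distances_unchanged(self):
        data = toy_mixed(12, seed=5)
        perm = [3, 1, 4, 0, 2]
        data_p = MixedDataMatrix(schema=[data.schema[j] for j in perm],
                                 frame=data.frame.iloc[:, perm])
        assert np.allclose(pairwise_distance_matrix(data).values,
                           pairwise_distance_matrix(data_p).values)

    def test_sample_permutation_permutes_distances(self):
        data = toy_mixed(10, seed=6)
        perm = np.random.default_rng(0).permutation(10)
        D = pairwise_distance_matrix(data).values
        Dp = pairwise_distance_matrix(data.subset(perm)).values
        assert np.allclose(Dp, D[np.ix_(perm, perm)])

    def test_single_continuous_variable_reduces_to_range_scaled_difference(self):
        schema = [VariableSchema("C", "c", "continuous", range=(0, 10))]
        x = np.array([0.0, 2.5, 9.0])
        data = MixedDataMatrix(schema=schema,
                               frame=pd.DataFrame({"C": x}))
        D = pairwise_distance_matrix(data).values
        assert np.allclose(D, np.abs(x[:, None] - x[None, :]) / 10)

    def test_weight_rescaling_invariance(self):
        data = toy_mixed(10, seed=2)
        w = dependency_weights(data)
        D1 = pairwise_distance_matrix(data, weights=w)
        w2 = DependencyWeights(w.codes, 7.5 * w.weights, w.nmi)
        D2 = pairwise_distance_matrix(data, weights=w2)
        assert np.allclose(D1.values, D2.values)


def entropy_oracle(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return -(p * np.log(p)).sum()


class TestDependencyWeights:
    def test_independent_variables_have_unit_weights(self):
        data = toy_mixed(5000, seed=11, p_ord=3, p_cont=2)
        w = dependency_weights(data)
        assert np.all(np.abs(w.weights - 1.0) < 0.05)

    def test_duplicated_variable_dominates(self):
        data = toy_mixed(200, seed=4, p_ord=2, p_cont=1)
        frame = data.frame.copy()
        frame["O9"] = frame["O0"]
        schema = data.schema + [VariableSchema("O9", "dup", "ordinal",
                                               levels=LIKERT)]
        dup = MixedDataMatrix(schema=schema, frame=frame)
        w = dependency_weights(dup)
        nmi = w.nmi
        assert nmi.loc["O0", "O9"] == pytest.approx(1.0)
        top2 = set(w.as_series().nlargest(2).index)
        assert top2 == {"O0", "O9"}

    def test_nmi_against_entropy_oracle(self):
        data = toy_mixed(60, seed=8, p_ord=2, p_cont=0)
        w = dependency_weights(data)
        a = data.frame["O0"].to_numpy()
        b = data.frame["O1"].to_numpy()
        ha = entropy_oracle(np.bincount(a))
        hb = entropy_oracle(np.bincount(b))
        joint = np.zeros((4, 4))
        for x, y in zip(a, b):
            joint[x, y] += 1
        hj = entropy_oracle(joint.ravel())
        nmi = (ha + hb - hj) / np.sqrt(ha * hb)
        assert w.nmi.loc["O0", "O1"] == pytest.approx(nmi, abs=1e-10)

    def test_constant_variable_gets_zero_nmi(self):
        data = toy_mixed(50, seed=13, p_ord=2, p_cont=0)
        frame = data.frame.copy()
        frame["K"] = 1
        schema = data.schema + [VariableSchema("K", "const", "ordinal",
                                               levels=LIKERT)]
        aug = MixedDataMatrix(schema=schema, frame=frame)
        w = dependency_weights(aug)
        assert np.all(w.nmi.loc["K", ["O0", "O1"]] == 0)

    def test_single_variable_weights_all_one(self):
        data = toy_mixed(10, seed=1, p_ord=1, p_cont=0)
        w = dependency_weights(data)
        assert np.allclose(w.weights, 1.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=10**6))
def test_distance_bounds_property(n, seed):
    """Random small tables always yield symmetric distances within [0, 1]."""
    data = toy_mixed(n, seed=seed, p_ord=2, p_cont=1)
    D = pairwise_distance_matrix(data)
    D.check()
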