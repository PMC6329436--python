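"""Phi coefficient, group detection, and severity-correlation behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from missig.exploratory import (
    ConstantVectorError,
    find_groups,
    indicator_outcome_association,
    missingness_rates,
    phi,
    phi_matrix,
    spearman_missing_vs_severity,
)


class TestPhi:
    def test_perfect_agreement(self):
        a = np.array([1, 1, 0, 0])
        assert phi(a, a) == 1.0

    def test_independence_table(self):
        assert phi([1, 1, 0, 0], [1, 0, 1, 0]) == 0.0

    def test_perfect_disagreement(self):
        assert phi([1, 1, 0, 0], [0, 0, 1, 1]) == -1.0

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantVectorError):
            phi([1, 1, 1], [0, 1, 0])

    def test_equals_pearson_on_random_tables(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(4, 40))
            a = rng.random(n) < rng.uniform(0.2, 0.8)
            b = rng.random(n) < rng.uniform(0.2, 0.8)
            if a.all() or (~a).any() == 0 or len(set(a)) < 2 or len(set(b)) < 2:
                continue
            pearson = np.corrcoef(a.astype(float), b.astype(float))[0, 1]
            assert phi(a, b) == pytest.approx(pearson, abs=1e-12)
            checked += 1

    @given(st.lists(st.booleans(), min_size=4, max_size=30), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_flip_invariance(self, a_list, data):
        a = np.array(a_list)
        b = np.array(data.draw(
            st.lists(st.booleans(), min_size=len(a), max_size=len(a))
        ))
        if len(set(a)) < 2 or len(set(b)) < 2:
            return
        assert phi(a, b) == pytest.approx(phi(b, a), abs=1e-14)
        assert phi(~a, ~b) == pytest.approx(phi(a, b), abs=1e-14)


class TestPhiMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        ind = pd.DataFrame((rng.random((50, 4)) < 0.4).astype(int),
                           columns=list("ABCD"))
        M = phi_matrix(ind)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)

    def test_constant_column_flagged_nan_not_zero(self):
        ind = pd.DataFrame({"A": [0, 0, 0, 0], "B": [0, 1, 0, 1]})
        M = phi_matrix(ind)
        assert np.isnan(M.loc["A", "B"])
        assert np.isnan(M.loc["A", "A"])
        assert M.loc["B", "B"] == 1.0


class TestFindGroups:
    def _matrix(self, names, entries):
        names = list(names)
        M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, v in entries:
            M.loc[a, b] = M.loc[b, a] = v
        return M

    def test_connected_component_not_clique(self):
        M = self._matrix("ABCD", [("A", "B", 0.96), ("B", "C", 0.96), ("A", "C", 0.5)])
        assert find_groups(M, 0.95) == [["A", "B", "C"]]

    def test_threshold_one_with_no_perfect_pairs(self):
        M = self._matrix("ABC", [("A", "B", 0.99)])
        assert find_groups(M, 1.0) == []

    def test_invariant_to_column_order(self):
        M = self._matrix("ABCD", [("A", "B", 0.97), ("C", "D", 0.98)])
        perm = ["C", "A", "D", "B"]
        assert find_groups(M, 0.95) == find_groups(M.loc[perm, perm], 0.95)

    def test_invalid_threshold_rejected(self):
        M = self._matrix("AB", [])
        with pytest.raises(ValueError, match="threshold"):
            find_groups(M, 0.0)


class TestRatesAndCorrelations:
    def test_rates_are_column_means(self):
        ind = pd.DataFrame({"A": [0, 0, 0, 0], "B": [1, 1, 1, 0]})
        rates = missingness_rates(ind)
        assert rates["A"] == 0.0
        assert rates["B"] == 0.75

    def test_spearman_perfect_when_severity_equals_counts(self):
        rng = np.random.default_rng(2)
        ind = pd.DataFrame((rng.random((40, 6)) < 0.5).astype(int))
        sev = ind.sum(axis=1).astype(float)
        rho, p = spearman_missing_vs_severity(ind, sev)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        ind = pd.DataFrame((rng.random((60, 6)) < 0.5).astype(int))
        sev = pd.Series(rng.standard_normal(60))
        rho1, _ = spearman_missing_vs_severity(ind, sev)
        rho2, _ = spearman_missing_vs_severity(ind, np.exp(3 * sev))
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_spearman_needs_variation(self):
        ind = pd.DataFrame(np.zeros((12, 3), dtype=int))
        with pytest.raises(ConstantVectorError):
            spearman_missing_vs_severity(ind, pd.Series(np.ones(12)))

    def test_indicator_identical_to_outcome_scores_one(self):
        y = pd.Series([1, 0, 1, 0, 1, 0])
        ind = pd.DataFrame({"I-A": y.to_numpy(), "I-B": [0, 0, 0, 0, 0, 0]})
        assoc = indicator_outcome_association(ind, y)
        assert assoc["I-A"] == 1.0
        assert np.isnan(assoc["I-B"])  # constant column flagged undefined

    def test_constant_outcome_rejected(self):
        ind = pd.DataFrame({"I-A": [0, 1, 0, 1]})
        with pytest.raises(ConstantVectorError):
            indicator_outcome_association(ind, pd.Series([1, 1, 1, 1]))


def test_mechanism_isolation_puts_liver_indicators_on_top(schema):
    """When only the liver panel's ordering is severity-linked, the liver
    indicators carry the largest outcome associations."""
    from missig.representation import build_indicator_matrix
    from missig.simulate import SimulationConfig, generate_cohort

    sim = SimulationConfig(n_patients=4000, delta={"liver": 1.5})
    cohort = generate_cohort(schema, sim, seed=17)
    ind = build_indicator_matrix(cohort.day(1).values)
    y = cohort.day(1).outcomes["in_hospital"]
    assoc = indicator_outcome_association(ind, y).abs().dropna()
    liver = [c for c in assoc.index if c[2:] in schema.panels["liver"]]
    non_liver = [c for c in assoc.index if c not in liver]
    assert assoc[liver].min() > assoc[non_liver].max()
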