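"""Differential time vectors, lagged cross-correlation, and sub-pathway extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from pertpath.subpathway import (
    DifferentialTimeVector,
    EdgeValidation,
    PathwayGraph,
    PerturbedSubpathway,
    bh_fdr,
    build_time_vectors,
    cross_correlation,
    extract_subpathways,
    moderated_t_deg,
    permutation_pvalue,
    propagation_delay,
    squeeze_variances,
    validate_edges,
)


def brute_force_delay(v1, v2):
    """Independent enumeration of the lagged inner product with the same tie rule."""
    v1, v2 = np.asarray(v1), np.asarray(v2)
    T = len(v1)
    vals = {}
    for n in range(-(T - 1), T):
        s = 0
        for t in range(1, T + 1):  # 1-based time, zero outside 1..T
            if 1 <= t + n <= T:
                s += v1[t - 1] * v2[t + n - 1]
        vals[n] = s
    peak = max(vals.values())
    candidates = [n for n, v in vals.items() if v == peak]
    best = max(candidates, key=lambda n: (abs(n), n >= 0))
    return best, peak


class TestModeratedT:
    def test_null_data_gives_no_calls(self):
        rng = np.random.default_rng(0)
        x = rng.normal(8, 0.5, size=(50, 3))
        assert (moderated_t_deg(x, x.copy()) == 0).all()

    def test_separated_means_called_up(self):
        rng = np.random.default_rng(1)
        control = rng.normal(8, 0.01, size=(20, 3))
        treated = control.copy()
        treated[5] += 10
        calls = moderated_t_deg(control, treated, lfc_cutoff=1.0, p_cutoff=0.05)
        assert calls[5] == 1
        assert (np.delete(calls, 5) == 0).all()
        down = moderated_t_deg(treated, control)
        assert down[5] == -1

    def test_single_replicate_falls_back_to_fold_change(self):
        control = np.array([[1.0], [1.0], [1.0]])
        treated = np.array([[3.0], [1.0], [-2.0]])
        calls = moderated_t_deg(control, treated, lfc_cutoff=1.0)
        assert calls.tolist() == [1, 0, -1]

    def test_mismatched_gene_sets_error(self):
        with pytest.raises(ValueError, match="gene sets"):
            moderated_t_deg(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_eb_shrinkage_matches_closed_form(self):
        """Moderated variances equal the scaled inverse-chi-square posterior mean.

        With many genes sharing one true variance, the empirical-Bayes prior
        absorbs most of the dispersion and each posterior variance is the
        stated convex combination of prior and sample variance.
        """
        rng = np.random.default_rng(7)
        df, sigma2 = 4, 0.25
        s2 = sigma2 * rng.chisquare(df, size=3000) / df
        post, d0, s0sq = squeeze_variances(s2, df)
        # Closed-form posterior mean given the fitted hyperparameters.
        if np.isfinite(d0):
            expected = (d0 * s0sq + df * s2) / (d0 + df)
        else:
            expected = np.full_like(s2, s0sq)
        np.testing.assert_allclose(post, expected, rtol=1e-12)
        # Shrinkage: moderated variances are far less dispersed and centered
        # near the shared truth.
        assert np.std(post) < 0.5 * np.std(s2)
        assert abs(np.mean(post) - sigma2) < 0.05
        # Hyperparameters solve the stated moment equations on log s^2.
        e = np.log(s2) - special.polygamma(0, df / 2) + np.log(df / 2)
        if np.isfinite(d0):
            assert abs(special.polygamma(1, d0 / 2) - (np.var(e, ddof=1)
                       - special.polygamma(1, df / 2))) < 1e-6


class TestTimeVectors:
    def test_chain_fixture_step_vectors(self, chain_pathway, chain_fixture):
        vecs = build_time_vectors(
            chain_fixture.treated, chain_fixture.genes,
            control_series=chain_fixture.control,
        )
        assert vecs["A"].v.tolist() == [1, 1, 1, 1]
        assert vecs["B"].v.tolist() == [0, 1, 1, 1]
        assert vecs["C"].v.tolist() == [0, 0, 1, 1]
        assert vecs["D"].v.tolist() == [0, 0, 0, 1]

    def test_vs_initial_constant_series_all_zero(self):
        series = np.full((5, 4, 3), 8.0)
        vecs = build_time_vectors(series, list("abcde"), mode="vs_initial")
        assert all((v.v == 0).all() for v in vecs.values())

    def test_vs_previous_monotone_increase(self):
        t = np.arange(4, dtype=float) * 5
        series = np.tile(t[None, :, None], (3, 1, 2))
        series += np.random.default_rng(0).normal(0, 0.01, series.shape)
        vecs = build_time_vectors(series, list("abc"), mode="vs_previous")
        assert vecs["a"].v.tolist() == [0, 1, 1, 1]

    def test_too_few_time_points_error(self):
        with pytest.raises(ValueError, match="time points"):
            build_time_vectors(np.zeros((2, 1, 3)), ["a", "b"], mode="vs_initial")

    def test_vs_control_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            build_time_vectors(np.zeros((2, 3, 2)), ["a", "b"], mode="vs_control")


class TestCrossCorrelation:
    @pytest.mark.parametrize(
        "v1,v2,n,expected",
        [
            ([1, 1, 0], [1, 1, 0], 0, 2),
            ([1, 0, 0], [0, 1, 0], 1, 1),
            ([1, 0, 0], [0, 1, 0], 0, 0),
            ([1, -1, 1], [-1, 1, -1], 1, 2),
            ([1, 0, 0], [0, 0, 1], 5, 0),  # lag beyond window
        ],
    )
    def test_known_values(self, v1, v2, n, expected):
        assert cross_correlation(v1, v2, n) == expected

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.data())
    def test_lag_antisymmetry(self, data):
        """(v1*v2)(n) == (v2*v1)(-n) for arbitrary ternary vectors."""
        T = data.draw(st.integers(2, 8))
        tern = st.lists(st.integers(-1, 1), min_size=T, max_size=T)
        v1, v2 = data.draw(tern), data.draw(tern)
        n = data.draw(st.integers(-T + 1, T - 1))
        assert cross_correlation(v1, v2, n) == cross_correlation(v2, v1, -n)


class TestPropagationDelay:
    @pytest.mark.parametrize(
        "v1,v2,d,peak",
        [
            ([1, 0, 0], [0, 1, 0], 1, 1),
            ([1, -1, 1], [-1, 1, -1], 1, 2),  # peak tied at n=+-1, sign tie -> +1
            ([0, 1, 0], [1, 0, 0], -1, 1),
            ([1, 1, 1, 1], [0, 1, 1, 1], 1, 3),  # step plateau endpoint
            ([0, 1, 1], [1, 1, 1], -1, 2),  # reversed step propagation
        ],
    )
    def test_known_delays(self, v1, v2, d, peak):
        assert propagation_delay(v1, v2) == (d, peak)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            T = int(rng.integers(2, 9))
            v1 = rng.integers(-1, 2, T)
            v2 = rng.integers(-1, 2, T)
            assert propagation_delay(v1, v2) == brute_force_delay(v1, v2)


class TestEdgeValidation:
    def _vectors(self, chain_fixture):
        return build_time_vectors(
            chain_fixture.treated, chain_fixture.genes,
            control_series=chain_fixture.control,
        )

    def test_chain_all_valid_with_unit_delay(self, chain_pathway, chain_fixture):
        vals = validate_edges(chain_pathway, self._vectors(chain_fixture), 2)
        assert all(ev.valid and ev.delay == 1 for ev in vals)

    def test_zero_threshold_invalidates_lagged_edges(self, chain_pathway, chain_fixture):
        vals = validate_edges(chain_pathway, self._vectors(chain_fixture), 0)
        assert all(not ev.valid for ev in vals)

    def test_reversed_edge_invalid(self, chain_fixture):
        back = PathwayGraph([("D", "A")], name="rev")
        (ev,) = validate_edges(back, self._vectors(chain_fixture), 2)
        assert not ev.valid and ev.delay < 0

    def test_missing_vector_skips_edge(self, chain_pathway, chain_fixture):
        vecs = self._vectors(chain_fixture)
        del vecs["D"]
        vals = validate_edges(chain_pathway, vecs, 2)
        assert len(vals) == 2  # C->D skipped


class TestExtractSubpathways:
    def _mk(self, edges):
        return [EdgeValidation(e, 1, 1, True) for e in edges]

    def test_single_chain_component(self, chain_pathway, chain_fixture):
        vecs = build_time_vectors(chain_fixture.treated, chain_fixture.genes,
                                  control_series=chain_fixture.control)
        vals = validate_edges(chain_pathway, vecs, 2)
        (sp,) = extract_subpathways(chain_pathway, vals, min_edges=3)
        assert set(sp.edge_tuples) == set(chain_pathway.edges)
        assert sp.statistic == sum(ev.peak for ev in vals)

    def test_below_min_edges_empty(self):
        pw = PathwayGraph([("A", "B"), ("B", "C")])
        assert extract_subpathways(pw, self._mk([("A", "B"), ("B", "C")])) == []

    def test_two_disjoint_components(self):
        edges1 = [("A", "B"), ("B", "C"), ("C", "D")]
        edges2 = [("X", "Y"), ("Y", "Z"), ("Z", "W")]
        pw = PathwayGraph(edges1 + edges2)
        sps = extract_subpathways(pw, self._mk(edges1 + edges2), min_edges=3)
        assert len(sps) == 2
        assert {frozenset(sp.genes) for sp in sps} == {
            frozenset("ABCD"), frozenset("XYZW")
        }


class TestPermutationPvalue:
    def _pool(self, rng, n, T):
        arr = rng.integers(-1, 2, size=(n, T))
        return {f"g{i}": DifferentialTimeVector(f"g{i}", arr[i]) for i in range(n)}

    def _subpathway(self, genes, pool):
        evs, stat = [], 0.0
        for u, v in zip(genes, genes[1:]):
            d, peak = propagation_delay(pool[u], pool[v])
            evs.append(EdgeValidation((u, v), d, peak, True))
            stat += peak
        return PerturbedSubpathway("p", 0, evs, stat)

    def test_observed_above_all_permutations_hits_plus_one_bound(self):
        # A strongly propagating sub-pathway against an all-zero donor pool.
        zero = {f"z{i}": DifferentialTimeVector(f"z{i}", np.zeros(4, dtype=int))
                for i in range(20)}
        evs = [EdgeValidation(e, 1, 3, True)
               for e in [("z0", "z1"), ("z1", "z2"), ("z2", "z3")]]
        sp = PerturbedSubpathway("p", 0, evs, 9.0)
        assert permutation_pvalue(sp, zero, B=999, seed=0) == pytest.approx(1 / 1000)

    def test_all_zero_vectors_give_p_one(self):
        zero = {f"z{i}": DifferentialTimeVector(f"z{i}", np.zeros(4, dtype=int))
                for i in range(20)}
        sp = self._subpathway(["z0", "z1", "z2", "z3"], zero)
        assert sp.statistic == 0.0
        assert permutation_pvalue(sp, zero, B=199, seed=0) == 1.0

    def test_pool_smaller_than_subpathway_errors(self):
        rng = np.random.default_rng(4)
        pool = self._pool(rng, 3, 4)
        sp = self._subpathway(["g0", "g1", "g2"], pool)
        small = {g: pool[g] for g in ["g0", "g1"]}
        with pytest.raises(ValueError, match="pool"):
            permutation_pvalue(sp, small, B=9, seed=0)

    def test_p_bounds_and_determinism(self):
        rng = np.random.default_rng(5)
        pool = self._pool(rng, 40, 5)
        for trial in range(10):
            genes = [f"g{i}" for i in rng.choice(40, 4, replace=False)]
            sp = self._subpathway(genes, pool)
            for ties in ("upper", "random"):
                p1 = permutation_pvalue(sp, pool, B=99, seed=trial, ties=ties)
                p2 = permutation_pvalue(sp, pool, B=99, seed=trial, ties=ties)
                assert p1 == p2
                assert 1 / 100 <= p1 <= 1.0

    def test_random_ties_never_exceed_upper(self):
        rng = np.random.default_rng(6)
        pool = self._pool(rng, 40, 4)
        for trial in range(10):
            genes = [f"g{i}" for i in rng.choice(40, 4, replace=False)]
            sp = self._subpathway(genes, pool)
            up = permutation_pvalue(sp, pool, B=199, seed=trial, ties="upper")
            rd = permutation_pvalue(sp, pool, B=199, seed=trial, ties="random")
            assert rd <= up


def test_bh_fdr_adjustment_known_case():
    p = [0.01, 0.02, 0.03, 0.04]
    np.testing.assert_allclose(bh_fdr(p), [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_fdr([0.5]), [0.5])


def test_pathway_graph_rejects_self_loops():
    with pytest.raises(ValueError, match="self-loop"):
        PathwayGraph([("A", "A")])
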