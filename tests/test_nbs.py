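import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasnbs import build_design, nbs_fwer, t_to_p, threshold_components, threshold_sweep
from atlasnbs.atlas import ParcellationScheme
from atlasnbs.connectome import CohortStack
from atlasnbs.design import DesignMatrix
from atlasnbs.nbs import NBSConfig, edge_glm_tstats


# ---------------------------------------------------------------------------
# oracles

def correlation_t(x, y):
    """Closed-form t of the Pearson correlation: r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.corrcoef(x, y)[0, 1]
    n = len(x)
    return r * np.sqrt(n - 2) / np.sqrt(1 - r**2)


def components_oracle(edges):
    """Brute-force DFS connected components of an edge list."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen, comps = set(), []
    for start in sorted(adj):
        if start in seen:
            continue
        stack, nodes = [start], set()
        while stack:
            u = stack.pop()
            if u in nodes:
                continue
            nodes.add(u)
            stack.extend(adj[u] - nodes)
        seen |= nodes
        comps.append(
            (frozenset(nodes), frozenset((min(a, b), max(a, b)) for a, b in edges
                                          if a in nodes and b in nodes))
        )
    return comps


def toy_parcellation(n):
    return ParcellationScheme(
        pd.DataFrame(
            {
                "id": range(n),
                "name": [f"n{i}" for i in range(n)],
                "hemisphere": ["L"] * n,
                "x": np.zeros(n),
                "y": np.zeros(n),
                "z": np.zeros(n),
            }
        )
    )


def make_stack(data, edge_index, n_nodes):
    return CohortStack(
        data=np.asarray(data, float),
        edge_index=list(edge_index),
        subject_ids=[f"s{i}" for i in range(len(data))],
        parcellation=toy_parcellation(n_nodes),
    )


def score_only_design(score):
    score = np.asarray(score, float)
    return DesignMatrix(
        X=np.column_stack([np.ones_like(score), score]),
        columns=["intercept", "score"],
        contrast=np.array([0.0, 1.0]),
        subject_ids=[f"s{i}" for i in range(len(score))],
    )


# ---------------------------------------------------------------------------
# edge GLM

class TestEdgeGLM:
    def test_matches_correlation_t_closed_form(self, rng):
        score = rng.normal(size=25)
        Y = rng.normal(size=(25, 40))
        t, df = edge_glm_tstats(Y, score_only_design(score))
        assert df == 23
        expected = [correlation_t(score, Y[:, j]) for j in range(40)]
        np.testing.assert_allclose(t, expected, rtol=1e-10)

    def test_matches_statsmodels_full_design(self, noisy_stack, noisy_cohort):
        import statsmodels.api as sm

        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        t, df = edge_glm_tstats(noisy_stack.data, design)
        for j in [0, 3, noisy_stack.n_edges - 1]:
            fit = sm.OLS(noisy_stack.data[:, j], design.X).fit()
            # our contrast is -score, so flip statsmodels' score t
            assert t[j] == pytest.approx(-fit.tvalues[1], rel=1e-9)
            assert df == int(fit.df_resid)

    def test_orthogonal_score_gives_zero_t(self):
        score = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([[1.0], [1.0], [2.0], [2.0], [3.0], [3.0]])
        t, _ = edge_glm_tstats(y, score_only_design(score))
        assert t[0] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_effect_flagged_as_infinite(self):
        score = np.arange(10.0)
        y = (2.0 + 0.1 * score)[:, None]
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            t, _ = edge_glm_tstats(y, score_only_design(score))
        assert np.isposinf(t[0])

    def test_nonfinite_stack_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            edge_glm_tstats(
                np.array([[np.nan] * 2] * 8), score_only_design(np.arange(8.0))
            )


class TestTtoP:
    def test_primary_threshold_correspondence(self):
        # t=3.5 at 39 df is two-sided p = 0.001 (3 decimals)
        assert round(t_to_p(3.5, 39, "two"), 3) == 0.001

    @pytest.mark.parametrize("t,df,sided,expected", [
        (0.0, 10, "two", 1.0),
        (1e6, 39, "two", 0.0),
        (0.0, 5, "one", 0.5),
    ])
    def test_limits(self, t, df, sided, expected):
        assert t_to_p(t, df, sided) == pytest.approx(expected, abs=1e-9)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            t_to_p(1.0, 0)


# ---------------------------------------------------------------------------
# component extraction

class TestThresholdComponents:
    def test_hand_built_five_node_graph(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4), (1, 3)]
        t = np.array([4.0, 3.6, 1.0, 3.9, 0.5, 3.7])
        comps = threshold_components(t, edges, 3.5)
        supra = [e for e, tv in zip(edges, t) if tv >= 3.5]
        oracle = components_oracle(supra)
        assert len(comps) == len(oracle)
        got = {(c.nodes, frozenset(c.edges)) for c in comps}
        assert got == set(oracle)

    def test_empty_above_threshold(self):
        comps = threshold_components(np.array([1.0, 2.0]), [(0, 1), (1, 2)], 3.5)
        assert comps == ()

    def test_tie_at_threshold_is_suprathreshold(self):
        comps = threshold_components(np.array([3.5]), [(0, 1)], 3.5)
        assert len(comps) == 1

    def test_negative_sign_selects_negative_tail(self):
        t = np.array([-4.0, 4.0])
        comps = threshold_components(t, [(0, 1), (2, 3)], 3.5, sign="negative")
        assert len(comps) == 1 and comps[0].edges == ((0, 1),)

    def test_nan_edges_never_suprathreshold(self):
        comps = threshold_components(np.array([np.nan, 4.0]), [(0, 1), (2, 3)], 3.5)
        assert comps[0].edges == ((2, 3),)

    def test_exhaustive_all_four_node_graphs(self):
        pairs = list(itertools.combinations(range(4), 2))
        for bits in range(2**6):
            edges = [pairs[i] for i in range(6) if bits >> i & 1]
            if not edges:
                continue
            t = np.full(len(edges), 5.0)
            comps = threshold_components(t, edges, 3.5)
            oracle = components_oracle(edges)
            assert {(c.nodes, frozenset(c.edges)) for c in comps} == set(oracle)

    @settings(max_examples=300, deadline=None)
    @given(seed=st.integers(0, 10**6), p=st.floats(0.1, 0.9))
    def test_random_eight_node_graphs_match_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        pairs = list(itertools.combinations(range(8), 2))
        keep = rng.random(len(pairs)) < p
        edges = [e for e, k in zip(pairs, keep) if k]
        if not edges:
            return
        t = np.full(len(edges), 4.0)
        comps = threshold_components(t, edges, 3.5)
        assert {(c.nodes, frozenset(c.edges)) for c in comps} == set(
            components_oracle(edges)
        )


# ---------------------------------------------------------------------------
# permutation inference

class TestNBSFwer:
    def test_planted_subnetwork_recovered(self, noisy_stack, noisy_cohort, planted_edges):
        _, records, truth = noisy_cohort
        design = build_design(records, "DRS")
        result = nbs_fwer(
            noisy_stack, design, NBSConfig(t_threshold=3.5, n_permutations=500, seed=7)
        )
        assert result.significant, "planted effect not detected"
        best = result.significant[0]
        assert set(planted_edges) <= set(best.edges)
        assert best.p_fwer <= 0.05

    def test_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(42)
        score = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        Y = rng.normal(size=(5, 6)) + 0.8 * score[:, None]
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)]
        design = score_only_design(score)
        threshold = 2.0

        t_obs, _ = edge_glm_tstats(Y, design)
        obs_comps = threshold_components(t_obs, edges, threshold)
        obs_max = obs_comps[0].size if obs_comps else 0

        # reduced model = intercept; enumerate all 120 residual permutations
        resid = Y - Y.mean(axis=0)
        fitted = np.broadcast_to(Y.mean(axis=0), Y.shape)
        null = []
        for perm in itertools.permutations(range(5)):
            t_p, _ = edge_glm_tstats(fitted + resid[list(perm)], design)
            comps = threshold_components(t_p, edges, threshold)
            null.append(comps[0].size if comps else 0)
        p_exact = np.mean(np.array(null) >= obs_max)

        stack = make_stack(Y, edges, 6)
        n_perm = 4000
        result = nbs_fwer(
            stack, design, NBSConfig(t_threshold=threshold, n_permutations=n_perm, seed=0)
        )
        p_hat = result.components[0].p_fwer
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_hat - p_exact) < 3 * se + 2 / n_perm

    def test_freedman_lane_equals_raw_permutation_without_nuisance(self, rng):
        # with an intercept-only reduced model, reconstituted data are exactly
        # the row-permuted data, so both code paths agree for a shared sequence
        score = rng.normal(size=12)
        Y = rng.normal(size=(12, 5))
        design = score_only_design(score)
        perm = rng.permutation(12)
        resid = Y - Y.mean(axis=0)
        reconstituted = Y.mean(axis=0) + resid[perm]
        t_fl, _ = edge_glm_tstats(reconstituted, design)
        t_raw, _ = edge_glm_tstats(Y[perm], design)
        np.testing.assert_allclose(t_fl, t_raw, rtol=1e-10)

    def test_p_invariant_to_subject_reordering(self, rng):
        score = rng.normal(size=15)
        Y = rng.normal(size=(15, 8)) + 1.2 * np.outer(score, np.ones(8))
        edges = [(i, i + 1) for i in range(8)]
        design = score_only_design(score)
        stack = make_stack(Y, edges, 9)
        cfg = NBSConfig(t_threshold=2.5, n_permutations=800, seed=3)
        r1 = nbs_fwer(stack, design, cfg)

        order = rng.permutation(15)
        stack2 = make_stack(Y[order], edges, 9)
        r2 = nbs_fwer(stack2, score_only_design(score[order]), cfg)
        t1 = r1.t_matrix[~np.isnan(r1.t_matrix)]
        t2 = r2.t_matrix[~np.isnan(r2.t_matrix)]
        np.testing.assert_allclose(t1, t2, rtol=1e-9)
        p1 = sorted(c.p_fwer for c in r1.components)
        p2 = sorted(c.p_fwer for c in r2.components)
        # same permutation-null law; sampled independently, so p agree within MC error
        for a, b in zip(p1, p2):
            assert abs(a - b) < 3 * np.sqrt(0.25 / 800) + 2 / 800

    def test_t_invariant_to_pca_sign_flip(self, noisy_stack, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        X_flipped = design.X.copy()
        X_flipped[:, 4] = -X_flipped[:, 4]
        flipped = DesignMatrix(
            X=X_flipped,
            columns=design.columns,
            contrast=design.contrast,
            subject_ids=design.subject_ids,
        )
        t1, _ = edge_glm_tstats(noisy_stack.data, design)
        t2, _ = edge_glm_tstats(noisy_stack.data, flipped)
        np.testing.assert_allclose(t1, t2, rtol=1e-10)

    def test_same_seed_reproducible(self, noisy_stack, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        cfg = NBSConfig(n_permutations=100, seed=11)
        r1 = nbs_fwer(noisy_stack, design, cfg)
        r2 = nbs_fwer(noisy_stack, design, cfg)
        np.testing.assert_array_equal(r1.null_max_size, r2.null_max_size)
        assert [c.p_fwer for c in r1.components] == [c.p_fwer for c in r2.components]

    def test_empty_stack_rejected(self, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        empty = make_stack(np.empty((40, 0)), [], 3)
        with pytest.raises(ValueError, match="no valid edges"):
            nbs_fwer(empty, design, NBSConfig(n_permutations=10, seed=0))

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            NBSConfig(n_permutations=0)


class TestThresholdSweep:
    def test_extent_never_grows_with_threshold(self, noisy_stack, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        cfg = NBSConfig(n_permutations=50, seed=2)
        results = threshold_sweep(noisy_stack, design, [3.3, 3.5, 3.7], cfg)
        assert sorted(results) == [3.3, 3.5, 3.7]
        sizes = [
            max((c.size for c in results[th].components), default=0)
            for th in [3.3, 3.5, 3.7]
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_high_threshold_reports_no_connections(self, noisy_stack, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        cfg = NBSConfig(n_permutations=20, seed=2)
        results = threshold_sweep(noisy_stack, design, [200.0], cfg)
        assert results[200.0].components == ()
        assert results[200.0].significant == ()

    def test_unsorted_thresholds_rejected(self, noisy_stack, noisy_cohort):
        _, records, _ = noisy_cohort
        design = build_design(records, "DRS")
        with pytest.raises(ValueError, match="sorted"):
            threshold_sweep(noisy_stack, design, [3.7, 3.3], NBSConfig(n_permutations=5, seed=0))
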