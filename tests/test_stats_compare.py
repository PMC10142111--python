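"""Differential statistics: U tests, adjustments, effects, structure."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ckdmrm import (
    AbundanceMatrix,
    CohortDesign,
    adjust_bh,
    adjust_holm,
    cohens_d,
    embed_pca_tsne,
    generate_cohort,
    hierarchical_cluster,
    ln1p_transform,
    mann_whitney,
    pearson_matrix,
    prevalence_filter,
    run_contrasts,
)
from ckdmrm.synthetic_cohort import PlantedMarker


# --- independent oracles -----------------------------------------------------


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Under H0 every partition of the pooled values into group sizes (n1, n2)
    is equally likely; p = fraction of partitions whose U is at least as
    extreme (on either tail) as the observed one.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(a, b):
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    u_obs = u_stat(x, y)
    mean_u = n1 * len(y) / 2
    dev = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mean_u) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def bh_oracle(p):
    """Step-up adjustment straight from its definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def holm_oracle(p):
    """Step-down adjustment straight from its definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 0.0
    for rank in range(1, m + 1):
        i = order[rank - 1]
        running = max(running, (m - rank + 1) * p[i])
        q[i] = min(running, 1.0)
    return q


# --- Mann-Whitney ------------------------------------------------------------


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_interleaved_matches_enumeration(self):
        x, y = [1, 3, 5, 7], [2, 4, 6, 8]
        u, p = mann_whitney(x, y)
        u_o, p_o = mw_enumeration_oracle(x, y)
        assert u == u_o == 6.0
        assert p == pytest.approx(p_o)

    def test_identical_samples(self):
        _, p = mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 4))
    def test_shift_invariance(self, seed, scale):
        """Adding a constant to both samples leaves U and p unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6) * scale
        y = rng.normal(size=7) * scale
        assert mann_whitney(x, y) == mann_whitney(x + 13.7, y + 13.7)


# --- adjustments -------------------------------------------------------------


class TestAdjustments:
    def test_bh_hand_examples(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(adjust_bh([0.5]), [0.5])
        assert np.allclose(adjust_bh([0.04, 0.01]), [0.04, 0.02])

    def test_holm_hand_examples(self):
        assert np.allclose(adjust_holm([0.01, 0.04]), [0.02, 0.04])
        assert np.allclose(adjust_holm([0.2]), [0.2])
        assert np.allclose(adjust_holm([0.01, 0.01, 0.01]), [0.03, 0.03, 0.03])

    def test_invalid_pvalues_rejected(self):
        for bad in ([-0.1], [1.5], [np.nan]):
            with pytest.raises(ValueError):
                adjust_bh(bad)
            with pytest.raises(ValueError):
                adjust_holm(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=100))
    def test_match_bruteforce_definitions(self, p):
        assert np.max(np.abs(adjust_bh(p) - bh_oracle(p))) < 1e-12
        assert np.max(np.abs(adjust_holm(p) - holm_oracle(p))) < 1e-12


# --- effect size -------------------------------------------------------------


class TestCohensD:
    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)

    def test_identical_groups_zero(self):
        assert cohens_d([2, 2, 2], [2, 2, 2]) == 0.0

    def test_antisymmetry(self):
        x, y = [1.0, 2.5, 3.0], [0.5, 4.0, 1.0]
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_sd_warns_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert cohens_d([1, 1], [2, 2]) == -np.inf


# --- contrasts ---------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_contrasts():
    design = CohortDesign(
        n_proteins=30,
        planted_markers=(PlantedMarker(3, {"sFSGS": 2.5, "MN": 2.5}),),
        seed=21,
    )
    matrix, _, truth = generate_cohort(design)
    ln = ln1p_transform(matrix)
    _, core = prevalence_filter(ln, 2 / 3, mode="all_groups")
    return run_contrasts(core, alpha_raw=0.05), truth


class TestContrasts:
    def test_planted_marker_flagged(self, planted_contrasts):
        """A protein with a large planted severe-group effect passes the
        FWER cutoff in the control-vs-sFSGS contrast."""
        results, truth = planted_contrasts
        hit = results[
            (results.protein_id == truth.marker_ids[0])
            & (results.group_a == "control")
            & (results.group_b == "sFSGS")
        ]
        assert bool(hit.fwer5.iloc[0])

    def test_flag_dominance(self, planted_contrasts):
        """Holm-significant implies BH-significant implies raw-significant
        (p_holm >= p_bh >= p_raw on shared p-values)."""
        results, _ = planted_contrasts
        assert (results.p_bh >= results.p_raw - 1e-12).all()
        assert (results.p_holm >= results.p_bh - 1e-12).all()
        assert not (results.fwer5 & ~results.fdr10).any()
        assert not (results.fdr10 & ~results.raw).any()

    def test_unknown_group_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown group"):
            run_contrasts(toy_matrix, contrasts=[("g1", "nope")])


# --- correlation / clustering / embedding ------------------------------------


class TestStructure:
    def test_pearson_trivials_and_oracle(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=5)
        vals = pd.DataFrame(
            {"a": base, "b": base.copy(), "c": -base, "d": rng.normal(size=5)},
            index=[f"s{i}" for i in range(5)],
        )
        m = AbundanceMatrix(vals, "ln1p")
        corr = pearson_matrix(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        # textbook formula oracle
        x, y = vals["a"], vals["d"]
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert corr.loc["a", "d"] == pytest.approx(r, abs=1e-12)

    def test_identical_samples_merge_at_zero(self):
        vals = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, -5.0]],
            index=["s1", "s2", "s3"], columns=["P1", "P2", "P3"],
        )
        res = hierarchical_cluster(AbundanceMatrix(vals, "ln1p"))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_first(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        vals = pd.DataFrame(
            [base, 2 * base + 0.01, -base],
            index=["s1", "s2", "s3"], columns=["P1", "P2", "P3", "P4"],
        )
        res = hierarchical_cluster(AbundanceMatrix(vals, "ln1p"))
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_topology_invariant_to_row_permutation(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(
            rng.normal(size=(6, 8)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"P{j}" for j in range(8)],
        )
        m1 = AbundanceMatrix(vals, "ln1p")
        perm = vals.sample(frac=1, random_state=1)
        m2 = AbundanceMatrix(perm, "ln1p")
        h1 = sorted(hierarchical_cluster(m1).linkage[:, 2])
        h2 = sorted(hierarchical_cluster(m2).linkage[:, 2])
        assert np.allclose(h1, h2)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(4, 5)),
                            index=list("abcd"), columns=[f"P{j}" for j in range(5)])
        nwk = hierarchical_cluster(AbundanceMatrix(vals, "ln1p")).to_newick()
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "abcd")

    def test_embedding_determinism_and_shape_guard(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(20, 10)),
                            index=[f"s{i}" for i in range(20)],
                            columns=[f"P{j}" for j in range(10)])
        m = AbundanceMatrix(vals, "zscore")
        c1 = embed_pca_tsne(m, n_components=7, seed=4)
        c2 = embed_pca_tsne(m, n_components=7, seed=4)
        assert c1.equals(c2)
        with pytest.raises(ValueError, match="n_components"):
            embed_pca_tsne(m, n_components=11, seed=4)
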