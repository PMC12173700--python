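"""Edge-wise Mann-Whitney contrast and its permutation machinery.

The enumeration oracle used here recomputes U and the exact two-sided
permutation p by brute force over every group labeling of the pooled data,
independently of the implementation's rank arithmetic.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connodiff.connectomes import RSFMRI
from connodiff.contrast import (
    build_schedule,
    contrast_analysis,
    edgewise_scan,
    mann_whitney_edge,
    null_z_matrix,
    permutation_test_edges,
    rosenthal_r,
)
from connodiff.simulate import SimulationConfig, simulate_cohort


def enumerate_u_and_p(a, b):
    """Brute-force U (A-first, ties 1/2) and exact two-sided p over all
    C(nA+nB, nA) labelings of the pooled sample."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_stat(a, b)
    mu = na * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitneyEdge:
    def test_full_ties(self):
        u, z, p, direction = mann_whitney_edge([3, 3, 3], [3, 3, 3, 3])
        assert u == 3 * 4 / 2
        assert z == 0 and p == 1 and direction == "tied"

    def test_separated_groups(self):
        u, z, p, direction = mann_whitney_edge([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert direction == "higher-in-B"
        _, p_exact = enumerate_u_and_p([1, 2, 3], [4, 5, 6])
        assert p_exact == pytest.approx(0.1)
        assert abs(p - p_exact) <= 0.05  # normal approximation quality

    def test_antisymmetry(self, rng):
        a, b = rng.random(6), rng.random(4)
        u1, z1, p1, d1 = mann_whitney_edge(a, b)
        u2, z2, p2, d2 = mann_whitney_edge(b, a)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)
        assert {d1, d2} == {"higher-in-A", "higher-in-B"} or d1 == d2 == "tied"

    def test_matches_scipy_u(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, rng.integers(2, 8)).astype(float)
            b = rng.integers(0, 6, rng.integers(2, 8)).astype(float)
            u, *_ = mann_whitney_edge(a, b)
            assert u == stats.mannwhitneyu(a, b, alternative="two-sided").statistic

    @given(st.integers(0, 2**31 - 1), st.integers(2, 4), st.integers(2, 4))
    @settings(max_examples=40, deadline=None)
    def test_enumeration_oracle_small_groups(self, seed, na, nb):
        # U always matches the enumeration oracle exactly; the exact p is a
        # coarse step function at these sizes, so the normal approximation
        # is only held to a loose bound here (see the moderate-size check)
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, na).astype(float)  # ties likely
        b = rng.integers(0, 5, nb).astype(float)
        u, z, p, _ = mann_whitney_edge(a, b)
        u_oracle, p_exact = enumerate_u_and_p(a, b)
        assert u == u_oracle
        assert abs(p - p_exact) <= 0.35 or p_exact == 1.0

    def test_normal_approximation_close_at_moderate_size(self, rng):
        # at 8 vs 8 (the smallest sizes the scan is meant for) the
        # tie-corrected, continuity-corrected approximation tracks the exact
        # permutation p within 0.05
        for _ in range(15):
            a = rng.integers(0, 6, 8).astype(float)
            b = rng.integers(0, 6, 8).astype(float)
            _, _, p, _ = mann_whitney_edge(a, b)
            _, p_exact = enumerate_u_and_p(a, b)
            if p_exact < 1.0:
                assert abs(p - p_exact) <= 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_edge([1.0], [2.0, 3.0])


class TestRosenthalR:
    @pytest.mark.parametrize("z,n,expected", [(0, 10, 0.0), (2, 100, 0.2), (-2, 100, 0.2)])
    def test_values(self, z, n, expected):
        assert rosenthal_r(z, n) == pytest.approx(expected)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            rosenthal_r(1.0, 0)


class TestSchedule:
    def test_group_sizes_preserved(self):
        sched = build_schedule(7, 5, 200, seed=1)
        assert np.all(sched.a_masks.sum(axis=1) == 7)
        assert sched.a_masks.shape == (200, 12)

    def test_reproducible(self):
        a = build_schedule(5, 5, 50, seed=9).a_masks
        b = build_schedule(5, 5, 50, seed=9).a_masks
        assert np.array_equal(a, b)

    def test_uniform_over_labelings(self):
        # nA = nB = 2: all C(4,2) = 6 labelings roughly equally frequent
        sched = build_schedule(2, 2, 12_000, seed=4)
        keys, counts = np.unique(sched.a_masks, axis=0, return_counts=True)
        assert len(keys) == 6
        assert np.all(np.abs(counts / 12_000 - 1 / 6) < 0.02)


def _null_cohort(seed, n_parcels=20, na=12, nb=12):
    cfg = SimulationConfig(n_parcels=n_parcels, n_group_a=na, n_group_b=nb,
                           within_block_r=0.0, between_block_r=0.0, seed=seed)
    cohort, _ = simulate_cohort(cfg)
    return cohort


class TestEdgewiseScan:
    def test_alpha_zero_empty_candidates(self, null_cohort):
        res = edgewise_scan(null_cohort, RSFMRI, alpha=0.0)
        assert not res.candidate_mask.any()

    def test_scan_matches_per_edge_test(self, null_cohort):
        from connodiff.contrast import cohort_edge_matrix

        res = edgewise_scan(null_cohort, RSFMRI)
        data, a_mask = cohort_edge_matrix(null_cohort, RSFMRI)
        for k in [0, 17, 100, 250]:
            u, z, p, _ = mann_whitney_edge(data[a_mask, k], data[~a_mask, k])
            assert res.u[k] == pytest.approx(u)
            assert res.z[k] == pytest.approx(z)
            assert res.p_param[k] == pytest.approx(p)

    def test_planted_shift_detected(self):
        cohort = _null_cohort(2)
        for s in cohort.subjects:  # shift edge (1,2) massively in group A
            if s.group_label == "CHR-P":
                v = s.connectomes[RSFMRI].values
                v[0, 1] = v[1, 0] = v[0, 1] + 10.0
        res = edgewise_scan(cohort, RSFMRI)
        assert res.candidate_mask[0]  # edge (1,2) is the first upper-tri entry
        assert res.direction[0] == 1

    def test_all_zero_edges_skipped(self):
        from connodiff.connectomes import DMRI

        cohort = _null_cohort(3)
        res = edgewise_scan(cohort, DMRI)  # sparse backbone: many zero edges
        assert (~res.tested).sum() > 0
        assert not res.candidate_mask[~res.tested].any()
        assert np.all(res.p_param[~res.tested] == 1.0)

    def test_subject_order_invariance(self):
        cohort = _null_cohort(4)
        res1 = edgewise_scan(cohort, RSFMRI)
        shuffled = cohort
        rng = np.random.default_rng(0)
        shuffled.subjects = [cohort.subjects[i] for i in rng.permutation(len(cohort.subjects))]
        res2 = edgewise_scan(shuffled, RSFMRI)
        assert np.allclose(res1.u, res2.u)
        assert np.allclose(res1.z, res2.z)


class TestPermutationStage:
    def test_extreme_observation_p_zero_and_add_one(self):
        cohort = _null_cohort(5)
        for s in cohort.subjects:
            if s.group_label == "CHR-P":
                v = s.connectomes[RSFMRI].values
                v[0, 1] = v[1, 0] = v[0, 1] + 50.0
        res = edgewise_scan(cohort, RSFMRI)
        sched = build_schedule(res.n_a, res.n_b, 200, seed=8)
        res = permutation_test_edges(cohort, RSFMRI, res, sched)
        assert res.perm_p[0] == 0.0
        res_a = permutation_test_edges(cohort, RSFMRI, edgewise_scan(cohort, RSFMRI), sched, add_one=True)
        assert res_a.perm_p[0] == pytest.approx(1 / 201)

    def test_median_observation_p_half(self, rng):
        # inject an observed |z| equal to the null median: perm_p ~ 0.5
        cohort = _null_cohort(6)
        res = edgewise_scan(cohort, RSFMRI)
        sched = build_schedule(res.n_a, res.n_b, 400, seed=3)
        from connodiff.contrast import cohort_edge_matrix

        data, _ = cohort_edge_matrix(cohort, RSFMRI)
        nulls = null_z_matrix(data, sched, columns=np.array([0]))
        res.z[0] = np.median(nulls)
        res.candidate_mask[0] = True
        res = permutation_test_edges(cohort, RSFMRI, res, sched)
        assert res.perm_p[0] == pytest.approx(0.5, abs=0.1)

    def test_significant_monotone_in_p_crit(self):
        cohort, _ = simulate_cohort(SimulationConfig(
            n_parcels=20, n_group_a=10, n_group_b=10, within_block_r=0.0, seed=41))
        res = edgewise_scan(cohort, RSFMRI, alpha=0.2)
        sched = build_schedule(res.n_a, res.n_b, 300, seed=2)
        strict = permutation_test_edges(cohort, RSFMRI, res, sched, p_crit=0.01).significant.copy()
        loose = permutation_test_edges(cohort, RSFMRI, res, sched, p_crit=0.2).significant.copy()
        assert np.all(loose[strict])  # lowering p_crit never adds edges

    def test_schedule_mismatch_rejected(self):
        cohort = _null_cohort(7)
        res = edgewise_scan(cohort, RSFMRI)
        bad = build_schedule(res.n_a + 1, res.n_b - 1, 10, seed=0)
        with pytest.raises(ValueError):
            permutation_test_edges(cohort, RSFMRI, res, bad)

    def test_contrast_analysis_deterministic(self):
        cohort = _null_cohort(9)
        r1 = contrast_analysis(cohort, RSFMRI, n_permutations=100, seed=5)
        r2 = contrast_analysis(cohort, RSFMRI, n_permutations=100, seed=5)
        assert np.array_equal(r1.perm_p, r2.perm_p, equal_nan=True)
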