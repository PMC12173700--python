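"""Structural-functional overlap: intersect of largest subnetworks with a
node-identity permutation null.

The observed statistic is the set of nodes common to the largest dMRI and
the largest rsfMRI difference subnetworks.  Its null distribution is built
by relabeling the groups (sizes preserved) within each modality, re-running
the edge-wise scan at the candidate threshold, intersecting the resulting
largest components, and recording which node identities appear.  Each
observed intersect node's p-value is the fraction of permutations in which
that identity appeared; the p-values are Benjamini-Hochberg corrected over
the observed intersect.

Inside the null loop the candidate (alpha-threshold) graph is used directly,
without the nested per-edge permutation stage — nesting two 10,000-iteration
permutation layers is computationally prohibitive and the inner stage only
prunes candidates, which the null intersect statistic does not require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectomes import CohortDataset, edge_ids
from .contrast import ContrastResult, _rank_statistics
from .subnetworks import DifferenceGraph, connected_components


def largest_subnetwork_nodes(contrast: ContrastResult, which: str = "significant") -> set[int]:
    """Node set of the largest component of the contrast's difference graph
    (empty when there are no edges).  Ties follow the component sort order:
    node count, then edge count, then smallest member id."""
    graph = DifferenceGraph.from_contrast(contrast, which=which)
    comps = connected_components(graph)
    return set(comps[0].nodes) if comps else set()


def intersect_nodes(a: set[int], b: set[int]) -> set[int]:
    """Plain set intersection of two node sets on the same atlas."""
    return set(a) & set(b)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1, returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def node_identity_p(counts: np.ndarray, n_iterations: int, add_one: bool = False) -> np.ndarray:
    """Per-node p: appearance count in the null divided by the number of
    permutations (the literal rule; ``add_one`` gives (c+1)/(G+1))."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts > n_iterations):
        raise ValueError("a null count exceeds the number of iterations")
    if add_one:
        return (counts + 1.0) / (n_iterations + 1.0)
    return counts / float(n_iterations)


class _UnionFind:
    """Minimal union-find for the per-iteration component computation."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent[p]
            x = p
            p = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _largest_component_nodes(ei: np.ndarray, ej: np.ndarray) -> frozenset[int]:
    """Largest-component node set under the standard sort order."""
    if ei.size == 0:
        return frozenset()
    uf = _UnionFind()
    n_edges: dict[int, int] = {}
    for i, j in zip(ei.tolist(), ej.tolist()):
        uf.union(i, j)
    comps: dict[int, set[int]] = {}
    for node in set(ei.tolist()) | set(ej.tolist()):
        comps.setdefault(uf.find(node), set()).add(node)
    for i, j in zip(ei.tolist(), ej.tolist()):
        r = uf.find(i)
        n_edges[r] = n_edges.get(r, 0) + 1
    best = min(comps, key=lambda r: (-len(comps[r]), -n_edges.get(r, 0), min(comps[r])))
    return frozenset(comps[best])


@dataclass
class OverlapResult:
    """Observed intersect with per-node permutation p and BH q."""

    intersect: list[int]  # sorted observed intersect node ids
    null_counts: np.ndarray  # per atlas node (index node_id - 1)
    p: dict[int, float]
    q: dict[int, float]
    significant: set[int]
    n_iterations: int
    seed: int | None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.intersect,
                "null_count": [int(self.null_counts[n - 1]) for n in self.intersect],
                "p": [self.p[n] for n in self.intersect],
                "q": [self.q[n] for n in self.intersect],
                "significant": [n in self.significant for n in self.intersect],
            }
        )


def overlap_null(
    cohort_dmri: CohortDataset,
    cohort_rsfmri: CohortDataset,
    alpha: float = 0.001,
    n_iterations: int = 10_000,
    seed: int | None = None,
    shared_relabeling: bool = False,
) -> np.ndarray:
    """Null appearance counts of every node identity in the intersect of
    largest components, over ``n_iterations`` group relabelings.

    Relabelings are drawn independently per modality by default (the
    post-QC subject sets generally differ between modalities);
    ``shared_relabeling`` reuses one relabeling per iteration for cohorts
    with identical subject lists.
    """
    from .contrast import cohort_edge_matrix  # local import to avoid cycle noise

    if cohort_dmri.atlas.n_parcels != cohort_rsfmri.atlas.n_parcels:
        raise ValueError("the two cohorts must share one atlas")
    n_parcels = cohort_dmri.atlas.n_parcels
    counts = np.zeros(n_parcels)
    if n_iterations == 0:
        return counts
    z_crit = stats.norm.isf(alpha / 2.0)
    ei, ej = edge_ids(n_parcels)

    per_modality = []
    rng = np.random.default_rng(seed)
    for cohort, modality in ((cohort_dmri, "dmri"), (cohort_rsfmri, "rsfmri")):
        data, a_mask = cohort_edge_matrix(cohort, modality)
        n = data.shape[0]
        n_a = int(a_mask.sum())
        base = np.zeros(n, dtype=bool)
        base[:n_a] = True
        _, _, _, sigma, ranks = _rank_statistics(data, base)
        tested = (~np.all(data == 0, axis=0)) & (sigma > 0)
        per_modality.append((ranks, sigma, tested, n, n_a))
    if shared_relabeling and per_modality[0][3] != per_modality[1][3]:
        raise ValueError("shared relabeling requires identical subject counts")

    for _ in range(n_iterations):
        sets = []
        shared_perm = rng.permutation(per_modality[0][3]) if shared_relabeling else None
        for ranks, sigma, tested, n, n_a in per_modality:
            perm = shared_perm if shared_perm is not None else rng.permutation(n)
            a_rows = perm[:n_a]
            r_a = ranks[a_rows].sum(axis=0)
            d = r_a - n_a * (n_a + 1) / 2.0 - n_a * (n - n_a) / 2.0
            with np.errstate(divide="ignore", invalid="ignore"):
                absz = np.maximum(np.abs(d) - 0.5, 0.0) / sigma
            cand = tested & (absz > z_crit)
            sets.append(_largest_component_nodes(ei[cand], ej[cand]))
        for node in sets[0] & sets[1]:
            counts[node - 1] += 1
    return counts


def overlap_analysis(
    cohort_dmri: CohortDataset,
    cohort_rsfmri: CohortDataset,
    contrast_dmri: ContrastResult,
    contrast_rsfmri: ContrastResult,
    n_iterations: int = 10_000,
    seed: int | None = None,
    q_crit: float = 0.05,
    shared_relabeling: bool = False,
    add_one: bool = False,
) -> OverlapResult:
    """Observed intersect of the largest dMRI/rsfMRI subnetworks, assessed
    against the node-identity permutation null; BH over the intersect."""
    observed = sorted(
        intersect_nodes(
            largest_subnetwork_nodes(contrast_dmri), largest_subnetwork_nodes(contrast_rsfmri)
        )
    )
    counts = overlap_null(
        cohort_dmri,
        cohort_rsfmri,
        alpha=contrast_dmri.alpha,
        n_iterations=n_iterations,
        seed=seed,
        shared_relabeling=shared_relabeling,
    )
    p_obs = node_identity_p(np.array([counts[n - 1] for n in observed]), n_iterations, add_one)
    q_obs = bh_adjust(p_obs)
    p = {n: float(v) for n, v in zip(observed, p_obs)}
    q = {n: float(v) for n, v in zip(observed, q_obs)}
    return OverlapResult(
        intersect=observed,
        null_counts=counts,
        p=p,
        q=q,
        significant={n for n in observed if q[n] <= q_crit},
        n_iterations=n_iterations,
        seed=seed,
    )
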