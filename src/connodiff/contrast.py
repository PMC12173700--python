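"""Edge-wise group contrast: Mann-Whitney tests, permutation nulls, effects.

This is the analysis's core statistic, a variant of the Network Based
Statistic that tests *each edge weight* against its own permutation null
rather than forming a cluster statistic:

1. For every unordered node pair, the two groups' edge-weight vectors are
   compared with a Mann-Whitney-Wilcoxon rank test (normal approximation
   with midrank ties, tie-corrected variance and continuity correction).
2. Edges with two-sided approximate p below a conservative ``alpha``
   (default 0.001) become candidates — a sparse matrix of uncorrected
   differences.
3. Candidate edges are re-tested against a permutation null: group labels
   are reassigned at random ``G`` times (group sizes preserved), the |z|
   statistic is recomputed under each relabeling, and the permutation p is
   the fraction of null |z| values at or above the observed one.
4. Effect sizes are Rosenthal's r = |z| / sqrt(N).

Because pooled ranks are invariant under relabeling, each permutation
reduces to re-summing fixed per-subject ranks over a new group-A subset —
one matrix product per schedule — which is what makes a 10,000-iteration
per-edge scan affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectomes import CohortDataset, edge_ids, upper_vector

DIR_HIGHER_A = 1
DIR_HIGHER_B = -1
DIR_TIED = 0
_DIR_NAMES = {DIR_HIGHER_A: "higher-in-A", DIR_HIGHER_B: "higher-in-B", DIR_TIED: "tied"}


# ---------------------------------------------------------------------------
# scalar operations


def rosenthal_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |z| / sqrt(N), N the total subject count."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return abs(z) / np.sqrt(n_total)


def _rank_statistics(data: np.ndarray, a_mask: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised Mann-Whitney over columns of ``data`` (subjects x edges).

    Returns (U, z, p, sigma, ranks) where U is the group-A-first statistic
    (number of (a, b) pairs with a > b, ties counted 1/2), z the continuity-
    corrected normal deviate with tie-corrected variance, and p the
    two-sided approximate p-value.  Columns where every pooled value is tied
    get z = 0, p = 1.
    """
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    na = int(a_mask.sum())
    nb = n - na
    ranks = stats.rankdata(data, axis=0)
    r_a = ranks[a_mask].sum(axis=0)
    u = r_a - na * (na + 1) / 2.0

    # tie correction: sum over tie groups of (t^3 - t), per column
    srt = np.sort(data, axis=0)
    new_run = np.ones_like(srt, dtype=bool)
    new_run[1:] = srt[1:] != srt[:-1]
    gid = np.cumsum(new_run, axis=0) - 1  # per-column run id, 0-based
    flat = gid + np.arange(m) * n  # disambiguate columns
    counts = np.bincount(flat.ravel(), minlength=n * m).astype(float)
    tie_term = ((counts**3 - counts).reshape(m, n)).sum(axis=1)

    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    d = u - na * nb / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sign(d) * np.maximum(np.abs(d) - 0.5, 0.0) / sigma
    z[sigma == 0] = 0.0
    z[~np.isfinite(z)] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    np.minimum(p, 1.0, out=p)
    return u, z, p, sigma, ranks


def mann_whitney_edge(a, b) -> tuple[float, float, float, str]:
    """Mann-Whitney for one edge: returns (U, z, p_param, direction).

    U is group-A-first (counts pairs where a beats b, ties 1/2); z uses the
    tie-corrected normal approximation with continuity correction; the
    direction labels which group has higher values ("tied" at U = nA*nB/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    data = np.concatenate([a, b])[:, None]
    mask = np.zeros(a.size + b.size, dtype=bool)
    mask[: a.size] = True
    u, z, p, _, _ = _rank_statistics(data, mask)
    d = u[0] - a.size * b.size / 2.0
    direction = _DIR_NAMES[DIR_TIED if d == 0 else (DIR_HIGHER_A if d > 0 else DIR_HIGHER_B)]
    return float(u[0]), float(z[0]), float(p[0]), direction


# ---------------------------------------------------------------------------
# cohort-level scan


@dataclass
class PermutationSchedule:
    """G random group relabelings with the original group sizes preserved.

    ``a_masks`` is a (G, n_subjects) boolean array; each row has exactly nA
    True entries marking the subjects assigned to group A in that iteration.
    """

    a_masks: np.ndarray
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return self.a_masks.shape[0]

    @property
    def n_a(self) -> int:
        return int(self.a_masks[0].sum()) if self.n_iterations else 0


def build_schedule(n_a: int, n_b: int, n_iterations: int = 10_000, seed: int | None = None) -> PermutationSchedule:
    """Uniform random relabelings (one shared schedule for all edges)."""
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    base = np.zeros(n_a + n_b, dtype=bool)
    base[:n_a] = True
    masks = np.tile(base, (n_iterations, 1))
    masks = rng.permuted(masks, axis=1)
    return PermutationSchedule(a_masks=masks, seed=seed)


@dataclass
class ContrastResult:
    """Per-edge statistics for one modality's group contrast.

    Arrays are aligned with the row-major upper-triangle edge order of
    :func:`connodiff.connectomes.edge_ids`.  ``perm_p`` is NaN for edges
    whose permutation null was not computed.
    """

    modality: str
    n_parcels: int
    edge_i: np.ndarray  # 1-based node ids, i < j
    edge_j: np.ndarray
    u: np.ndarray
    z: np.ndarray
    p_param: np.ndarray
    r_effect: np.ndarray
    direction: np.ndarray  # +1 higher in A, -1 higher in B, 0 tied
    tested: np.ndarray  # False where the edge was zero in every subject
    candidate_mask: np.ndarray
    n_a: int
    n_b: int
    alpha: float
    perm_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]
    p_crit: float | None = None

    def __post_init__(self) -> None:
        m = self.edge_i.size
        if self.perm_p is None:
            self.perm_p = np.full(m, np.nan)
        if self.significant is None:
            self.significant = np.zeros(m, dtype=bool)

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    def candidate_edges(self) -> list[tuple[int, int]]:
        return [
            (int(i), int(j))
            for i, j in zip(self.edge_i[self.candidate_mask], self.edge_j[self.candidate_mask])
        ]

    def significant_edges(self) -> list[tuple[int, int]]:
        return [
            (int(i), int(j))
            for i, j in zip(self.edge_i[self.significant], self.edge_j[self.significant])
        ]

    def to_dataframe(self, all_edges: bool = False) -> pd.DataFrame:
        keep = np.ones(self.edge_i.size, dtype=bool) if all_edges else self.tested
        return pd.DataFrame(
            {
                "i": self.edge_i[keep],
                "j": self.edge_j[keep],
                "U": self.u[keep],
                "z": self.z[keep],
                "p_param": self.p_param[keep],
                "r_effect": self.r_effect[keep],
                "direction": [_DIR_NAMES[int(d)] for d in self.direction[keep]],
                "tested": self.tested[keep],
                "candidate": self.candidate_mask[keep],
                "perm_p": self.perm_p[keep],
                "significant": self.significant[keep],
            }
        )


def cohort_edge_matrix(cohort: CohortDataset, modality: str) -> tuple[np.ndarray, np.ndarray]:
    """(subjects x edges) data matrix and the group-A membership mask.

    Subjects lacking the modality are dropped; group A rows come first.
    """
    subs = cohort.with_modality(modality)
    label_a = cohort.contrast_labels[0]
    data = np.vstack([upper_vector(s.connectomes[modality].values) for s in subs])
    a_mask = np.array([s.group_label == label_a for s in subs])
    return data, a_mask


def edgewise_scan(cohort: CohortDataset, modality: str, alpha: float = 0.001) -> ContrastResult:
    """Mann-Whitney statistics for every node pair of one modality.

    Edges whose weight is zero in every subject of both groups (connections
    removed by thresholding or absent from the tractography backbone) are
    skipped: they carry no data and are never candidates.
    """
    cohort.validate(modality)
    data, a_mask = cohort_edge_matrix(cohort, modality)
    n_parcels = cohort.atlas.n_parcels
    u, z, p, sigma, _ = _rank_statistics(data, a_mask)
    tested = ~np.all(data == 0, axis=0)
    n_a = int(a_mask.sum())
    n_b = int((~a_mask).sum())
    d = u - n_a * n_b / 2.0
    direction = np.sign(d).astype(int)
    p = np.where(tested, p, 1.0)
    ei, ej = edge_ids(n_parcels)
    return ContrastResult(
        modality=modality,
        n_parcels=n_parcels,
        edge_i=ei,
        edge_j=ej,
        u=u,
        z=z,
        p_param=p,
        r_effect=np.abs(z) / np.sqrt(n_a + n_b),
        direction=direction,
        tested=tested,
        candidate_mask=tested & (p < alpha),
        n_a=n_a,
        n_b=n_b,
        alpha=alpha,
    )


def null_z_matrix(
    data: np.ndarray, schedule: PermutationSchedule, columns: np.ndarray | None = None
) -> np.ndarray:
    """|z| under every relabeling of the schedule, shape (G, n_edges).

    Ranks, tie structure and variance are label-invariant, so each iteration
    is a rank re-summation: R_A(g) = a_masks[g] @ ranks.
    """
    n = data.shape[0]
    a_mask0 = np.zeros(n, dtype=bool)  # tie stats independent of labels
    a_mask0[: schedule.n_a] = True
    _, _, _, sigma, ranks = _rank_statistics(data, a_mask0)
    if columns is not None:
        ranks = ranks[:, columns]
        sigma = sigma[columns]
    n_a = schedule.n_a
    n_b = n - n_a
    r_a = schedule.a_masks.astype(float) @ ranks
    u = r_a - n_a * (n_a + 1) / 2.0
    d = u - n_a * n_b / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(d) - 0.5, 0.0) / sigma
    z[:, sigma == 0] = 0.0
    return z


def permutation_test_edges(
    cohort: CohortDataset,
    modality: str,
    result: ContrastResult,
    schedule: PermutationSchedule,
    p_crit: float = 0.05,
    add_one: bool = False,
    all_edges: bool = False,
) -> ContrastResult:
    """Permutation p-values for the candidate edges (or all tested edges).

    perm_p = #{g : |z_null,g| >= |z_obs|} / G, or (count+1)/(G+1) with
    ``add_one=True`` (which cannot return exactly zero).  Fills ``perm_p``
    and ``significant`` (perm_p <= p_crit among candidates) on ``result``.
    """
    data, a_mask = cohort_edge_matrix(cohort, modality)
    if int(a_mask.sum()) != schedule.n_a or data.shape[0] != schedule.a_masks.shape[1]:
        raise ValueError("schedule group sizes do not match the cohort")
    cols = np.flatnonzero(result.tested if all_edges else result.candidate_mask)
    g = schedule.n_iterations
    perm_p = np.full(result.edge_i.size, np.nan)
    if cols.size:
        null_abs_z = null_z_matrix(data, schedule, columns=cols)
        obs = np.abs(result.z[cols])
        count = (null_abs_z >= obs[None, :]).sum(axis=0)
        perm_p[cols] = (count + 1) / (g + 1) if add_one else count / g
    result.perm_p = perm_p
    result.significant = result.candidate_mask & (perm_p <= p_crit)
    result.p_crit = p_crit
    return result


def contrast_analysis(
    cohort: CohortDataset,
    modality: str,
    alpha: float = 0.001,
    n_permutations: int = 10_000,
    p_crit: float = 0.05,
    add_one: bool = False,
    seed: int | None = None,
) -> ContrastResult:
    """Full edge-wise contrast: scan, schedule, permutation stage."""
    result = edgewise_scan(cohort, modality, alpha=alpha)
    data, a_mask = cohort_edge_matrix(cohort, modality)
    schedule = build_schedule(int(a_mask.sum()), int((~a_mask).sum()), n_permutations, seed)
    return permutation_test_edges(cohort, modality, result, schedule, p_crit=p_crit, add_one=add_one)
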