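"""Clinical correlations with permutation-based FDR control.

Edges incident to the cross-modality overlap nodes are correlated (Pearson)
with clinical severity, functioning and cognition scores within the case
group.  Significance uses a permutation scheme — the score vector is
shuffled across subjects and |r| recomputed for every tested edge — followed
by Benjamini-Hochberg correction over the tested edge family per score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectomes import CohortDataset
from .contrast import ContrastResult
from .overlap import bh_adjust

Edge = tuple[int, int]


def select_candidate_edges(
    intersect: set[int], contrast: ContrastResult, scope: str = "significant"
) -> list[Edge]:
    """Edges whose connectivity is tested against the clinical scores.

    ``scope="significant"`` (default): significant contrast edges with at
    least one endpoint in the intersect.  ``scope="all-incident"``: every
    atlas pair touching an intersect node (the broader reading).
    Deduplicated and sorted; an edge touching two intersect nodes appears
    once.
    """
    if scope == "significant":
        edges = {e for e in contrast.significant_edges() if e[0] in intersect or e[1] in intersect}
    elif scope == "all-incident":
        n = contrast.n_parcels
        edges = set()
        for a in intersect:
            for b in range(1, n + 1):
                if b != a:
                    edges.add((min(a, b), max(a, b)))
    else:
        raise ValueError("scope must be 'significant' or 'all-incident'")
    return sorted(edges)


def pearson_r(x, y) -> tuple[float, int]:
    """Product-moment correlation with pairwise deletion of missing values.

    Returns (r, df) with df = n - 2 over the complete pairs.  Raises on
    fewer than 3 complete pairs or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlated vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return r, n - 2


@dataclass
class EdgeCorrelation:
    edge: Edge
    score: str
    r: float
    df: int
    p_perm: float
    q: float = np.nan


def correlation_permutation_fdr(
    edge_values: np.ndarray,
    score: np.ndarray,
    n_iterations: int = 1_000,
    seed: int | None = None,
    null: str = "per-edge",
    add_one: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for |r| between one score and many edges.

    ``edge_values`` is (subjects x edges); rows with a missing score are
    dropped.  Each iteration permutes the score across subjects and
    recomputes |r| for every edge.  With ``null="per-edge"`` (default) each
    edge is compared against its own null; ``null="max"`` compares against
    the across-edge maximum (familywise control).  Returns (r_obs, p_perm).
    """
    edge_values = np.asarray(edge_values, dtype=float)
    score = np.asarray(score, dtype=float)
    if edge_values.ndim != 2 or edge_values.shape[0] != score.size:
        raise ValueError("edge_values must be (n_subjects, n_edges) matching the score")
    if edge_values.shape[1] == 0:
        raise ValueError("no edges to test")
    keep = np.isfinite(score)
    score = score[keep]
    edge_values = edge_values[keep]
    n = score.size
    if n < 3:
        raise ValueError("need at least 3 subjects with the score")
    if np.std(score) == 0:
        raise ValueError("score has zero variance")
    # canonical subject order (sorted by score) so the Monte-Carlo null is
    # exactly invariant to any common reordering of subjects
    order = np.argsort(score, kind="mergesort")
    score = score[order]
    edge_values = edge_values[order]

    def corr_with(s: np.ndarray) -> np.ndarray:
        sc = s - s.mean()
        ec = edge_values - edge_values.mean(axis=0)
        denom = np.sqrt((sc @ sc) * (ec * ec).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sc @ ec) / denom
        return np.where(denom > 0, r, 0.0)

    r_obs = corr_with(score)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(edge_values.shape[1])
    abs_obs = np.abs(r_obs)
    for _ in range(n_iterations):
        r_null = np.abs(corr_with(rng.permutation(score)))
        if null == "max":
            exceed += r_null.max() >= abs_obs
        elif null == "per-edge":
            exceed += r_null >= abs_obs
        else:
            raise ValueError("null must be 'per-edge' or 'max'")
    p = (exceed + 1) / (n_iterations + 1) if add_one else exceed / n_iterations
    return r_obs, p


def clinical_correlations(
    cohort: CohortDataset,
    modality: str,
    edges: list[Edge],
    scores: list[str],
    group: str | None = None,
    n_iterations: int = 1_000,
    seed: int | None = None,
    null: str = "per-edge",
    add_one: bool = False,
) -> pd.DataFrame:
    """Pearson r, permutation p and BH q for each (edge, score) pair.

    ``group`` restricts the analysis to one contrast group (by default the
    first contrast label — the case group); BH is applied per score over the
    tested edge family.  Returns a tidy DataFrame (i, j, score, r, df,
    p_perm, q).
    """
    if group is None:
        group = cohort.contrast_labels[0]
    subs = [s for s in cohort.group(group) if modality in s.connectomes]
    if not edges:
        return pd.DataFrame(columns=["i", "j", "score", "r", "df", "p_perm", "q"])
    values = np.array(
        [[s.connectomes[modality].values[i - 1, j - 1] for i, j in edges] for s in subs]
    )
    rows = []
    ss = np.random.SeedSequence(seed)
    for score_name, child in zip(scores, ss.spawn(len(scores))):
        sv = np.array([s.clinical_scores.get(score_name, np.nan) for s in subs])
        r_obs, p_perm = correlation_permutation_fdr(
            values,
            sv,
            n_iterations=n_iterations,
            seed=child,
            null=null,
            add_one=add_one,
        )
        q = bh_adjust(p_perm)
        n_complete = int(np.isfinite(sv).sum())
        for (i, j), r, pp, qq in zip(edges, r_obs, p_perm, q):
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "score": score_name,
                    "r": float(r),
                    "df": n_complete - 2,
                    "p_perm": float(pp),
                    "q": float(qq),
                }
            )
    return pd.DataFrame(rows)
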