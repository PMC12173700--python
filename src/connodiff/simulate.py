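"""Synthetic paired dMRI/rsfMRI cohorts with known ground truth.

The study's subject-level data are not openly deposited, so every downstream
stage is exercised on simulated cohorts that emulate the *outputs* of the
imaging pipeline (not the imaging itself):

* dMRI: sparse non-negative streamline-count matrices.  A random connected
  backbone carries negative-binomial counts (streamline counts are
  overdispersed relative to Poisson); off-backbone pairs are structural zeros.
* rsfMRI: Pearson-correlation matrices computed from finite multivariate
  normal time series drawn from a block-structured latent covariance, so
  sampling noise scales realistically with the number of volumes.
* Group effects are *planted*: a set of edges whose count mean (dMRI,
  multiplicative) or latent correlation (rsfMRI, additive) differs between
  the two groups, with a designated node set shared across modalities.
* Clinical scores are linear in the mean connectivity of designated planted
  edges plus Gaussian noise; motion summaries have a configurable fraction of
  high-motion outliers.

One global seed fans out to per-stage child seeds (numpy ``SeedSequence``)
so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectomes import (
    DMRI,
    RSFMRI,
    UNITS_COUNT,
    UNITS_R,
    CohortDataset,
    Connectome,
    SubjectRecord,
    default_atlas,
)

Edge = tuple[int, int]


def _norm_edge(e: Edge) -> Edge:
    i, j = int(e[0]), int(e[1])
    if i == j:
        raise ValueError(f"self-loop edge {e}")
    return (i, j) if i < j else (j, i)


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults describe a desk-scale cohort: 60 parcels (1,770 node pairs),
    30 vs 30 subjects, 150 functional volumes (matching a 5-minute run at a
    2-second repetition time), a 20%-dense structural backbone with mean
    count 30 and negative-binomial dispersion 8, and a 6-block functional
    community structure.  Effects default to zero (a null cohort); planted
    scenarios set the ``planted_*`` and ``effect_*`` fields.
    """

    n_parcels: int = 60
    n_group_a: int = 30
    n_group_b: int = 30
    group_labels: tuple[str, str] = ("CHR-P", "HC")

    # structural count model
    backbone_density: float = 0.2
    count_mean: float = 30.0
    count_dispersion: float = 8.0

    # functional model
    timeseries_length: int = 150
    n_blocks: int = 6
    within_block_r: float = 0.3
    between_block_r: float = 0.0

    # planted group effects (direction +1 = hyper in group A, -1 = hypo)
    planted_edges_dmri: list[Edge] = field(default_factory=list)
    planted_edges_rsfmri: list[Edge] = field(default_factory=list)
    planted_directions_dmri: list[int] | None = None
    planted_directions_rsfmri: list[int] | None = None
    overlap_nodes: list[int] = field(default_factory=list)
    effect_delta_dmri: float = 0.0  # multiplicative: mean * (1+delta) or /(1+delta)
    effect_delta_rsfmri: float = 0.0  # additive on the latent correlation

    # clinical coupling: score name -> (modality, edge subset); empty map
    # couples every score to all planted dMRI edges when beta != 0
    clinical_beta: float = 0.0
    clinical_noise_sd: float = 1.0
    clinical_targets: dict[str, tuple[str, list[Edge]]] = field(default_factory=dict)

    # motion
    motion_baseline_mm: float = 0.2
    motion_spread: float = 0.25  # lognormal sigma of the baseline
    motion_outlier_fraction: float = 0.0
    motion_outlier_factor: float = 10.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.backbone_density <= 1):
            raise ValueError("backbone_density must be in (0, 1]")
        if not (0 <= self.motion_outlier_fraction < 0.5):
            raise ValueError("motion_outlier_fraction must be in [0, 0.5)")
        if self.n_parcels < 2 or self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("all sizes must be >= 2")
        if self.effect_delta_dmri < 0 or self.effect_delta_rsfmri < 0:
            raise ValueError("effect deltas must be >= 0")
        self.planted_edges_dmri = [_norm_edge(e) for e in self.planted_edges_dmri]
        self.planted_edges_rsfmri = [_norm_edge(e) for e in self.planted_edges_rsfmri]
        for e in self.planted_edges_dmri + self.planted_edges_rsfmri:
            if not (1 <= e[0] <= self.n_parcels and 1 <= e[1] <= self.n_parcels):
                raise ValueError(f"planted edge {e} outside 1..{self.n_parcels}")
        touched_d = {n for e in self.planted_edges_dmri for n in e}
        touched_r = {n for e in self.planted_edges_rsfmri for n in e}
        for n in self.overlap_nodes:
            if n not in touched_d or n not in touched_r:
                raise ValueError(f"overlap node {n} not touched by both planted edge sets")

    def directions(self, modality: str) -> np.ndarray:
        edges = self.planted_edges_dmri if modality == DMRI else self.planted_edges_rsfmri
        dirs = (
            self.planted_directions_dmri if modality == DMRI else self.planted_directions_rsfmri
        )
        if dirs is None:
            return np.ones(len(edges), dtype=int)
        if len(dirs) != len(edges):
            raise ValueError("planted direction list length must match edge list")
        arr = np.asarray(dirs, dtype=int)
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError("directions must be +1 (hyper in A) or -1 (hypo in A)")
        return arr


@dataclass
class PlantedTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    planted_edges: dict[str, list[Edge]]
    planted_directions: dict[str, np.ndarray]
    overlap_nodes: list[int]
    clinical_targets: dict[str, tuple[str, list[Edge]]]
    motion_outliers: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def make_backbone(
    n: int,
    density: float,
    rng: np.random.Generator,
    include_edges: list[Edge] | None = None,
) -> np.ndarray:
    """Random connected binary adjacency with expected edge fraction ≈ density.

    A uniform random spanning tree (random-walk insertion) guarantees
    connectivity; extra edges are added uniformly until the target count.
    ``include_edges`` are forced into the backbone (counted toward density).
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    adj = np.zeros((n, n), dtype=bool)
    order = rng.permutation(n)
    for k in range(1, n):  # random tree: attach each node to a previous one
        prev = order[rng.integers(0, k)]
        adj[order[k], prev] = adj[prev, order[k]] = True
    if include_edges:
        for i, j in include_edges:
            adj[i - 1, j - 1] = adj[j - 1, i - 1] = True
    target = int(round(density * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    free = ~adj[iu, ju]
    deficit = target - int(np.count_nonzero(adj[iu, ju]))
    if deficit > 0:
        pick = rng.choice(np.flatnonzero(free), size=min(deficit, int(free.sum())), replace=False)
        adj[iu[pick], ju[pick]] = True
        adj[ju[pick], iu[pick]] = True
    np.fill_diagonal(adj, False)
    return adj


def simulate_dmri(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Connectome], PlantedTruth]:
    """Streamline-count connectomes for both groups with planted effects.

    Counts on backbone edges are negative-binomial with mean ``count_mean``
    and dispersion k (variance mu + mu^2/k); group A's mean on planted edges
    is multiplied by (1+delta) for hyper edges and divided for hypo edges.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_parcels
    backbone = make_backbone(n, config.backbone_density, rng, include_edges=config.planted_edges_dmri)
    for i, j in config.planted_edges_dmri:
        if not backbone[i - 1, j - 1]:
            raise ValueError(f"planted edge {(i, j)} is off the backbone")

    mean_b = np.where(backbone, config.count_mean, 0.0)
    mean_a = mean_b.copy()
    dirs = config.directions(DMRI)
    for (i, j), d in zip(config.planted_edges_dmri, dirs):
        f = (1 + config.effect_delta_dmri) if d > 0 else 1.0 / (1 + config.effect_delta_dmri)
        mean_a[i - 1, j - 1] = mean_a[j - 1, i - 1] = config.count_mean * f

    k = config.count_dispersion
    iu, ju = np.triu_indices(n, k=1)

    def draw(mean: np.ndarray, sid: str) -> Connectome:
        mu = mean[iu, ju]
        vals = np.zeros_like(mu)
        on = mu > 0
        # NB(k, p) with p = k/(k+mu) has mean mu and variance mu + mu^2/k
        vals[on] = rng.negative_binomial(k, k / (k + mu[on]))
        m = np.zeros((n, n))
        m[iu, ju] = vals
        m[ju, iu] = vals
        return Connectome(subject_id=sid, modality=DMRI, values=m, units=UNITS_COUNT).validate()

    conns = [draw(mean_a, f"A{s:03d}") for s in range(config.n_group_a)]
    conns += [draw(mean_b, f"B{s:03d}") for s in range(config.n_group_b)]
    truth = PlantedTruth(
        planted_edges={DMRI: list(config.planted_edges_dmri)},
        planted_directions={DMRI: dirs},
        overlap_nodes=list(config.overlap_nodes),
        clinical_targets=dict(config.clinical_targets),
    )
    return conns, truth


def _block_correlation(config: SimulationConfig) -> np.ndarray:
    n, b = config.n_parcels, config.n_blocks
    block = np.repeat(np.arange(b), int(np.ceil(n / b)))[:n]
    same = block[:, None] == block[None, :]
    c = np.where(same, config.within_block_r, config.between_block_r).astype(float)
    np.fill_diagonal(c, 1.0)
    return c


def nearest_positive_definite(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to positive definiteness by clipping its
    eigenvalues at ``floor`` and rescaling back to unit diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w.min() < floor:
        c = (v * np.clip(w, floor, None)) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
    return c


def simulate_rsfmri(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Connectome], PlantedTruth]:
    """Sample-correlation connectomes from block-structured latent covariance.

    Group A's latent correlation is shifted by ±delta on the planted edges
    (then projected to the nearest positive-definite correlation matrix);
    each subject contributes the Pearson correlation matrix of T multivariate
    normal samples, so finite-T noise is realistic.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, t = config.n_parcels, config.timeseries_length
    if t < 3:
        raise ValueError("timeseries_length must be >= 3")
    c_b = _block_correlation(config)
    c_a = c_b.copy()
    dirs = config.directions(RSFMRI)
    for (i, j), d in zip(config.planted_edges_rsfmri, dirs):
        shifted = np.clip(c_a[i - 1, j - 1] + d * config.effect_delta_rsfmri, -0.99, 0.99)
        c_a[i - 1, j - 1] = c_a[j - 1, i - 1] = shifted
    c_a = nearest_positive_definite(c_a)
    c_b = nearest_positive_definite(c_b)
    l_a = np.linalg.cholesky(c_a)
    l_b = np.linalg.cholesky(c_b)

    def draw(l: np.ndarray, sid: str) -> Connectome:
        x = rng.standard_normal((t, n)) @ l.T
        r = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(r, 0.0)
        return Connectome(subject_id=sid, modality=RSFMRI, values=r, units=UNITS_R).validate()

    conns = [draw(l_a, f"A{s:03d}") for s in range(config.n_group_a)]
    conns += [draw(l_b, f"B{s:03d}") for s in range(config.n_group_b)]
    truth = PlantedTruth(
        planted_edges={RSFMRI: list(config.planted_edges_rsfmri)},
        planted_directions={RSFMRI: dirs},
        overlap_nodes=list(config.overlap_nodes),
        clinical_targets=dict(config.clinical_targets),
    )
    return conns, truth


def simulate_clinical(
    subjects: list[SubjectRecord],
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SubjectRecord]:
    """Fill clinical scores: score = beta * mean connectivity over the
    designated planted-edge subset + N(0, noise_sd).

    With an empty ``clinical_targets`` map, every score is coupled to all
    planted dMRI edges (or pure noise when there are none / beta = 0).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    targets = dict(config.clinical_targets)
    if not targets:
        d_edges = truth.planted_edges.get(DMRI, [])
        targets = {s: (DMRI, list(d_edges)) for s in ("caarms_total", "spia_total", "gaf", "bacs_total")}
    truth.clinical_targets = targets
    for s in subjects:
        for score, (modality, edges) in targets.items():
            noise = rng.normal(0.0, config.clinical_noise_sd)
            if config.clinical_beta == 0 or not edges:
                s.clinical_scores[score] = noise
                continue
            if modality not in s.connectomes:
                continue  # excluded modality: leave the score missing
            v = s.connectomes[modality].values
            try:
                signal = float(np.mean([v[i - 1, j - 1] for i, j in edges]))
            except IndexError as e:
                raise ValueError("designated clinical edge outside the atlas") from e
            s.clinical_scores[score] = config.clinical_beta * signal + noise
    return subjects


def simulate_motion(
    subjects: list[SubjectRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SubjectRecord], dict[str, list[str]]]:
    """Fill per-modality motion summaries (mm): lognormal baseline around
    ``motion_baseline_mm`` with a planted fraction of large outliers."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    outliers: dict[str, list[str]] = {DMRI: [], RSFMRI: []}
    n = len(subjects)
    n_out = int(round(config.motion_outlier_fraction * n))
    for modality in (DMRI, RSFMRI):
        base = config.motion_baseline_mm * rng.lognormal(0.0, config.motion_spread, size=n)
        idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
        base[idx] *= config.motion_outlier_factor
        for s, v in zip(subjects, base):
            s.motion_summary[modality] = float(v)
        outliers[modality] = [subjects[i].subject_id for i in idx]
    return subjects, outliers


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, PlantedTruth]:
    """Full paired cohort: atlas, both modalities, motion and clinical scores.

    The global seed spawns independent child streams for the dMRI, rsfMRI,
    motion and clinical stages, so e.g. changing the clinical noise does not
    perturb the connectomes.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_d, rng_r, rng_m, rng_c = (np.random.default_rng(s) for s in ss.spawn(4))
    d_conns, d_truth = simulate_dmri(config, rng_d)
    r_conns, r_truth = simulate_rsfmri(config, rng_r)
    label_a, label_b = config.group_labels
    subjects = []
    for idx, (cd, cr) in enumerate(zip(d_conns, r_conns)):
        group = label_a if idx < config.n_group_a else label_b
        subjects.append(
            SubjectRecord(
                subject_id=cd.subject_id,
                group_label=group,
                connectomes={DMRI: cd, RSFMRI: cr},
            )
        )
    truth = PlantedTruth(
        planted_edges={**d_truth.planted_edges, **r_truth.planted_edges},
        planted_directions={**d_truth.planted_directions, **r_truth.planted_directions},
        overlap_nodes=list(config.overlap_nodes),
        clinical_targets=dict(config.clinical_targets),
    )
    subjects, truth.motion_outliers = simulate_motion(subjects, config, rng_m)
    subjects = simulate_clinical(subjects, truth, config, rng_c)
    cohort = CohortDataset(
        atlas=default_atlas(config.n_parcels),
        subjects=subjects,
        contrast_labels=(label_a, label_b),
    )
    return cohort.validate(), truth


def planted_scenario(
    n_parcels: int = 60,
    n_group_a: int = 30,
    n_group_b: int = 30,
    effect_delta_dmri: float = 4.0,
    effect_delta_rsfmri: float = 0.55,
    clinical_beta: float = 0.0,
    clinical_noise_sd: float = 1.0,
    seed: int = 0,
) -> SimulationConfig:
    """A standard planted-effect scenario used across recovery tests.

    Two six-node planted subnetworks (a path plus chords, so each is one
    connected component) sharing three nodes across modalities:

    * dMRI edges among nodes 1..6 (mixed hyper/hypo),
    * rsfMRI edges among nodes 4..9 (hyper, planted on between-block pairs),
    * designated cross-modality overlap nodes {4, 5, 6}.
    """
    if n_parcels < 12:
        raise ValueError("planted scenario needs at least 12 parcels")
    dmri_edges = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (1, 3), (2, 4)]
    dmri_dirs = [1, 1, 1, -1, -1, 1, 1]
    rsf_edges = [(4, 5), (5, 6), (6, 7), (7, 8), (8, 9), (4, 6), (5, 7)]
    return SimulationConfig(
        n_parcels=n_parcels,
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        planted_edges_dmri=dmri_edges,
        planted_directions_dmri=dmri_dirs,
        planted_edges_rsfmri=rsf_edges,
        overlap_nodes=[4, 5, 6],
        effect_delta_dmri=effect_delta_dmri,
        effect_delta_rsfmri=effect_delta_rsfmri,
        clinical_beta=clinical_beta,
        clinical_noise_sd=clinical_noise_sd,
        seed=seed,
    )
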