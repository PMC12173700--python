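"""Connectome data model, file I/O and connectome-level quality control.

The analysis operates on per-subject square symmetric connectivity matrices
defined on a shared cortical parcellation: streamline-count matrices from
probabilistic tractography (dMRI) and Pearson-correlation matrices from
resting-state fMRI parcel time courses.  This module holds the in-memory
containers (:class:`Parcel`, :class:`Atlas`, :class:`Connectome`,
:class:`SubjectRecord`, :class:`CohortDataset`), plain-text readers/writers
(dense TSV and MatrixMarket), and the quality-control transformations applied
before any group comparison: absolute thresholding of counts at a minimum
streamline count, absolute thresholding of correlations, Fisher r-to-z
variance stabilisation, and motion-based participant exclusion.

Node ids are 1-based throughout the public API (matching how parcels are
referred to in atlas tables); matrices are 0-indexed internally and
``node_id = row_index + 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

DMRI = "dmri"
RSFMRI = "rsfmri"
MODALITIES = (DMRI, RSFMRI)

UNITS_COUNT = "streamline-count"
UNITS_R = "pearson-r"
UNITS_Z = "fisher-z"

#: default units of a raw connectome per modality
DEFAULT_UNITS = {DMRI: UNITS_COUNT, RSFMRI: UNITS_R}

CLINICAL_SCORES = ("caarms_total", "spia_total", "gaf", "bacs_total")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Parcel:
    """One atlas parcel (graph node)."""

    node_id: int
    hemisphere: str
    network_label: str = "None"
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if self.node_id < 1:
            raise ValueError("node_id must be >= 1")


@dataclass(frozen=True)
class Atlas:
    """An ordered parcellation; node ids are exactly 1..n_parcels."""

    parcels: tuple[Parcel, ...]

    def __post_init__(self) -> None:
        ids = [p.node_id for p in self.parcels]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("atlas node_ids must be exactly 1..n_parcels in order")

    @property
    def n_parcels(self) -> int:
        return len(self.parcels)

    @property
    def n_pairs(self) -> int:
        return n_node_pairs(self.n_parcels)

    def parcel(self, node_id: int) -> Parcel:
        return self.parcels[node_id - 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": [p.node_id for p in self.parcels],
                "hemisphere": [p.hemisphere for p in self.parcels],
                "network_label": [p.network_label for p in self.parcels],
                "region_label": [p.region_label for p in self.parcels],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Atlas":
        df = df.sort_values("node_id")
        parcels = tuple(
            Parcel(
                node_id=int(r.node_id),
                hemisphere=str(r.hemisphere),
                network_label=str(r.network_label),
                region_label=str(r.region_label),
            )
            for r in df.itertuples()
        )
        return cls(parcels)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Atlas":
        # keep_default_na=False: the literal network label "None" must not
        # be parsed as missing data
        return cls.from_dataframe(
            pd.read_csv(path, sep="\t", dtype={"node_id": int}, keep_default_na=False)
        )


#: the 12 large-scale network labels of the Gordon-style parcellation, plus
#: "None" for parcels outside any named network
NETWORK_LABELS = (
    "Auditory",
    "CinguloOperc",
    "CinguloParietal",
    "Default",
    "DorsalAttn",
    "FrontoParietal",
    "RetrosplenialTemporal",
    "Salience",
    "SMhand",
    "SMmouth",
    "VentralAttn",
    "Visual",
)


def default_atlas(n_parcels: int) -> Atlas:
    """A synthetic atlas: left hemisphere first half, networks round-robin.

    Stands in for a real parcellation metadata table when simulating cohorts.
    """
    if n_parcels < 2:
        raise ValueError("an atlas needs at least 2 parcels")
    labels = NETWORK_LABELS + ("None",)
    parcels = tuple(
        Parcel(
            node_id=i + 1,
            hemisphere="L" if i < n_parcels // 2 else "R",
            network_label=labels[i % len(labels)],
            region_label=f"parcel_{i + 1}",
        )
        for i in range(n_parcels)
    )
    return Atlas(parcels)


@dataclass
class Connectome:
    """One subject's symmetric connectivity matrix with a modality tag."""

    subject_id: str
    modality: str
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    def validate(self) -> "Connectome":
        """Check the invariants: square, symmetric, zero diagonal, finite,
        and non-negative for streamline counts.  Returns self."""
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectome matrix contains non-finite values")
        if not np.allclose(v, v.T):
            raise ValueError("connectome matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectome diagonal must be zero (no self-loops)")
        if self.units == UNITS_COUNT and np.any(v < 0):
            raise ValueError("streamline counts must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        return self

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "Connectome":
        return Connectome(
            subject_id=self.subject_id,
            modality=self.modality,
            values=values,
            units=self.units if units is None else units,
        )


@dataclass
class SubjectRecord:
    """One participant: group label, motion summaries, clinical scores and
    per-modality connectomes (a modality is absent if excluded/missing)."""

    subject_id: str
    group_label: str
    motion_summary: dict[str, float] = field(default_factory=dict)
    clinical_scores: dict[str, float] = field(default_factory=dict)
    connectomes: dict[str, Connectome] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, v in self.motion_summary.items():
            if v < 0:
                raise ValueError(f"motion summary for {m} must be >= 0")


@dataclass
class CohortDataset:
    """A cohort on a shared atlas with an ordered pair of contrast labels.

    ``contrast_labels = (A, B)`` fixes which group is "A" in every downstream
    statistic (direction conventions, group sizes)."""

    atlas: Atlas
    subjects: list[SubjectRecord]
    contrast_labels: tuple[str, str]

    def validate(self, modality: str | None = None) -> "CohortDataset":
        a, b = self.contrast_labels
        for s in self.subjects:
            if s.group_label not in self.contrast_labels:
                raise ValueError(
                    f"subject {s.subject_id} group {s.group_label!r} not in {self.contrast_labels}"
                )
            for c in s.connectomes.values():
                if c.n_parcels != self.atlas.n_parcels:
                    raise ValueError("connectome dimension does not match atlas")
        mods = [modality] if modality else list(MODALITIES)
        for m in mods:
            for g in (a, b):
                n = sum(1 for s in self.subjects if s.group_label == g and m in s.connectomes)
                if n < 2:
                    raise ValueError(f"group {g!r} has fewer than 2 subjects with a {m} connectome")
        return self

    def group(self, label: str, modality: str | None = None) -> list[SubjectRecord]:
        subs = [s for s in self.subjects if s.group_label == label]
        if modality is not None:
            subs = [s for s in subs if modality in s.connectomes]
        return subs

    def with_modality(self, modality: str) -> list[SubjectRecord]:
        """Subjects of either contrast group carrying the modality, group A first."""
        a, b = self.contrast_labels
        return self.group(a, modality) + self.group(b, modality)


# ---------------------------------------------------------------------------
# edge indexing helpers


def n_node_pairs(n: int) -> int:
    """Number of unordered node pairs among ``n`` parcels: n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 parcels")
    return n * (n - 1) // 2


def edge_ids(n: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based (i, j) arrays for every unordered pair i < j, row-major."""
    iu, ju = np.triu_indices(n, k=1)
    return iu + 1, ju + 1


def upper_vector(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle in the same order as :func:`edge_ids`."""
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju]


def vector_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`upper_vector`: symmetric matrix with zero diagonal."""
    m = np.zeros((n, n), dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = vec
    m[ju, iu] = vec
    return m


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path: str | Path, format: str | None = None, n_expected: int | None = None) -> np.ndarray:
    """Read a square connectivity matrix from dense TSV or MatrixMarket.

    ``format`` is ``"dense-tsv"`` or ``"matrix-market"``; inferred from the
    extension (.tsv / .mtx) when None.  Symmetry is deliberately NOT enforced
    here — raw directed tract counts may be asymmetric.
    """
    path = Path(path)
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "dense-tsv"
    if format == "dense-tsv":
        try:
            m = np.loadtxt(path, delimiter="\t", dtype=float, ndmin=2)
        except ValueError as e:
            raise ValueError(f"non-numeric cell in {path}: {e}") from e
    elif format == "matrix-market":
        m = sio.mmread(path)
        if sparse.issparse(m):
            m = m.toarray()
        m = np.asarray(m, dtype=float)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {m.shape}")
    if n_expected is not None and m.shape[0] != n_expected:
        raise ValueError(f"matrix in {path} has {m.shape[0]} rows, expected {n_expected}")
    return m


def write_matrix(path: str | Path, matrix: np.ndarray, format: str | None = None) -> None:
    """Write a square matrix as dense TSV or MatrixMarket coordinate format."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "dense-tsv"
    if format == "dense-tsv":
        np.savetxt(path, matrix, delimiter="\t", fmt="%.17g")
    elif format == "matrix-market":
        sio.mmwrite(str(path), sparse.coo_matrix(matrix))
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def write_connectome(path: str | Path, c: Connectome, format: str | None = None) -> None:
    """Write a connectome matrix plus a sidecar JSON header."""
    write_matrix(path, c.values, format=format)
    header = {
        "subject_id": c.subject_id,
        "modality": c.modality,
        "units": c.units,
        "n_parcels": c.n_parcels,
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))


def read_connectome(path: str | Path, format: str | None = None) -> Connectome:
    """Read a connectome written by :func:`write_connectome`."""
    header = json.loads(Path(str(path) + ".json").read_text())
    values = read_matrix(path, format=format, n_expected=header["n_parcels"])
    return Connectome(
        subject_id=header["subject_id"],
        modality=header["modality"],
        values=values,
        units=header["units"],
    )


# ---------------------------------------------------------------------------
# quality-control transformations


def symmetrize(values: np.ndarray, method: str = "mean") -> np.ndarray:
    """Symmetrize a square matrix (mean/min/max of the two directions) and
    zero the diagonal.

    Probabilistic tractography counts are directional; the analysis treats
    node pairs as undirected, so directed counts are reduced to one value per
    pair before anything else.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if method == "mean":
        out = (values + values.T) / 2.0
    elif method == "min":
        out = np.minimum(values, values.T)
    elif method == "max":
        out = np.maximum(values, values.T)
    else:
        raise ValueError(f"unknown symmetrization method {method!r}")
    np.fill_diagonal(out, 0.0)
    return out


def apply_dmri_threshold(c: Connectome, min_count: float = 10) -> Connectome:
    """Zero out streamline counts below ``min_count`` (entries equal to the
    threshold are kept).  Removes spurious low-count connections."""
    if c.units != UNITS_COUNT:
        raise ValueError(f"dMRI threshold expects units {UNITS_COUNT!r}, got {c.units!r}")
    v = c.values.copy()
    v[v < min_count] = 0.0
    return c.copy_with(v)


def apply_rsfmri_threshold(c: Connectome, r_min: float = 0.05) -> Connectome:
    """Zero out correlations with absolute value <= ``r_min``; retained
    entries keep their sign (strict ``|r| > r_min`` survives)."""
    if c.units != UNITS_R:
        raise ValueError(f"rsfMRI threshold expects units {UNITS_R!r}, got {c.units!r}")
    if np.any(np.abs(c.values) > 1 + 1e-12):
        raise ValueError("correlation entries must satisfy |r| <= 1")
    v = c.values.copy()
    v[np.abs(v) <= r_min] = 0.0
    return c.copy_with(v)


def fisher_z_transform(c: Connectome) -> Connectome:
    """Fisher r-to-z: z = atanh(r) on every retained (nonzero) entry.

    Applied after absolute thresholding, so |r| = 1 entries have already been
    ruled out by the caller's pipeline; they raise here regardless.
    """
    if c.units != UNITS_R:
        raise ValueError(f"Fisher transform expects units {UNITS_R!r}, got {c.units!r}")
    v = c.values
    nonzero = v != 0
    if np.any(np.abs(v[nonzero]) >= 1):
        raise ValueError("|r| >= 1 on a retained entry; cannot Fisher-transform")
    out = np.zeros_like(v)
    out[nonzero] = np.arctanh(v[nonzero])
    return c.copy_with(out, units=UNITS_Z)


def motion_exclude(
    subjects: list[SubjectRecord],
    modality: str,
    n_sd: float = 1.0,
    sided: str = "upper",
    pooled: bool = True,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition subjects into (kept, excluded) by the motion rule.

    A subject is excluded when its motion summary for ``modality`` exceeds
    mean + ``n_sd``·SD (sample SD) of the reference sample — the pooled cohort
    by default, or each subject's own group when ``pooled=False``.  With
    ``sided="both"`` subjects below mean − n_sd·SD are excluded too; the
    default is one-sided (only high movers are removed).
    """
    if sided not in ("upper", "both"):
        raise ValueError("sided must be 'upper' or 'both'")
    for s in subjects:
        if modality not in s.motion_summary:
            raise ValueError(f"subject {s.subject_id} has no motion summary for {modality}")

    def bounds(vals: np.ndarray) -> tuple[float, float]:
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        lo = mean - n_sd * sd if sided == "both" else -np.inf
        return lo, mean + n_sd * sd

    if pooled:
        cuts = {None: bounds(np.array([s.motion_summary[modality] for s in subjects]))}
        key = lambda s: None  # noqa: E731
    else:
        groups = sorted({s.group_label for s in subjects})
        cuts = {
            g: bounds(np.array([s.motion_summary[modality] for s in subjects if s.group_label == g]))
            for g in groups
        }
        key = lambda s: s.group_label  # noqa: E731

    kept, excluded = [], []
    for s in subjects:
        lo, hi = cuts[key(s)]
        v = s.motion_summary[modality]
        (excluded if (v > hi or v < lo) else kept).append(s)
    return kept, excluded


def qc_connectome(c: Connectome, dmri_min_count: float = 10, rsfmri_abs_r: float = 0.05) -> Connectome:
    """Full per-connectome QC: symmetrized input assumed; thresholds the
    matrix by modality and Fisher-transforms correlations."""
    if c.modality == DMRI:
        return apply_dmri_threshold(c, dmri_min_count)
    return fisher_z_transform(apply_rsfmri_threshold(c, rsfmri_abs_r))


# ---------------------------------------------------------------------------
# cohort I/O (manifest + matrices in a directory)


MANIFEST_COLUMNS = [
    "subject_id",
    "group_label",
    "motion_dmri",
    "motion_rsfmri",
    "caarms_total",
    "spia_total",
    "gaf",
    "bacs_total",
    "path_dmri",
    "path_rsfmri",
]


def write_cohort(directory: str | Path, cohort: CohortDataset, matrix_format: str = "dense-tsv") -> Path:
    """Write a cohort directory: manifest.csv, atlas.tsv and one matrix file
    (plus JSON sidecar) per subject per present modality."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "matrices").mkdir(exist_ok=True)
    ext = ".mtx" if matrix_format == "matrix-market" else ".tsv"
    rows = []
    for s in cohort.subjects:
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "group_label": s.group_label,
            "motion_dmri": s.motion_summary.get(DMRI, np.nan),
            "motion_rsfmri": s.motion_summary.get(RSFMRI, np.nan),
        }
        for score in CLINICAL_SCORES:
            row[score] = s.clinical_scores.get(score, np.nan)
        for m in MODALITIES:
            col = f"path_{m}"
            if m in s.connectomes:
                rel = f"matrices/{s.subject_id}_{m}{ext}"
                write_connectome(directory / rel, s.connectomes[m], format=matrix_format)
                row[col] = rel
            else:
                row[col] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(directory / "manifest.csv", index=False)
    cohort.atlas.to_tsv(directory / "atlas.tsv")
    return directory


def load_cohort(
    directory: str | Path,
    contrast_labels: tuple[str, str] | None = None,
    group_column: str = "group_label",
) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`.

    ``group_column`` allows re-running the whole pipeline on an alternative
    grouping column of the same manifest (e.g. a symptom-persistence label)
    without any other code change.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", dtype={"subject_id": str})
    atlas = Atlas.from_tsv(directory / "atlas.tsv")
    if group_column not in manifest.columns:
        raise ValueError(f"manifest has no column {group_column!r}")
    subjects = []
    for r in manifest.itertuples():
        motion = {}
        for m in MODALITIES:
            v = getattr(r, f"motion_{m}")
            if pd.notna(v):
                motion[m] = float(v)
        scores = {}
        for score in CLINICAL_SCORES:
            v = getattr(r, score)
            if pd.notna(v):
                scores[score] = float(v)
        conns = {}
        for m in MODALITIES:
            rel = getattr(r, f"path_{m}")
            if isinstance(rel, str) and rel:
                conns[m] = read_connectome(directory / rel)
        subjects.append(
            SubjectRecord(
                subject_id=str(r.subject_id),
                group_label=str(getattr(r, group_column)),
                motion_summary=motion,
                clinical_scores=scores,
                connectomes=conns,
            )
        )
    if contrast_labels is None:
        labels = sorted({s.group_label for s in subjects})
        if len(labels) != 2:
            raise ValueError(f"cohort has {len(labels)} group labels; pass contrast_labels explicitly")
        contrast_labels = (labels[0], labels[1])
    return CohortDataset(atlas=atlas, subjects=subjects, contrast_labels=contrast_labels)
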