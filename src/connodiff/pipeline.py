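"""End-to-end orchestration: configuration, staged runs, report assembly.

A run goes: (simulate →) qc → edge-wise contrast per modality → subnetwork
extraction → cross-modality overlap → clinical correlations → cohort
statistics.  Stages communicate through plain-text files (TSV/JSON) in the
output directory so each CLI stage is independently runnable, and a
:class:`RunManifest` records the config snapshot, per-stage seeds, output
hashes and timings so any run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import clinical_correlations, select_candidate_edges
from .connectomes import (
    DMRI,
    MODALITIES,
    RSFMRI,
    CLINICAL_SCORES,
    CohortDataset,
    load_cohort,
    motion_exclude,
    qc_connectome,
)
from .contrast import ContrastResult, contrast_analysis, _DIR_NAMES
from .cohort_stats import mwu_rosenthal
from .overlap import OverlapResult, overlap_analysis
from .subnetworks import DifferenceGraph, analyse_subnetworks


# ---------------------------------------------------------------------------
# configuration


@dataclass
class QCConfig:
    dmri_min_count: float = 10.0
    rsfmri_abs_r: float = 0.05
    motion_sd: float = 1.0
    motion_sidedness: str = "upper"
    motion_pooled: bool = True

    def __post_init__(self) -> None:
        if self.dmri_min_count <= 0 or self.rsfmri_abs_r <= 0 or self.motion_sd <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.motion_sidedness not in ("upper", "both"):
            raise ValueError("motion_sidedness must be 'upper' or 'both'")


@dataclass
class ContrastConfig:
    alpha: float = 0.001
    permutations: int = 10_000
    p_crit: float = 0.05
    add_one: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1) or not (0 <= self.p_crit <= 1):
            raise ValueError("alpha and p_crit must lie in [0, 1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


@dataclass
class OverlapConfig:
    permutations: int = 10_000
    shared_relabeling: bool = False
    q_crit: float = 0.05

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


@dataclass
class ClinicalConfig:
    permutations: int = 1_000
    scores: tuple[str, ...] = CLINICAL_SCORES
    edge_scope: str = "significant"
    null: str = "per-edge"

    def __post_init__(self) -> None:
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.edge_scope not in ("significant", "all-incident"):
            raise ValueError("edge_scope must be 'significant' or 'all-incident'")


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults are the published protocol values
    (count threshold 10, |r| > 0.05, alpha = 0.001, 10,000 contrast/overlap
    permutations, 1,000 clinical permutations, ±1 SD motion rule)."""

    cohort_dir: str = ""
    output_dir: str = "out"
    group_column: str = "group_label"
    contrast_labels: tuple[str, str] | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)
    seed: int = 0


_SECTIONS = {"qc": QCConfig, "contrast": ContrastConfig, "overlap": OverlapConfig, "clinical": ClinicalConfig}


def _build_section(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "scores" in data:
        data = {**data, "scores": tuple(data["scores"])}
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a plain dict; unknown keys and
    out-of-range values are rejected."""
    data = dict(data or {})
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value)
        elif key == "contrast_labels" and value is not None:
            if len(value) != 2:
                raise ValueError("contrast_labels must name exactly two groups")
            kwargs[key] = (str(value[0]), str(value[1]))
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    if not isinstance(cfg.seed, int):
        raise ValueError("seed must be an integer")
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML or JSON pipeline config file; defaults fill every
    omitted parameter."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["clinical"]["scores"] = list(d["clinical"]["scores"])
    if d.get("contrast_labels") is not None:
        d["contrast_labels"] = list(d["contrast_labels"])
    return d


# ---------------------------------------------------------------------------
# stages


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage integer seeds (< 2^31) from the global seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def apply_qc(cohort: CohortDataset, qc: QCConfig) -> tuple[CohortDataset, dict]:
    """Motion exclusion and matrix-level QC per modality.

    A subject excluded for motion in one modality keeps the other; matrices
    of kept subjects are thresholded (and Fisher-transformed for rsfMRI).
    """
    excluded_log: dict[str, list[str]] = {}
    new_subjects = {s.subject_id: dataclasses.replace(s, connectomes=dict(s.connectomes)) for s in cohort.subjects}
    for modality in MODALITIES:
        have = [s for s in cohort.subjects if modality in s.connectomes]
        with_motion = [s for s in have if modality in s.motion_summary]
        if with_motion and len(with_motion) == len(have):
            kept, excluded = motion_exclude(
                have, modality, n_sd=qc.motion_sd, sided=qc.motion_sidedness, pooled=qc.motion_pooled
            )
        else:  # no motion summaries recorded: keep everyone
            kept, excluded = have, []
        excluded_log[modality] = [s.subject_id for s in excluded]
        for s in excluded:
            new_subjects[s.subject_id].connectomes.pop(modality, None)
        for s in kept:
            c = qc_connectome(
                s.connectomes[modality], dmri_min_count=qc.dmri_min_count, rsfmri_abs_r=qc.rsfmri_abs_r
            )
            new_subjects[s.subject_id].connectomes[modality] = c
    out = CohortDataset(
        atlas=cohort.atlas,
        subjects=list(new_subjects.values()),
        contrast_labels=cohort.contrast_labels,
    )
    return out.validate(), excluded_log


def contrast_sidecar(result: ContrastResult) -> dict:
    return {
        "modality": result.modality,
        "n_parcels": result.n_parcels,
        "n_a": result.n_a,
        "n_b": result.n_b,
        "alpha": result.alpha,
        "p_crit": result.p_crit,
    }


def write_contrast(result: ContrastResult, path: Path) -> None:
    result.to_dataframe(all_edges=True).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(json.dumps(contrast_sidecar(result), indent=1))


def read_contrast(path: Path) -> ContrastResult:
    """Reconstruct a ContrastResult from the TSV + JSON pair written by
    :func:`write_contrast`."""
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    name_to_dir = {v: k for k, v in _DIR_NAMES.items()}
    return ContrastResult(
        modality=meta["modality"],
        n_parcels=meta["n_parcels"],
        edge_i=df["i"].to_numpy(),
        edge_j=df["j"].to_numpy(),
        u=df["U"].to_numpy(float),
        z=df["z"].to_numpy(float),
        p_param=df["p_param"].to_numpy(float),
        r_effect=df["r_effect"].to_numpy(float),
        direction=np.array([name_to_dir[d] for d in df["direction"]]),
        tested=df["tested"].to_numpy(bool),
        candidate_mask=df["candidate"].to_numpy(bool),
        n_a=meta["n_a"],
        n_b=meta["n_b"],
        alpha=meta["alpha"],
        perm_p=df["perm_p"].to_numpy(float),
        significant=df["significant"].to_numpy(bool),
        p_crit=meta.get("p_crit"),
    )


def cohort_stats_table(cohort: CohortDataset, scores: tuple[str, ...] = CLINICAL_SCORES) -> pd.DataFrame:
    """Group comparison of clinical scores and motion (Mann-Whitney U with
    Rosenthal's r), one row per variable."""
    a, b = cohort.contrast_labels
    rows = []
    variables = [(s, lambda subj, s=s: subj.clinical_scores.get(s)) for s in scores]
    variables += [
        (f"motion_{m}", lambda subj, m=m: subj.motion_summary.get(m)) for m in MODALITIES
    ]
    for name, get in variables:
        va = np.array([get(s) for s in cohort.group(a) if get(s) is not None], dtype=float)
        vb = np.array([get(s) for s in cohort.group(b) if get(s) is not None], dtype=float)
        if va.size < 2 or vb.size < 2:
            continue
        u, p, r = mwu_rosenthal(va, vb)
        rows.append(
            {
                "variable": name,
                f"n_{a}": va.size,
                f"n_{b}": vb.size,
                f"median_{a}": float(np.median(va)),
                f"median_{b}": float(np.median(vb)),
                "U": u,
                "p": p,
                "rosenthal_r": r,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run_all


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict[str, int]
    output_hashes: dict[str, str]
    timings_s: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, cohort: CohortDataset | None = None) -> dict:
    """Run every stage, write all outputs under ``config.output_dir`` and
    return the assembled report dict.

    ``cohort`` may be passed in memory; otherwise ``config.cohort_dir`` is
    loaded.  Deterministic for a fixed config + seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    seed_map = {
        "contrast_dmri": seeds[0],
        "contrast_rsfmri": seeds[1],
        "overlap": seeds[2],
        "clinical": seeds[3],
    }
    timings: dict[str, float] = {}
    report: dict = {"groups": None, "subnetworks": {}, "hubs": {}, "overlap": None, "clinical": None}

    t0 = time.perf_counter()
    if cohort is None:
        if not config.cohort_dir:
            raise ValueError("no cohort supplied: set cohort_dir or pass a cohort")
        cohort = load_cohort(
            config.cohort_dir, contrast_labels=config.contrast_labels, group_column=config.group_column
        )
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    qc_cohort, excluded = apply_qc(cohort, config.qc)
    timings["qc"] = time.perf_counter() - t0
    report["motion_excluded"] = excluded
    a, b = qc_cohort.contrast_labels
    report["groups"] = {
        a: len(qc_cohort.group(a)),
        b: len(qc_cohort.group(b)),
    }

    contrasts: dict[str, ContrastResult] = {}
    for modality in MODALITIES:
        t0 = time.perf_counter()
        res = contrast_analysis(
            qc_cohort,
            modality,
            alpha=config.contrast.alpha,
            n_permutations=config.contrast.permutations,
            p_crit=config.contrast.p_crit,
            add_one=config.contrast.add_one,
            seed=seed_map[f"contrast_{modality}"],
        )
        contrasts[modality] = res
        write_contrast(res, out / f"contrast_{modality}.tsv")
        timings[f"contrast_{modality}"] = time.perf_counter() - t0
        report.setdefault("contrast", {})[modality] = {
            "n_candidates": int(res.candidate_mask.sum()),
            "n_significant": int(res.significant.sum()),
            "effect_sizes": {
                "min": float(res.r_effect[res.significant].min()) if res.significant.any() else None,
                "median": float(np.median(res.r_effect[res.significant])) if res.significant.any() else None,
                "max": float(res.r_effect[res.significant].max()) if res.significant.any() else None,
            },
        }

    t0 = time.perf_counter()
    for modality in MODALITIES:
        graph = DifferenceGraph.from_contrast(contrasts[modality])
        reports = analyse_subnetworks(graph)
        summary = []
        for k, rep in enumerate(reports, start=1):
            df = rep.to_dataframe()
            atlas = qc_cohort.atlas
            df["region_label"] = [atlas.parcel(n).region_label for n in df["node_id"]]
            df["network_label"] = [atlas.parcel(n).network_label for n in df["node_id"]]
            df.to_csv(out / f"subnet_{modality}_{k}.tsv", sep="\t", index=False)
            summary.append(
                {
                    "nodes": list(rep.subnet.nodes),
                    "n_edges": rep.subnet.edge_count,
                    "hubs": sorted(rep.hubs),
                }
            )
        report["subnetworks"][modality] = summary
        report["hubs"][modality] = sorted({h for rep in reports for h in rep.hubs})
    timings["subnets"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ov: OverlapResult = overlap_analysis(
        qc_cohort,
        qc_cohort,
        contrasts[DMRI],
        contrasts[RSFMRI],
        n_iterations=config.overlap.permutations,
        seed=seed_map["overlap"],
        q_crit=config.overlap.q_crit,
        shared_relabeling=config.overlap.shared_relabeling,
    )
    ov_df = ov.to_dataframe()
    ov_df["region_label"] = [qc_cohort.atlas.parcel(n).region_label for n in ov_df["node_id"]]
    ov_df["network_label"] = [qc_cohort.atlas.parcel(n).network_label for n in ov_df["node_id"]]
    ov_df.to_csv(out / "overlap.tsv", sep="\t", index=False)
    report["overlap"] = {
        "intersect": ov.intersect,
        "q": {str(n): ov.q[n] for n in ov.intersect},
        "significant": sorted(ov.significant),
    }
    timings["overlap"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    clin_frames = []
    for modality in MODALITIES:
        edges = select_candidate_edges(set(ov.intersect), contrasts[modality], scope=config.clinical.edge_scope)
        if not edges:
            continue
        df = clinical_correlations(
            qc_cohort,
            modality,
            edges,
            scores=list(config.clinical.scores),
            n_iterations=config.clinical.permutations,
            seed=seed_map["clinical"],
            null=config.clinical.null,
        )
        df.insert(0, "modality", modality)
        clin_frames.append(df)
    clin = pd.concat(clin_frames, ignore_index=True) if clin_frames else pd.DataFrame(
        columns=["modality", "i", "j", "score", "r", "df", "p_perm", "q"]
    )
    clin.to_csv(out / "clinical.tsv", sep="\t", index=False)
    report["clinical"] = {
        "n_tested": int(len(clin)),
        "n_significant": int((clin["q"] <= 0.05).sum()) if len(clin) else 0,
    }
    timings["clinical"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_df = cohort_stats_table(qc_cohort, tuple(config.clinical.scores))
    stats_df.to_csv(out / "cohort_stats.tsv", sep="\t", index=False)
    timings["cohort_stats"] = time.perf_counter() - t0

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.txt").write_text(_format_report(report))
    manifest = RunManifest(
        config=config_to_dict(config),
        version=__version__,
        stage_seeds=seed_map,
        output_hashes={p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"},
        timings_s={k: round(v, 4) for k, v in timings.items()},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return report


def _format_report(report: dict) -> str:
    lines = ["Differential connectome analysis report", "=" * 40]
    lines.append(f"groups: {report['groups']}")
    for modality, c in report.get("contrast", {}).items():
        lines.append(
            f"{modality}: {c['n_candidates']} candidate edges, {c['n_significant']} significant"
        )
    for modality, subnets in report["subnetworks"].items():
        for k, s in enumerate(subnets, start=1):
            lines.append(
                f"{modality} subnetwork {k}: {len(s['nodes'])} nodes, {s['n_edges']} edges, hubs {s['hubs']}"
            )
    if report["overlap"] is not None:
        lines.append(f"overlap intersect: {report['overlap']['intersect']}")
        lines.append(f"overlap significant (q<=0.05): {report['overlap']['significant']}")
    if report["clinical"] is not None:
        lines.append(
            f"clinical: {report['clinical']['n_tested']} edge-score tests, "
            f"{report['clinical']['n_significant']} significant"
        )
    return "\n".join(lines) + "\n"
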