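"""Per-subject and group workflow with on-disk artifacts.

Each subject: load → normalize → (optionally subsampled) dictionary
learning → spatial maps → template matching, with every artifact (NIfTI
maps, CSV tables, JSON manifest) written under the subject's output
directory.  The group stage builds consensus maps across subjects, writes
the group/individual overlap tables, and renders one montage per template.
Numeric outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from .errors import SparseNetsError
from .io import load_fmri, save_volume
from .matching import (
    MatchResult,
    groupwise_networks,
    load_templates,
    overlap_tables,
)
from .model import SparseNetworkModel, SparseNetworkResults

__all__ = [
    "PipelineConfig",
    "SubjectRun",
    "GroupRun",
    "run_subject",
    "run_group",
    "report",
]

log = logging.getLogger("sparsenets")


@dataclass
class PipelineConfig:
    """Everything one analysis needs, loadable from YAML/JSON."""

    subjects: list[str]
    mask: str
    templates: dict[str, str]
    output_dir: str
    dataset_name: str = "dataset"
    k: int = 400
    lam: float | None = None
    batch_size: int = 256
    n_epochs: int = 5
    seed: int = 0
    sampling_ratio: float = 1.0
    z_thresh: float = 2.0
    overlap_method: str = "jaccard"
    min_overlap: float = 0.05
    consensus_thresh: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.mask, *self.subjects, *self.templates.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class SubjectRun:
    """Outcome of one subject's pipeline run."""

    subject_id: str
    output_dir: Path
    success: bool
    results: SparseNetworkResults | None = None
    match: MatchResult | None = None
    manifest: dict = field(default_factory=dict)
    error: str | None = None
    failed_stage: str | None = None


@dataclass
class GroupRun:
    group_maps: dict
    group_overlaps: dict
    tables: object
    output_dir: Path
    manifest: dict = field(default_factory=dict)


def _write_manifest(path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_subject(
    cfg: PipelineConfig, subject_path: str | Path, subject_id: str | None = None
) -> SubjectRun:
    """Run the full per-subject pipeline; partial outputs survive failures."""
    subject_path = Path(subject_path)
    sid = subject_id or subject_path.name.split(".")[0]
    outdir = Path(cfg.output_dir) / "subjects" / sid
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subject_id": sid, "input": str(subject_path), "files": []}
    stage = "load"
    try:
        t0 = time.perf_counter()
        signals = load_fmri(subject_path, cfg.mask)
        log.info("%s load: %.2fs", sid, time.perf_counter() - t0)

        stage = "learn"
        model = SparseNetworkModel(
            signals,
            k=cfg.k,
            lam=cfg.lam,
            batch_size=cfg.batch_size,
            n_epochs=cfg.n_epochs,
            sampling_ratio=cfg.sampling_ratio,
        )
        t0 = time.perf_counter()
        results = model.fit(seed=cfg.seed)
        log.info("%s learn: %.2fs", sid, time.perf_counter() - t0)

        stage = "map"
        map_paths = results.save_maps(outdir / "maps", z_thresh=cfg.z_thresh)
        manifest["files"] += sorted(str(p) for p in map_paths)
        table = results.component_table(cfg.z_thresh)
        table_path = outdir / "components.csv"
        table.to_csv(table_path, index=False, float_format="%.6f")
        manifest["files"].append(str(table_path))

        stage = "match"
        templates = load_templates(
            cfg.templates, grid_shape=signals.mask.shape
        )
        match = results.match(
            templates,
            z_thresh=cfg.z_thresh,
            min_overlap=cfg.min_overlap,
            method=cfg.overlap_method,
        )
        match_path = outdir / "match.csv"
        _write_match_csv(match, match_path)
        manifest["files"].append(str(match_path))
        if results.fit.sampled_indices is not None:
            idx_path = outdir / "sampled_columns.json"
            idx_path.write_text(
                json.dumps(results.fit.sampled_indices.tolist())
            )
            manifest["files"].append(str(idx_path))

        manifest["summary"] = {
            "lam": results.lam,
            "objective": results.objective,
            "epoch_objectives": results.epoch_objectives,
        }
        _write_manifest(outdir / "manifest.json", manifest)
        return SubjectRun(
            subject_id=sid,
            output_dir=outdir,
            success=True,
            results=results,
            match=match,
            manifest=manifest,
        )
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(outdir / "manifest.json", manifest)
        log.error("%s failed at stage %s: %s", sid, stage, exc)
        return SubjectRun(
            subject_id=sid,
            output_dir=outdir,
            success=False,
            manifest=manifest,
            error=str(exc),
            failed_stage=stage,
        )


def _write_match_csv(match: MatchResult, path: Path) -> None:
    import pandas as pd

    rows = [
        {
            "template": label,
            "component": "" if match.assignment[label] is None else match.assignment[label],
            "overlap": match.overlaps[label],
        }
        for label in match.assignment
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def run_group(cfg: PipelineConfig, subject_runs: Sequence[SubjectRun]) -> GroupRun:
    """Aggregate successful subjects into group consensus networks."""
    good = [r for r in subject_runs if r.success]
    if not good:
        raise SparseNetsError("no successful subject runs to aggregate")
    mask_shape = good[0].results.model.signals.mask.shape
    templates = load_templates(cfg.templates, grid_shape=mask_shape)
    matches = [r.match for r in good]
    components = [r.results.components(cfg.z_thresh) for r in good]
    group_maps, group_overlaps = groupwise_networks(
        matches,
        components,
        templates,
        consensus_thresh=cfg.consensus_thresh,
        method=cfg.overlap_method,
    )
    tables = overlap_tables(
        {cfg.dataset_name: group_overlaps},
        {cfg.dataset_name: [m.overlaps for m in matches]},
        labels=list(templates.labels),
    )
    outdir = Path(cfg.output_dir) / "group"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"dataset": cfg.dataset_name, "n_subjects": len(good), "files": []}
    mask = good[0].results.model.signals.mask
    for label, gmap in group_maps.items():
        p = save_volume(
            gmap.astype(np.uint8), mask, outdir / f"group_{label}.nii.gz", dtype=np.uint8
        )
        manifest["files"].append(str(p))
    group_csv = outdir / "group_overlap.csv"
    tables.group.to_csv(group_csv, float_format="%.6f")
    indiv_csv = outdir / "individual_overlap.csv"
    tables.individual.to_csv(indiv_csv)
    manifest["files"] += [str(group_csv), str(indiv_csv)]
    for ti, label in enumerate(templates.labels):
        p = _montage(group_maps[label], templates.maps[ti], label, outdir)
        manifest["files"].append(str(p))
    manifest["files"].sort()
    _write_manifest(outdir / "manifest.json", manifest)
    return GroupRun(
        group_maps=group_maps,
        group_overlaps=group_overlaps,
        tables=tables,
        output_dir=outdir,
        manifest=manifest,
    )


def _montage(group_map: np.ndarray, template: np.ndarray, label: str, outdir: Path) -> Path:
    """Most-informative axial slice: maximizes in-slice voxel count."""
    combined = group_map | template
    z = int(np.argmax(combined.sum(axis=(0, 1)))) if combined.any() else combined.shape[2] // 2
    fig, ax = plt.subplots(figsize=(3, 3))
    overlay = np.zeros(group_map.shape[:2] + (3,))
    overlay[..., 0] = template[:, :, z]  # red: template
    overlay[..., 1] = group_map[:, :, z]  # green: identified (yellow = both)
    ax.imshow(np.rot90(overlay), interpolation="nearest")
    ax.set_title(f"{label} (slice {z})", fontsize=8)
    ax.axis("off")
    path = outdir / f"montage_{label}.png"
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


def report(run: SubjectRun, z_thresh: float | None = None) -> dict:
    """PNG gallery: one axial mosaic per component, plus a JSON index.

    Filenames are zero-padded sequential, so a k-component run yields PNGs
    named 000…(k−1) in order.
    """
    if not run.success or run.results is None:
        raise SparseNetsError(f"cannot report failed run {run.subject_id}")
    comps = run.results.components(
        z_thresh if z_thresh is not None else 2.0
    )
    outdir = run.output_dir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(comps) - 1)))
    index = {"subject_id": run.subject_id, "pngs": []}
    for c in comps:
        path = outdir / f"{c.index:0{width}d}.png"
        _component_mosaic(c.z_map, path)
        index["pngs"].append(path.name)
    (outdir / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True))
    return index


def _component_mosaic(z_map: np.ndarray, path: Path, n_slices: int = 8) -> None:
    nz = z_map.shape[2]
    picks = np.linspace(0, nz - 1, n_slices).astype(int)
    vmax = max(float(np.abs(z_map).max()), 1e-6)
    fig, axes = plt.subplots(2, (n_slices + 1) // 2, figsize=(2 * ((n_slices + 1) // 2), 4))
    for ax, zi in zip(np.ravel(axes), picks):
        ax.imshow(np.rot90(z_map[:, :, zi]), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.axis("off")
    fig.savefig(path, dpi=80, bbox_inches="tight")
    plt.close(fig)
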