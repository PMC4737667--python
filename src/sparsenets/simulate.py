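"""Synthetic resting-state fMRI with planted functional networks.

Generates a 4D volume in which K spatially compact networks — irregular
connected blobs grown by stochastic radial accretion inside an ellipsoidal
brain mask — each follow their own smoothed-noise time course.  Voxel
signals are the linear mixture of the networks the voxel belongs to plus
white Gaussian noise whose standard deviation is 1/SNR relative to the
unit-variance time courses.  Per-subject variability is a boundary jitter
of each network: every displaced voxel stays within ``jitter`` voxels of
the template.  The ground truth (templates, subject maps, time courses) is
returned and written alongside the volumes so every pipeline stage can be
scored against it.

What this emulates: compact, low-overlap resting-state networks with
distinct spontaneous time courses mixed into voxel signals.  What it does
not: hemodynamics, physiological and spatially correlated noise, scanner
drift beyond what detrending removes, or multi-site variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import PlacementError
from .io import BrainMask, save_volume
from .matching import TemplateSet

__all__ = [
    "SyntheticSpec",
    "SubjectData",
    "generate_mask",
    "generate_templates",
    "generate_subject",
    "generate_dataset",
    "subject_signal_matrix",
    "subject_seeds",
]

_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic multi-subject dataset."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    mask_radius: float = 0.95  # ellipsoid semi-axes as a fraction of half-extent
    n_networks: int = 10
    n_timepoints: int = 120
    blob_size: int = 180  # mean network extent in voxels
    snr: float = 5.0  # signal sd / noise sd
    n_subjects: int = 5
    jitter: int = 1  # per-subject boundary displacement depth, voxels
    seed: int = 0
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("need at least one network")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class SubjectData:
    """One subject's 4D volume plus its generation ground truth."""

    data: np.ndarray  # (x, y, z, m)
    timecourses: np.ndarray  # (K, m), unit variance
    maps: tuple[np.ndarray, ...]  # K jittered boolean maps
    n_boundary_changed: np.ndarray  # per network: voxels added + removed


def generate_mask(spec: SyntheticSpec) -> BrainMask:
    """Ellipsoidal 'brain' mask centered on the grid."""
    shape = np.asarray(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = np.maximum(shape / 2.0 * spec.mask_radius, 1.0)
    ix = np.indices(spec.grid_shape).astype(float)
    r2 = sum(((ix[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return BrainMask(grid=r2 <= 1.0)


def _grow_blob(
    rng: np.random.Generator,
    mask: np.ndarray,
    start: np.ndarray,
    size: int,
    slack: float = 0.5,
) -> np.ndarray:
    """Stochastic radial growth of a connected ``size``-voxel blob.

    Each step annexes a random boundary voxel from those within ``slack``
    of the minimal distance to the seed, so blobs come out compact (their
    planted geometry survives single-voxel misregistration) with an
    irregular, seed-dependent boundary rather than as exact spheres.
    Growth is confined to true cells of ``mask`` (the free region).
    """
    blob = np.zeros(mask.shape, dtype=bool)
    start = np.asarray(start)
    blob[tuple(start)] = True
    shape = np.asarray(mask.shape)
    boundary: dict[tuple[int, int, int], float] = {}

    def add_neighbors(voxel: np.ndarray) -> None:
        for d in _NEIGHBORS:
            c = voxel + d
            if (
                np.all((c >= 0) & (c < shape))
                and mask[tuple(c)]
                and not blob[tuple(c)]
            ):
                boundary[tuple(c)] = float(np.linalg.norm(c - start))

    add_neighbors(start)
    while blob.sum() < size and boundary:
        items = sorted(boundary.items())
        dists = np.array([d for _, d in items])
        near = np.flatnonzero(dists <= dists.min() + slack)
        chosen = items[near[rng.integers(len(near))]][0]
        del boundary[chosen]
        blob[chosen] = True
        add_neighbors(np.asarray(chosen))
    return blob


def generate_templates(spec: SyntheticSpec, max_retries: int = 200) -> TemplateSet:
    """Plant K compact, mutually disjoint blobs inside the mask interior.

    Blobs grow inside the mask eroded by ``spec.jitter`` voxels, so a
    subject displacement within the jitter bound never pushes a network
    outside the brain; they are carved from the still-free region, so the
    pairwise-overlap constraint is met with overlap exactly zero.  Each
    seed is required to have clearance (distance to occupied/outside
    space) of roughly the blob radius so late blobs are not squeezed into
    crevices.
    """
    from scipy.ndimage import binary_erosion, distance_transform_edt

    mask = generate_mask(spec).grid
    region = (
        binary_erosion(mask, iterations=spec.jitter) if spec.jitter > 0 else mask
    )
    if not region.any():
        raise PlacementError("mask interior is empty after the jitter margin")
    rng = np.random.default_rng(spec.seed)
    free = region.copy()
    maps: list[np.ndarray] = []
    for _ in range(spec.n_networks):
        size = int(
            rng.integers(
                max(4, round(0.85 * spec.blob_size)),
                max(5, round(1.15 * spec.blob_size)) + 1,
            )
        )
        radius = (3.0 * size / (4.0 * np.pi)) ** (1.0 / 3.0)
        dist = distance_transform_edt(free)
        clearance = min(radius, float(dist.max()))
        candidates = np.column_stack(np.nonzero(dist >= clearance))
        placed = False
        for _ in range(max_retries):
            if len(candidates) == 0:
                break
            start = candidates[rng.integers(len(candidates))]
            blob = _grow_blob(rng, free, start, size)
            if blob.sum() >= size:
                maps.append(blob)
                free &= ~blob
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place network {len(maps) + 1} of "
                f"{spec.n_networks} disjoint blobs of ~{spec.blob_size} voxels"
            )
    labels = tuple(f"network_{i + 1:02d}" for i in range(spec.n_networks))
    return TemplateSet(labels=labels, maps=tuple(maps))


def _smooth_timecourses(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """Independent smoothed-noise processes, standardized to unit variance."""
    window = 3  # moving average over ~3 TRs: resting-state-like slow drift
    raw = rng.standard_normal((k, m + window - 1))
    kernel = np.ones(window) / window
    tc = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, raw)
    tc -= tc.mean(axis=1, keepdims=True)
    tc /= tc.std(axis=1, keepdims=True)
    return tc


#: probability a template boundary voxel survives in a subject's map
P_KEEP_BOUNDARY = 0.7
#: probability a voxel just outside the template joins a subject's map
P_ADD_BOUNDARY = 0.3


def _jitter_map(
    rng: np.random.Generator, template: np.ndarray, mask: np.ndarray, depth: int
) -> np.ndarray:
    """Per-subject spatial variability: displace the network boundary.

    Every voxel within ``depth`` of the template boundary is resampled —
    boundary voxels stay in with probability ``P_KEEP_BOUNDARY`` and
    adjacent outside voxels join with probability ``P_ADD_BOUNDARY`` — so
    each subject's network differs from the template only within a
    ``depth``-voxel margin.  Local boundary displacement (rather than a
    rigid translation of the whole network) mirrors how anatomy varies
    across subjects, and it is what lets a multi-subject consensus sharpen
    back toward the template.
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    if depth == 0:
        return template.copy()
    inner = template & ~binary_erosion(template, iterations=depth)
    outer = binary_dilation(template, iterations=depth) & ~template & mask
    subject = template.copy()
    subject[inner] = rng.random(int(inner.sum())) < P_KEEP_BOUNDARY
    subject[outer] = rng.random(int(outer.sum())) < P_ADD_BOUNDARY
    return subject


def generate_subject(
    spec: SyntheticSpec, templates: TemplateSet, subject_seed: int
) -> SubjectData:
    """Mix jittered network maps with fresh time courses and noise."""
    rng = np.random.default_rng(subject_seed)
    mask = generate_mask(spec).grid
    k, m = len(templates), spec.n_timepoints
    maps = tuple(
        _jitter_map(rng, t, mask, spec.jitter) for t in templates.maps
    )
    changed = np.array(
        [int((maps[i] ^ templates.maps[i]).sum()) for i in range(k)]
    )
    tc = _smooth_timecourses(rng, k, m)
    data = np.zeros(spec.grid_shape + (m,), dtype=float)
    for i, network in enumerate(maps):
        data[network] += tc[i]
    noise_sd = 0.0 if np.isinf(spec.snr) else 1.0 / spec.snr
    if noise_sd > 0:
        data[mask] += rng.normal(0.0, noise_sd, size=(int(mask.sum()), m))
    return SubjectData(
        data=data, timecourses=tc, maps=maps, n_boundary_changed=changed
    )


def subject_signal_matrix(subject: SubjectData, mask: BrainMask) -> "SignalMatrix":
    """Flatten a generated subject volume into a SignalMatrix (no file I/O)."""
    from .io import SignalMatrix

    vi = mask.voxel_index()
    return SignalMatrix(
        data=np.ascontiguousarray(subject.data[vi[:, 0], vi[:, 1], vi[:, 2], :].T),
        voxel_index=vi,
        mask=mask,
    )


def subject_seeds(spec: SyntheticSpec) -> list[int]:
    """Deterministic per-subject seeds derived from the dataset seed."""
    ss = np.random.SeedSequence(spec.seed)
    state = ss.generate_state(spec.n_subjects + 1)[1:]
    return [int(s % (2**31)) for s in state]


def generate_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict:
    """Write the dataset to disk: subject 4D NIfTIs, mask, templates, truth.

    The truth sidecar (JSON) holds template voxel lists, per-subject jitters
    and time courses; it is consumed only by evaluation code, never by the
    analysis pipeline itself.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = generate_mask(spec)
    templates = generate_templates(spec)
    mask_path = outdir / "mask.nii.gz"
    save_volume(mask.grid.astype(np.uint8), mask, mask_path, dtype=np.uint8)
    template_paths = {}
    for label, tmap in zip(templates.labels, templates.maps):
        p = outdir / f"template_{label}.nii.gz"
        save_volume(tmap.astype(np.uint8), mask, p, dtype=np.uint8)
        template_paths[label] = str(p)

    truth: dict = {
        "spec": {**asdict(spec), "grid_shape": list(spec.grid_shape)},
        "templates": {
            label: np.column_stack(np.nonzero(tmap)).tolist()
            for label, tmap in zip(templates.labels, templates.maps)
        },
        "subjects": {},
    }
    subject_paths = []
    for i, sseed in enumerate(subject_seeds(spec)):
        sid = f"subject_{i + 1:02d}"
        subject = generate_subject(spec, templates, sseed)
        img = nib.Nifti1Image(subject.data.astype(np.float32), mask.affine)
        img.header.set_zooms((1.0, 1.0, 1.0, spec.tr_seconds))
        path = outdir / f"{sid}.nii.gz"
        nib.save(img, str(path))
        subject_paths.append(str(path))
        truth["subjects"][sid] = {
            "seed": sseed,
            "n_boundary_changed": subject.n_boundary_changed.tolist(),
            "timecourses": np.round(subject.timecourses, 10).tolist(),
            "maps": {
                label: np.column_stack(np.nonzero(m)).tolist()
                for label, m in zip(templates.labels, subject.maps)
            },
        }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True))
    return {
        "mask": str(mask_path),
        "templates": template_paths,
        "subjects": subject_paths,
        "truth": str(truth_path),
    }
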