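"""Identify resting-state networks by spatial overlap with template maps.

Candidate network maps are scored against labeled binary templates with a
set-overlap measure (Jaccard by default), assigned one-to-one by a greedy
best-first rule, and aggregated across subjects into group-consensus maps —
the per-dataset analog of reporting one group overlap row plus the
mean ± sd of individual-subject overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ShapeError
from .io import load_mask
from .mapping import NetworkComponent

__all__ = [
    "TemplateSet",
    "MatchResult",
    "OverlapTables",
    "spatial_overlap",
    "match_components",
    "groupwise_networks",
    "overlap_tables",
    "load_templates",
]

DEFAULT_MIN_OVERLAP = 0.05
DEFAULT_CONSENSUS = 0.5
OVERLAP_METHODS = ("jaccard", "dice", "fraction_of_template")


@dataclass(frozen=True)
class TemplateSet:
    """Ordered, labeled binary template volumes on the analysis grid."""

    labels: tuple[str, ...]
    maps: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(
            self, "maps", tuple(np.asarray(m, dtype=bool) for m in self.maps)
        )
        if len(self.labels) != len(self.maps):
            raise ShapeError("labels and maps differ in length")
        if len(self.maps) == 0:
            raise ValueError("template set is empty")
        shape = self.maps[0].shape
        for label, m in zip(self.labels, self.maps):
            if m.shape != shape:
                raise ShapeError(f"template {label!r} has shape {m.shape} != {shape}")
            if not m.any():
                raise ValueError(f"template {label!r} is empty")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.maps[0].shape


def load_templates(paths: Mapping[str, str | Path], grid_shape=None) -> TemplateSet:
    """Read labeled template NIfTIs (any nonzero voxel counts as in-network)."""
    labels, maps = [], []
    for label, path in paths.items():
        mask = load_mask(path)
        if grid_shape is not None and mask.shape != tuple(grid_shape):
            raise ShapeError(
                f"template {label!r} grid {mask.shape} does not match the "
                f"analysis grid {tuple(grid_shape)}"
            )
        labels.append(label)
        maps.append(mask.grid)
    return TemplateSet(labels=tuple(labels), maps=tuple(maps))


@dataclass(frozen=True)
class MatchResult:
    """One-to-one template → component assignment with overlap scores."""

    assignment: dict[str, int | None]
    overlaps: dict[str, float]


def spatial_overlap(A: np.ndarray, T: np.ndarray, method: str = "jaccard") -> float:
    """Set overlap between a candidate map A and a template T, in [0, 1].

    jaccard: |A∩T| / |A∪T|  (default, symmetric)
    dice: 2|A∩T| / (|A| + |T|)
    fraction_of_template: |A∩T| / |T|
    """
    A = np.asarray(A, dtype=bool)
    T = np.asarray(T, dtype=bool)
    if A.shape != T.shape:
        raise ShapeError(f"map shape {A.shape} != template shape {T.shape}")
    n_t = int(T.sum())
    if n_t == 0:
        raise ValueError("template is empty")
    n_a = int(A.sum())
    if n_a == 0:
        return 0.0
    inter = int(np.count_nonzero(A & T))
    if method == "jaccard":
        return inter / (n_a + n_t - inter)
    if method == "dice":
        return 2.0 * inter / (n_a + n_t)
    if method == "fraction_of_template":
        return inter / n_t
    raise ValueError(f"unknown overlap method {method!r}")


def match_components(
    components: Sequence[NetworkComponent],
    templates: TemplateSet,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    method: str = "jaccard",
) -> MatchResult:
    """Greedy one-to-one assignment of components to templates.

    Repeatedly takes the highest-overlap (template, component) pair among
    the still-unassigned until every template is assigned or the best
    remaining overlap drops below ``min_overlap``.  Ties break toward the
    lower component index, then the earlier template.
    """
    if len(components) == 0:
        raise ValueError("need at least one component to match")
    n_t, n_c = len(templates), len(components)
    scores = np.zeros((n_t, n_c))
    for ti, tmap in enumerate(templates.maps):
        for ci, comp in enumerate(components):
            scores[ti, ci] = spatial_overlap(comp.binary_map, tmap, method=method)
    assignment: dict[str, int | None] = {lbl: None for lbl in templates.labels}
    overlaps: dict[str, float] = {lbl: 0.0 for lbl in templates.labels}
    free_t = list(range(n_t))
    free_c = list(range(n_c))
    while free_t and free_c:
        # highest overlap first; ties toward the lower component index,
        # then the earlier template
        best_key, best_pair = None, None
        for ti in free_t:
            for ci in free_c:
                key = (-scores[ti, ci], components[ci].index, ti)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (ti, ci)
        ti, ci = best_pair
        if scores[ti, ci] < min_overlap:
            break
        label = templates.labels[ti]
        assignment[label] = components[ci].index
        overlaps[label] = float(scores[ti, ci])
        free_t.remove(ti)
        free_c.remove(ci)
    return MatchResult(assignment=assignment, overlaps=overlaps)


def groupwise_networks(
    matches: Sequence[MatchResult],
    subject_components: Sequence[Sequence[NetworkComponent]],
    templates: TemplateSet,
    consensus_thresh: float = DEFAULT_CONSENSUS,
    method: str = "jaccard",
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Consensus group map per template and its overlap with the template.

    For each template the matched subject binary maps are stacked, the
    voxelwise proportion computed, and the map binarized at
    ``consensus_thresh`` (proportion ≥ threshold).  A template matched in
    zero subjects yields an empty map and overlap 0.
    """
    if len(matches) == 0:
        raise ValueError("need at least one subject")
    if len(matches) != len(subject_components):
        raise ShapeError("matches and subject_components differ in length")
    comp_by_index = [
        {c.index: c for c in comps} for comps in subject_components
    ]
    group_maps: dict[str, np.ndarray] = {}
    group_overlaps: dict[str, float] = {}
    for ti, label in enumerate(templates.labels):
        stack = []
        for match, lookup in zip(matches, comp_by_index):
            ci = match.assignment.get(label)
            if ci is not None:
                stack.append(lookup[ci].binary_map)
        if not stack:
            group_maps[label] = np.zeros(templates.shape, dtype=bool)
            group_overlaps[label] = 0.0
            continue
        proportion = np.mean(np.asarray(stack, dtype=float), axis=0)
        gmap = proportion >= consensus_thresh
        group_maps[label] = gmap
        group_overlaps[label] = spatial_overlap(
            gmap, templates.maps[ti], method=method
        )
    return group_maps, group_overlaps


@dataclass(frozen=True)
class OverlapTables:
    """Group and individual overlap tables (datasets × templates)."""

    group: pd.DataFrame
    individual: pd.DataFrame  # "mean ± sd" strings
    individual_mean: pd.DataFrame
    individual_sd: pd.DataFrame


def overlap_tables(
    group_results: Mapping[str, Mapping[str, float]],
    individual_results: Mapping[str, Sequence[Mapping[str, float]]],
    labels: Sequence[str],
) -> OverlapTables:
    """Build the per-dataset overlap tables.

    ``group_results[dataset][label]`` is the group overlap; the individual
    table reports mean ± population (n-denominator) standard deviation of
    the per-subject overlaps.
    """
    labels = list(labels)
    datasets = list(group_results.keys())
    group = pd.DataFrame(
        [[float(group_results[d][lbl]) for lbl in labels] for d in datasets],
        index=datasets,
        columns=labels,
    )
    means = np.zeros((len(datasets), len(labels)))
    sds = np.zeros_like(means)
    for di, d in enumerate(datasets):
        per_subject = individual_results[d]
        for li, lbl in enumerate(labels):
            vals = np.array([s[lbl] for s in per_subject], dtype=float)
            means[di, li] = vals.mean()
            sds[di, li] = vals.std()  # population sd
    mean_df = pd.DataFrame(means, index=datasets, columns=labels)
    sd_df = pd.DataFrame(sds, index=datasets, columns=labels)
    formatted = pd.DataFrame(
        [
            [f"{means[di, li]:.2f} ± {sds[di, li]:.2f}" for li in range(len(labels))]
            for di in range(len(datasets))
        ],
        index=datasets,
        columns=labels,
    )
    return OverlapTables(
        group=group,
        individual=formatted,
        individual_mean=mean_df,
        individual_sd=sd_df,
    )
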