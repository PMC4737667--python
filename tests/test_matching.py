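"""Template matching: overlap scores, greedy assignment, group consensus."""

import numpy as np
import pytest

from sparsenets import (
    NetworkComponent,
    TemplateSet,
    groupwise_networks,
    match_components,
    overlap_tables,
    spatial_overlap,
)
from sparsenets.errors import ShapeError

SHAPE = (8, 8, 8)


def cube(x0, x1):
    g = np.zeros(SHAPE, dtype=bool)
    g[x0:x1, x0:x1, x0:x1] = True
    return g


def as_component(index, binary_map):
    return NetworkComponent(
        index=index,
        timecourse=np.zeros(4),
        raw_map=binary_map.astype(float),
        z_map=binary_map.astype(float),
        binary_map=binary_map,
        n_active=int(binary_map.sum()),
    )


class TestSpatialOverlap:
    def test_identity(self):
        a = cube(1, 4)
        assert spatial_overlap(a, a) == 1.0

    def test_disjoint(self):
        assert spatial_overlap(cube(0, 2), cube(4, 7)) == 0.0

    def test_direct_formula(self):
        a = np.zeros(SHAPE, dtype=bool)
        t = np.zeros(SHAPE, dtype=bool)
        a.ravel()[:100] = True
        t.ravel()[50:150] = True
        assert spatial_overlap(a, t) == pytest.approx(50 / 150)
        assert spatial_overlap(a, t, "dice") == pytest.approx(0.5)
        assert spatial_overlap(a, t, "fraction_of_template") == pytest.approx(0.5)

    def test_symmetric_jaccard(self):
        rng = np.random.default_rng(0)
        a = rng.random(SHAPE) < 0.3
        t = rng.random(SHAPE) < 0.3
        t.ravel()[0] = True
        a.ravel()[1] = True
        assert spatial_overlap(a, t) == spatial_overlap(t, a)

    def test_empty_candidate_is_zero(self):
        assert spatial_overlap(np.zeros(SHAPE, bool), cube(1, 3)) == 0.0

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            spatial_overlap(cube(1, 3), np.zeros(SHAPE, bool))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            spatial_overlap(cube(1, 3), np.ones((4, 4, 4), bool))


class TestMatchComponents:
    def test_exact_components_identity_assignment(self):
        maps = [cube(0, 3), cube(4, 7)]
        templates = TemplateSet(labels=("a", "b"), maps=tuple(maps))
        comps = [as_component(i, m) for i, m in enumerate(maps)]
        result = match_components(comps, templates)
        assert result.assignment == {"a": 0, "b": 1}
        assert result.overlaps == {"a": 1.0, "b": 1.0}

    def test_injective_assignment(self):
        """A component overlapping two templates goes to the better one only."""
        t1, t2 = cube(0, 4), cube(2, 6)
        templates = TemplateSet(labels=("t1", "t2"), maps=(t1, t2))
        comp = as_component(0, cube(0, 4))  # equals t1, overlaps t2
        result = match_components([comp], templates)
        assert result.assignment["t1"] == 0
        assert result.assignment["t2"] is None
        assert result.overlaps["t2"] == 0.0

    def test_below_min_overlap_unassigned(self):
        templates = TemplateSet(labels=("a",), maps=(cube(0, 2),))
        comp = as_component(0, cube(5, 7))
        result = match_components([comp], templates, min_overlap=0.05)
        assert result.assignment["a"] is None

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        maps = [rng.random(SHAPE) < 0.2 for _ in range(4)]
        for m in maps:
            m.ravel()[0] = True
        templates = TemplateSet(labels=("a", "b", "c"), maps=tuple(maps[:3]))
        comps = [as_component(i, m) for i, m in enumerate(maps)]
        r1 = match_components(comps, templates)
        r2 = match_components(list(reversed(comps)), templates)
        assert r1.assignment == r2.assignment
        assert r1.overlaps == r2.overlaps

    def test_no_components_rejected(self):
        templates = TemplateSet(labels=("a",), maps=(cube(0, 2),))
        with pytest.raises(ValueError):
            match_components([], templates)


class TestGroupwise:
    def test_single_subject_equals_own_map(self):
        tmap = cube(1, 5)
        templates = TemplateSet(labels=("a",), maps=(tmap,))
        comp = as_component(0, cube(2, 6))
        match = match_components([comp], templates)
        gmaps, gov = groupwise_networks([match], [[comp]], templates)
        np.testing.assert_array_equal(gmaps["a"], comp.binary_map)
        assert gov["a"] == match.overlaps["a"]

    def test_consensus_of_identical_maps(self):
        tmap = cube(1, 5)
        templates = TemplateSet(labels=("a",), maps=(tmap,))
        comps = [as_component(0, cube(2, 6)) for _ in range(4)]
        matches = [match_components([c], templates) for c in comps]
        gmaps, _ = groupwise_networks(matches, [[c] for c in comps], templates)
        np.testing.assert_array_equal(gmaps["a"], comps[0].binary_map)

    def test_unmatched_template_empty_group(self):
        templates = TemplateSet(labels=("a",), maps=(cube(0, 2),))
        comp = as_component(0, cube(5, 7))  # no overlap
        match = match_components([comp], templates)
        gmaps, gov = groupwise_networks([match], [[comp]], templates)
        assert not gmaps["a"].any()
        assert gov["a"] == 0.0

    def test_group_beats_individual_mean_under_boundary_jitter(self):
        """Majority consensus across 20 jittered subjects sharpens the map."""
        from scipy.ndimage import binary_dilation, binary_erosion

        rng = np.random.default_rng(2)
        tmap = cube(1, 6)
        templates = TemplateSet(labels=("a",), maps=(tmap,))
        inner = tmap & ~binary_erosion(tmap)
        outer = binary_dilation(tmap) & ~tmap
        matches, comps = [], []
        for _ in range(20):
            m = tmap.copy()
            m[inner] = rng.random(int(inner.sum())) < 0.7
            m[outer] = rng.random(int(outer.sum())) < 0.3
            comp = as_component(0, m)
            comps.append([comp])
            matches.append(match_components([comp], templates))
        _, gov = groupwise_networks(matches, comps, templates)
        indiv_mean = np.mean([m.overlaps["a"] for m in matches])
        assert gov["a"] >= indiv_mean


class TestOverlapTables:
    def test_mean_pm_population_sd(self):
        tables = overlap_tables(
            {"ds": {"a": 1.0}},
            {"ds": [{"a": 0.3}, {"a": 0.5}]},
            labels=["a"],
        )
        assert tables.individual.loc["ds", "a"] == "0.40 ± 0.10"
        assert tables.individual_mean.loc["ds", "a"] == pytest.approx(0.4)
        assert tables.individual_sd.loc["ds", "a"] == pytest.approx(0.1)
        assert tables.group.loc["ds", "a"] == 1.0

    def test_recompute_to_machine_precision(self):
        rng = np.random.default_rng(3)
        labels = ["x", "y", "z"]
        indiv = {
            ds: [{lbl: rng.random() for lbl in labels} for _ in range(5)]
            for ds in ("d1", "d2")
        }
        group = {ds: {lbl: rng.random() for lbl in labels} for ds in ("d1", "d2")}
        tables = overlap_tables(group, indiv, labels)
        for ds in ("d1", "d2"):
            for lbl in labels:
                vals = np.array([s[lbl] for s in indiv[ds]])
                assert tables.individual_mean.loc[ds, lbl] == pytest.approx(
                    vals.mean(), abs=1e-12
                )
                assert tables.individual_sd.loc[ds, lbl] == pytest.approx(
                    vals.std(), abs=1e-12
                )
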