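"""Overlay maps: richness, function, overlap and change summaries."""

import numpy as np
import pytest

from frugicast import forecast as fc
from frugicast.grids import BinaryRangeMap, GridSpec
from frugicast.sde import SDEProfile

from conftest import random_range_map


def _map(arr, grid, species="sp", scenario="current"):
    return BinaryRangeMap(np.asarray(arr), species, scenario, grid)


def _profiles(weights, plant="p", with_qual=True):
    out = []
    for fid, w in weights.items():
        if with_qual:
            out.append(SDEProfile(fid, plant, qsde=w, qual=1.0, sde=w))
        else:
            out.append(SDEProfile(fid, plant, qsde=w))
    return out


class TestAreasAndOverlap:
    def test_empty_map_zero_area(self, grid):
        assert fc.range_area(_map(np.zeros((4, 4)), grid)) == 0.0

    def test_full_grid_area(self):
        g = GridSpec(10, 10, cell_area=1.0)
        assert fc.range_area(_map(np.ones((10, 10)), g)) == 100.0

    def test_hand_counted_area(self):
        g = GridSpec(3, 3, cell_area=2.5)
        m = _map([[1, 0, 1], [0, 0, 0], [1, 1, 0]], g)
        assert fc.range_area(m) == pytest.approx(4 * 2.5)

    def test_grid_mismatch_rejected(self, grid):
        other = GridSpec(4, 4, cell_size=2.0)
        with pytest.raises(ValueError):
            fc.range_area(_map(np.zeros((4, 4)), grid), other)

    def test_identical_maps_full_overlap(self, rng, grid):
        m = random_range_map(rng, grid, "p")
        s = fc.cooccurrence(m, _map(m.presence, grid, "f"))
        assert s.pct_of_plant_range == 100.0

    def test_disjoint_maps_no_overlap(self, grid):
        p = _map(np.eye(4, dtype=int), grid, "p")
        a = _map(1 - np.eye(4, dtype=int), grid, "f")
        assert fc.cooccurrence(p, a).pct_of_plant_range == 0.0

    def test_worked_percentage(self):
        g = GridSpec(3, 3)
        plant = _map([[1, 1, 1], [1, 1, 1], [1, 1, 0]], g, "p")  # 8 cells
        animal = _map([[1, 1, 1], [1, 1, 1], [0, 0, 0]], g, "f")  # 6 in plant
        s = fc.cooccurrence(plant, animal)
        assert s.pct_of_plant_range == pytest.approx(75.0)
        assert s.intersection_area == 6.0

    def test_scenario_mismatch_rejected(self, grid):
        p = _map(np.ones((4, 4)), grid, "p", "current")
        a = _map(np.ones((4, 4)), grid, "f", "moderate")
        with pytest.raises(ValueError):
            fc.cooccurrence(p, a)

    def test_pct_symmetric_only_for_equal_areas(self, grid):
        p = _map([[1, 1, 0, 0]] * 4, grid, "a")
        q = _map([[0, 1, 1, 0]] * 4, grid, "b")
        assert (
            fc.cooccurrence(p, q).pct_of_plant_range
            == fc.cooccurrence(q, p).pct_of_plant_range
        )
        bigger = _map([[1, 1, 1, 0]] * 4, grid, "c")
        assert (
            fc.cooccurrence(p, bigger).pct_of_plant_range
            != fc.cooccurrence(bigger, p).pct_of_plant_range
        )


class TestRichnessAndFunction:
    def test_no_animals_zero_richness(self, rng, grid):
        plant = random_range_map(rng, grid, "p", p=1.0)
        r = fc.richness_map(plant, [])
        assert np.nansum(r.counts) == 0

    def test_single_ubiquitous_animal(self, grid):
        plant = _map([[1, 1, 0, 0]] * 4, grid, "p")
        animal = _map(np.ones((4, 4), int), grid, "f")
        r = fc.richness_map(plant, [animal])
        assert np.all(r.counts[plant.presence == 1] == 1)
        assert np.all(np.isnan(r.counts[plant.presence == 0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_richness_matches_per_cell_count(self, seed):
        rng = np.random.default_rng(seed)
        g = GridSpec(4, 4)
        plant = random_range_map(rng, g, "p", p=0.8)
        animals = [random_range_map(rng, g, f"f{i}") for i in range(3)]
        r = fc.richness_map(plant, animals)
        for i in range(4):
            for j in range(4):
                if plant.presence[i, j]:
                    assert r.counts[i, j] == sum(a.presence[i, j] for a in animals)

    @pytest.mark.parametrize("seed", range(5))
    def test_function_matches_explicit_loop(self, seed):
        rng = np.random.default_rng(seed)
        g = GridSpec(4, 4)
        plant = random_range_map(rng, g, "p", p=0.9)
        animals = [random_range_map(rng, g, f) for f in ("a", "b", "c")]
        weights = {"a": 20.0, "b": 5.0, "c": 1.0}
        fm = fc.function_map(plant, animals, _profiles(weights), metric="qsde")
        for i in range(4):
            for j in range(4):
                if plant.presence[i, j]:
                    expected = sum(
                        a.presence[i, j] * weights[a.species_id] for a in animals
                    )
                    assert fm.values[i, j] == pytest.approx(expected)
                else:
                    assert np.isnan(fm.values[i, j])

    def test_function_reduces_to_richness_with_unit_weights(self, rng):
        g = GridSpec(6, 6)
        plant = random_range_map(rng, g, "p", p=0.9)
        animals = [random_range_map(rng, g, f"f{i}") for i in range(4)]
        profiles = _profiles({f"f{i}": 1.0 for i in range(4)})
        fm = fc.function_map(plant, animals, profiles)
        rm = fc.richness_map(plant, animals)
        np.testing.assert_array_equal(fm.values, rm.counts)

    def test_function_additive_over_species(self, rng):
        g = GridSpec(5, 5)
        plant = random_range_map(rng, g, "p", p=1.0)
        animals = [random_range_map(rng, g, f"f{i}") for i in range(3)]
        weights = {"f0": 3.0, "f1": 7.0, "f2": 11.0}
        joint = fc.function_map(plant, animals, _profiles(weights))
        summed = sum(
            fc.function_map(plant, [a], _profiles(weights)).values for a in animals
        )
        np.testing.assert_allclose(joint.values, summed)

    def test_function_monotone_in_presence(self, rng):
        g = GridSpec(5, 5)
        plant = random_range_map(rng, g, "p", p=1.0)
        a = random_range_map(rng, g, "f0", p=0.3)
        grown = a.presence.copy()
        grown[0, :] = 1
        before = fc.function_map(plant, [a], _profiles({"f0": 5.0}))
        after = fc.function_map(
            plant, [BinaryRangeMap(grown, "f0", "current", g)], _profiles({"f0": 5.0})
        )
        assert np.all(after.values >= before.values)

    def test_sde_metric_excludes_species_without_trials(self, rng, grid):
        plant = random_range_map(rng, grid, "p", p=1.0)
        a = _map(np.ones((4, 4), int), grid, "a")
        b = _map(np.ones((4, 4), int), grid, "b")
        profiles = [
            SDEProfile("a", "p", qsde=10.0, qual=0.5, sde=5.0),
            SDEProfile("b", "p", qsde=99.0),  # no trial data
        ]
        fm = fc.function_map(plant, [a, b], profiles, metric="sde")
        assert np.all(fm.values[plant.presence == 1] == 5.0)
        with pytest.raises(ValueError):
            fc.function_map(plant, [b], [profiles[1]], metric="sde")


class TestChanges:
    @pytest.mark.parametrize(
        "cur, fut, expected", [(200.0, 150.0, -25.0), (100.0, 130.0, 30.0), (5.0, 5.0, 0.0)]
    )
    def test_percent_change_scalar(self, cur, fut, expected):
        assert fc.percent_change(cur, fut) == pytest.approx(expected)

    def test_percent_change_zero_current_excluded(self):
        out = fc.percent_change(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(50.0)

    def test_unchanged_maps_zero_change(self, rng, grid):
        plant = random_range_map(rng, grid, "p", p=1.0)
        animal = random_range_map(rng, grid, "f", p=0.8)
        maps = {
            s: BinaryRangeMap(plant.presence, "p", s, grid)
            for s in ("current", "moderate", "business-as-usual")
        }
        animals = {
            s: [BinaryRangeMap(animal.presence, "f", s, grid)]
            for s in ("current", "moderate", "business-as-usual")
        }
        out = fc.assemblage_change(maps, animals, _profiles({"f": 4.0}))
        assert all(c.pct_change == 0.0 for c in out)

    def test_halved_range_is_minus_fifty(self):
        g = GridSpec(2, 4)
        plant = {"current": _map(np.ones((2, 4), int), g, "p", "current"),
                 "moderate": _map(np.ones((2, 4), int), g, "p", "moderate")}
        a_cur = _map(np.ones((2, 4), int), g, "f", "current")
        half = np.ones((2, 4), int)
        half[0, :] = 0
        a_fut = _map(half, g, "f", "moderate")
        out = fc.assemblage_change(
            plant, {"current": [a_cur], "moderate": [a_fut]},
            _profiles({"f": 2.0}), scenarios=("moderate",),
        )
        by_entity = {c.entity: c for c in out}
        assert by_entity["f"].pct_change == pytest.approx(-50.0)

    def test_assemblage_change_is_weighted_species_mean(self, rng):
        """Assemblage %-change equals the current-contribution-weighted
        mean of the species %-changes."""
        g = GridSpec(6, 6)
        scens = ("current", "moderate")
        plant = {s: _map(np.ones((6, 6), int), g, "p", s) for s in scens}
        animals = {
            s: [random_range_map(rng, g, f"f{i}", s, p=0.7) for i in range(4)]
            for s in scens
        }
        weights = {f"f{i}": float(i + 1) for i in range(4)}
        out = fc.assemblage_change(
            plant, animals, _profiles(weights), scenarios=("moderate",)
        )
        species = [c for c in out if not c.entity.startswith("assemblage")]
        total = next(c for c in out if c.entity.startswith("assemblage"))
        num = sum(c.current_value * c.pct_change for c in species)
        den = sum(c.current_value for c in species)
        assert total.pct_change == pytest.approx(num / den)

    def test_missing_scenario_rejected(self, rng, grid):
        plant = {"current": random_range_map(rng, grid, "p")}
        with pytest.raises(ValueError):
            fc.assemblage_change(plant, {}, [], scenarios=("moderate",))
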