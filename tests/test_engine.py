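import numpy as np
import pytest

from evocell import engine
from evocell.accounting import Role
from evocell.config import (
    HabitatConfig,
    SpeciesDef,
    parse_distribution_code,
)
from evocell.engine import (
    Cell,
    Organism,
    initialize,
    largest_remainder,
    load_checkpoint,
    run,
    save_checkpoint,
    step,
    stochastic_round,
)


def make_cfg(species, cells=4, resources=10, code="100n", generations=5,
             varia=False, seed=0):
    return HabitatConfig(
        NumberOfCells=cells,
        NumberOfRsrcsInEachCell=resources,
        Distribution=parse_distribution_code(code),
        species=species,
        generations=generations,
        seed=seed,
        varia=varia,
    )


class TestHelpers:
    def test_stochastic_round_integer(self, rng):
        assert stochastic_round(3.0, rng) == 3

    def test_stochastic_round_bounds(self, rng):
        draws = [stochastic_round(2.3, rng) for _ in range(500)]
        assert set(draws) <= {2, 3}
        assert abs(np.mean(draws) - 2.3) < 0.1  # unbiased in expectation

    def test_largest_remainder_sums(self):
        assert sum(largest_remainder(7, [1, 1, 1])) == 7
        assert largest_remainder(10, [3, 1]) == [8, 2]
        assert largest_remainder(0, [5, 5]) == [0, 0]
        assert largest_remainder(4, [0, 0]) == [0, 0]


class TestInitialize:
    def test_places_all_items(self):
        cfg = make_cfg([SpeciesDef(id="A", NumberOfItems=37, DirectOffspring=1)])
        state = initialize(cfg, seed=1)
        assert state.species_totals(cfg)["A"] == 37
        assert state.generation == 0

    def test_seed_reproducible(self):
        cfg = make_cfg([SpeciesDef(id="A", NumberOfItems=20, DirectOffspring=1)])
        a = [len(c.organisms) for c in initialize(cfg, seed=9).cells]
        b = [len(c.organisms) for c in initialize(cfg, seed=9).cells]
        assert a == b


class TestStep:
    def test_full_fed_is_deterministic(self):
        # demand (2 organisms x 3) fits in 10 resources: exactly 6 newborns
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=2, DirectOffspring=3)],
            cells=1, resources=10,
        )
        state = initialize(cfg, seed=5)
        step(state, cfg)
        assert state.species_totals(cfg)["A"] == 6

    def test_parents_do_not_survive(self):
        # zero fitness: the lineage ends after one generation
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=8, DirectOffspring=0)], cells=2
        )
        state = initialize(cfg, seed=5)
        step(state, cfg)
        assert state.species_totals(cfg)["A"] == 0

    def test_consumption_capped_by_resources(self):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=50, DirectOffspring=4)],
            cells=1, resources=12,
        )
        state = initialize(cfg, seed=5)
        step(state, cfg)
        assert state.species_totals(cfg)["A"] == 12  # one unit, one descendant


class TestAssociationRoles:
    def test_couples_equal_lower_quorum(self, rng):
        cfg = make_cfg([
            SpeciesDef(id="M", DirectOffspring=0, IndirectOffspring=4,
                       AssociatedSpecies=["F"]),
            SpeciesDef(id="F", DirectOffspring=0, IndirectOffspring=4,
                       AssociatedSpecies=["M"]),
        ])
        cell = Cell(0, [Organism("M", 0, 4) for _ in range(5)]
                    + [Organism("F", 0, 4) for _ in range(3)], 10)
        engine.do_association(cell, cfg, rng)
        paired_m = sum(1 for o in cell.organisms
                       if o.species == "M" and o.role is Role.RECIPROCAL_INTER)
        singles_m = sum(1 for o in cell.organisms
                        if o.species == "M" and o.role is Role.INDIVIDUAL)
        assert paired_m == 3  # min(5, 3)
        assert singles_m == 2

    def test_one_way_listing_makes_actor(self, rng):
        cfg = make_cfg([
            SpeciesDef(id="Host", DirectOffspring=3, IndirectOffspring=2,
                       AssociatedSpecies=["Guest"]),
            SpeciesDef(id="Guest", DirectOffspring=1),
        ])
        cell = Cell(0, [Organism("Host", 3, 2), Organism("Guest", 1, 0)], 10)
        engine.do_association(cell, cfg, rng)
        roles = {o.species: o.role for o in cell.organisms}
        assert roles == {"Host": Role.ACTOR, "Guest": Role.RECIPIENT}


class TestGrouping:
    def _cfg(self, pf_group=0.0):
        return make_cfg([
            SpeciesDef(id="C", NumberOfItems=6, DirectOffspring=0,
                       GroupPartner=["C"], PhenotypicFlexibility=1.0),
            SpeciesDef(id="C|C", DirectOffspring=5,
                       PhenotypicFlexibility=pf_group),
        ])

    def test_self_grouping_pairs_floor(self, rng):
        cfg = self._cfg()
        cell = Cell(0, [Organism("C", 0, 0) for _ in range(7)], 10)
        engine.do_grouping(cell, cfg, rng)
        counts = {}
        for o in cell.organisms:
            counts[o.species] = counts.get(o.species, 0) + 1
        assert counts == {"C|C": 3, "C": 1}  # floor(7/2) pairs, one odd bee

    def test_ungroup_splits_left_associative(self, rng):
        cfg = self._cfg(pf_group=0.0)
        newborn = engine.do_ungroup({"C|C": 4}, cfg, rng)
        assert newborn == {"C": 8}

    def test_ungroup_keeps_share(self, rng):
        cfg = self._cfg(pf_group=1.0)
        newborn = engine.do_ungroup({"C|C": 4}, cfg, rng)
        assert newborn == {"C|C": 4}


class TestVaria:
    def test_sum_invariant(self, rng):
        cfg = make_cfg(
            [SpeciesDef(id="A", DirectOffspring=3, IndirectOffspring=3,
                        FitnessVariationLimit=2)],
            varia=True,
        )
        orgs = [Organism("A", 3, 3) for _ in range(200)]
        engine.apply_varia(orgs, cfg, rng)
        for o in orgs:
            assert o.direct + o.indirect == 6
            assert 0 <= o.direct <= 6
        assert len({o.direct for o in orgs}) > 1  # it actually varies


class TestRun:
    def test_series_shape_and_start(self):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=10, DirectOffspring=2)],
            generations=6,
        )
        series = run(cfg, seed=3)
        assert series.counts.shape == (7, 1)
        assert series.counts[0, 0] == 10

    def test_all_extinct_zero_fill(self):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=5, DirectOffspring=0)],
            generations=4,
        )
        series = run(cfg, seed=3)
        assert (series.counts[1:] == 0).all()

    def test_seed_determinism(self):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=30, DirectOffspring=2)],
            cells=6, resources=8, generations=10,
        )
        a = run(cfg, seed=77).counts
        b = run(cfg, seed=77).counts
        assert (a == b).all()

    def test_to_dataframe_tidy(self):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=4, DirectOffspring=2)],
            generations=2,
        )
        df = run(cfg, seed=1, replicate_id=3).to_dataframe()
        assert list(df.columns) == ["replicate", "generation", "species", "count"]
        assert set(df["replicate"]) == {3}
        assert len(df) == 3  # (gens + 1) x 1 species


class TestCountsRunner:
    def _cfg(self, cells=10):
        return make_cfg(
            [SpeciesDef(id="A", NumberOfItems=cells, DirectOffspring=2),
             SpeciesDef(id="B", NumberOfItems=cells, DirectOffspring=2)],
            cells=cells, resources=4, generations=20,
        )

    def test_eligibility(self):
        assert engine.counts_runner_eligible(self._cfg())
        grouped = make_cfg([
            SpeciesDef(id="C", NumberOfItems=4, GroupPartner=["C"],
                       PhenotypicFlexibility=1.0),
            SpeciesDef(id="C|C", DirectOffspring=2),
        ])
        assert not engine.counts_runner_eligible(grouped)

    def test_conserves_population_cap(self):
        cfg = self._cfg()
        series = engine.run_counts(cfg, seed=4)
        # at saturation the population equals the habitat resource budget
        assert series.counts[5:].sum(axis=1).max() <= 10 * 4

    def test_rejects_ineligible(self):
        grouped = make_cfg([
            SpeciesDef(id="C", NumberOfItems=4, GroupPartner=["C"],
                       PhenotypicFlexibility=1.0),
            SpeciesDef(id="C|C", DirectOffspring=2),
        ])
        with pytest.raises(ValueError):
            engine.run_counts(grouped, seed=1)


class TestCheckpoint:
    def test_round_trip_resumes_identically(self, tmp_path):
        cfg = make_cfg(
            [SpeciesDef(id="A", NumberOfItems=30, DirectOffspring=2)],
            cells=6, resources=8, generations=10, seed=123,
        )
        full = run(cfg, seed=123).counts

        state = initialize(cfg, seed=123)
        for _ in range(4):
            step(state, cfg)
        path = tmp_path / "ckpt.json"
        save_checkpoint(state, cfg, str(path))

        loaded, cfg2 = load_checkpoint(str(path))
        assert loaded.generation == 4
        tail = run(cfg2, state=loaded, generations=6).counts
        assert (tail[-1] == full[-1]).all()

    def test_corrupt_file_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(IOError):
            load_checkpoint(str(path))
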