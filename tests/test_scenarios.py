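import pytest

from evocell import engine
from evocell.config import validate_config
from evocell.scenarios import (
    generations_for_years,
    list_scenarios,
    make_scenario,
    scenario_names,
)


class TestGenerationsForYears:
    def test_whole_generations(self):
        assert generations_for_years(100, 4.0) == 25

    def test_floors(self):
        assert generations_for_years(10, 3.0) == 3

    def test_bad_generation_time(self):
        with pytest.raises(ValueError):
            generations_for_years(10, 0)


class TestCatalogue:
    def test_at_least_18_scenarios(self):
        specs = list_scenarios()
        assert len({s.name for s in specs}) >= 18

    def test_expected_outcomes_attached(self):
        by_name = {s.name: s for s in list_scenarios() if s.variant in (None, 1)}
        assert by_name["Exclu"].expected == "The most efficient excludes the other"
        assert by_name["Fish"].expected == "The sex ratio 1:1 prevails"

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="Exclu"):
            make_scenario("NoSuchScenario")

    def test_bad_variant(self):
        with pytest.raises(ValueError):
            make_scenario("Sex2", variant=99)
        with pytest.raises(ValueError):
            make_scenario("Symb", variant=0)

    def test_spec_build_applies_knobs(self):
        spec = next(s for s in list_scenarios() if s.name == "LCFY")
        cfg = spec.build(cells=7)
        assert cfg.NumberOfCells == 7


@pytest.mark.parametrize("name", scenario_names())
def test_every_scenario_validates_and_runs(name):
    cfg = make_scenario(name)
    assert validate_config(cfg) == []
    series = engine.run(cfg, seed=1, generations=10)
    assert series.counts.shape[0] == 11


def test_variants_validate():
    for variant in range(1, 9):
        assert validate_config(make_scenario("Sex2", variant=variant)) == []
    for variant in range(1, 6):
        assert validate_config(make_scenario("Symb", variant=variant)) == []


class TestEncodings:
    def test_fisher_strategies(self):
        cfg = make_scenario("Fish")
        even = cfg.species_by_id("FemaleEven")
        biased = cfg.species_by_id("FemaleBiased")
        # no couple, no brood; the female's indirect offspring are her sons
        assert even.DirectOffspring == 0 and even.IndirectOffspring == 4
        assert biased.IndirectOffspring != 4
        male_b = cfg.species_by_id("MaleBiased")
        assert biased.IndirectOffspring + male_b.IndirectOffspring == 8

    def test_sex2_like_parent_fitness_equal(self):
        cfg = make_scenario("Sex2", variant=1)
        assert cfg.species_by_id("Asexual").DirectOffspring == 4
        assert cfg.species_by_id("Female").IndirectOffspring == 4
        assert cfg.species_by_id("Female").DirectOffspring == 0

    def test_pathogen_groups_declared(self):
        cfg = make_scenario("Sex2", variant=8)
        assert cfg.has_species("Asexual|Pathogen")
        # groups dissolve each generation: offspring born uninfected
        assert cfg.species_by_id("Asexual|Pathogen").PhenotypicFlexibility == 0.0

    def test_colab_equal_inclusive_fitness(self):
        cfg = make_scenario("Colab")
        assert cfg.species_by_id("A").inclusive_fitness == 5
        assert cfg.species_by_id("B").inclusive_fitness == 5
        assert cfg.species_by_id("C|C").DirectOffspring == 5
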