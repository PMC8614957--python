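import math

import numpy as np
import pandas as pd
import pytest

from evocell import analysis, engine
from evocell.engine import PopulationSeries
from evocell.scenarios import make_scenario


def series_from_rows(species_ids, rows, replicate_id=0):
    s = PopulationSeries(species_ids, replicate_id=replicate_id)
    for row in rows:
        s.append(dict(zip(species_ids, row)))
    return s


class TestReplicateSeeds:
    def test_deterministic(self):
        assert analysis.replicate_seeds(7, 5) == analysis.replicate_seeds(7, 5)

    def test_distinct_and_31_bit(self):
        seeds = analysis.replicate_seeds(0, 50)
        assert len(set(seeds)) == 50
        assert all(0 <= s < 2**31 for s in seeds)


class TestOutcomeLabel:
    def test_fixation(self):
        s = series_from_rows(["A", "B"], [[5, 5], [9, 0]])
        assert analysis.outcome_label(s) == "fixed:A"

    def test_all_extinct(self):
        s = series_from_rows(["A", "B"], [[5, 5], [0, 0]])
        assert analysis.outcome_label(s) == "all_extinct"

    def test_coexistence(self):
        s = series_from_rows(["A", "B"], [[5, 5], [4, 6]])
        assert analysis.outcome_label(s) == "coexistence"


class TestExtinctionGeneration:
    def test_alive_is_none(self):
        s = series_from_rows(["A"], [[3], [3]])
        assert analysis.extinction_generation(s, "A") is None

    def test_generation_of_loss(self):
        s = series_from_rows(["A"], [[3], [2], [0], [0]])
        assert analysis.extinction_generation(s, "A") == 2

    def test_never_present(self):
        s = series_from_rows(["A"], [[0], [0]])
        assert analysis.extinction_generation(s, "A") == 0


class TestSexRatio:
    def test_ratio_and_nan(self):
        s = series_from_rows(["M", "F"], [[4, 4], [6, 3], [2, 0]])
        r = analysis.sex_ratio(s, "M", "F")
        assert r[0] == 1.0
        assert r[1] == 2.0
        assert math.isnan(r[2])

    def test_mean_final_pools_replicates(self):
        a = series_from_rows(["M", "F"], [[1, 1], [2, 1]])
        b = series_from_rows(["M", "F"], [[1, 1], [1, 2]])
        mean = analysis.mean_final_sex_ratio([a, b], "M", "F", last=1)
        assert mean == pytest.approx((2.0 + 0.5) / 2)


class TestComponentSeries:
    def test_composite_membership(self):
        s = series_from_rows(["C", "C|C"], [[4, 3], [0, 5]])
        total = analysis.component_series(s, "C")
        assert total.tolist() == [10, 10]  # a C|C group holds two C


class TestRunReplicates:
    def test_summary_counts(self):
        cfg = make_scenario("DeriSP", generations=30)
        summary = analysis.run_replicates(cfg, n=4, base_seed=5, generations=30)
        assert summary.n == 4
        assert len(summary.outcomes) == 4
        fr = summary.fixation_fraction
        assert set(fr) == {"Sp1", "Sp2"}
        assert all(0.0 <= v <= 1.0 for v in fr.values())
        assert summary.mean_counts.shape == (31, 2)

    def test_to_dict_serializable(self):
        import json

        cfg = make_scenario("DeriSP", generations=5)
        summary = analysis.run_replicates(cfg, n=2, base_seed=5, generations=5)
        json.dumps(summary.to_dict())


class TestSeriesToCsv:
    def test_round_trip(self, tmp_path):
        cfg = make_scenario("DeriSP", generations=3)
        series = [engine.run(cfg, seed=s, generations=3, replicate_id=i)
                  for i, s in enumerate([1, 2])]
        path = tmp_path / "pop.csv"
        analysis.series_to_csv(series, str(path))
        df = pd.read_csv(path)
        assert list(df.columns) == ["replicate", "generation", "species", "count"]
        assert set(df["replicate"]) == {0, 1}
        assert len(df) == 2 * 4 * 2  # replicates x (gens+1) x species


class TestPerCellVariance:
    def test_keys_and_nonnegative(self):
        cfg = make_scenario("DeriSP")
        state = engine.initialize(cfg, seed=1)
        var = analysis.per_cell_variance(state, cfg)
        assert set(var) == {"Sp1", "Sp2"}
        assert all(v >= 0 for v in var.values())
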