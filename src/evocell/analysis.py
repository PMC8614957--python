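"""Replicate orchestration and summary statistics.

The study protocol runs ten independently seeded replicates per
configuration and reads outcomes off the recorded population series:
which species fixed or went extinct, how the sex ratio evolved, how
spread out organisms are across cells, and how strongly drift acts at a
given habitat size. All summaries are pure functions of recorded series
and can be recomputed offline from the exported CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .config import HabitatConfig, parse_species_id
from .engine import HabitatState, PopulationSeries
from .scenarios import make_scenario

__all__ = [
    "ReplicateSummary",
    "replicate_seeds",
    "run_replicates",
    "outcome_label",
    "extinction_generation",
    "sex_ratio",
    "mean_final_sex_ratio",
    "component_series",
    "drift_strength",
    "per_cell_variance",
    "series_to_csv",
]


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible, well-separated child seeds (31-bit)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def outcome_label(series: PopulationSeries) -> str:
    """Final-state label at the configured horizon: the sole surviving
    species, ``all_extinct``, or ``coexistence``."""
    final = series.counts[-1]
    survivors = [s for s, c in zip(series.species_ids, final) if c > 0]
    if not survivors:
        return "all_extinct"
    if len(survivors) == 1:
        return f"fixed:{survivors[0]}"
    return "coexistence"


@dataclass
class ReplicateSummary:
    """Aggregate of n replicate runs of one configuration."""

    species_ids: list[str]
    series: list[PopulationSeries]
    outcomes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.outcomes:
            self.outcomes = [outcome_label(s) for s in self.series]

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def fixation_fraction(self) -> dict[str, float]:
        """Per-species share of replicates in which it was the sole
        survivor (the remainder were still coexisting or empty)."""
        return {
            sid: sum(o == f"fixed:{sid}" for o in self.outcomes) / self.n
            for sid in self.species_ids
        }

    @property
    def mean_counts(self) -> np.ndarray:
        """Mean population series across replicates, shape
        (generations + 1, n_species)."""
        return np.mean([s.counts for s in self.series], axis=0)

    def survival_fraction(self, species_id: str) -> float:
        j = self.species_ids.index(species_id)
        return float(np.mean([s.counts[-1, j] > 0 for s in self.series]))

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n,
            "outcomes": list(self.outcomes),
            "fixation_fraction": self.fixation_fraction,
            "final_mean_counts": dict(
                zip(self.species_ids, self.mean_counts[-1].tolist())
            ),
        }


def run_replicates(
    cfg: HabitatConfig,
    n: Optional[int] = None,
    base_seed: Optional[int] = None,
    generations: Optional[int] = None,
    runner: Callable[..., PopulationSeries] = engine.run,
) -> ReplicateSummary:
    """Run n independently seeded replicates and aggregate outcomes.

    Defaults follow the configuration (ten replicates, its seed);
    results are deterministic given ``base_seed``.
    """
    n = cfg.replicates if n is None else n
    base = cfg.seed if base_seed is None else base_seed
    seeds = replicate_seeds(base, n)
    series = [
        runner(cfg, seed=s, generations=generations, replicate_id=i)
        for i, s in enumerate(seeds)
    ]
    return ReplicateSummary([s.id for s in cfg.species], series)


def extinction_generation(
    series: PopulationSeries, species_id: str
) -> Optional[int]:
    """First generation at which the species hits zero and never
    recovers; ``None`` if it is alive at the end of the series."""
    counts = series.series(species_id)
    if counts[-1] > 0:
        return None
    nonzero = np.flatnonzero(counts)
    return 0 if nonzero.size == 0 else int(nonzero[-1]) + 1


def sex_ratio(
    series: PopulationSeries, male_species: str, female_species: str
) -> np.ndarray:
    """Per-generation male:female ratio; NaN where females are absent."""
    males = series.series(male_species).astype(float)
    females = series.series(female_species).astype(float)
    out = np.full_like(males, np.nan)
    np.divide(males, females, out=out, where=females > 0)
    return out


def mean_final_sex_ratio(
    summaries: Sequence[PopulationSeries],
    male_species: str,
    female_species: str,
    last: int = 100,
) -> float:
    """Mean male:female ratio over the last ``last`` generations, pooled
    across replicates (NaN generations, where the strategy is absent,
    are ignored)."""
    tails = [
        sex_ratio(s, male_species, female_species)[-last:] for s in summaries
    ]
    return float(np.nanmean(np.concatenate(tails)))


def component_series(series: PopulationSeries, component: str) -> np.ndarray:
    """Population of a component species counting members inside
    composite organisms (an ``A|A`` group contributes two ``A``)."""
    total = np.zeros(series.counts.shape[0], dtype=np.int64)
    for sid in series.species_ids:
        mult = parse_species_id(sid).count(component)
        if mult:
            total = total + mult * series.series(sid)
    return total


def drift_strength(
    cell_counts: Sequence[int],
    n_replicates: int = 100,
    base_seed: int = 0,
    generations: int = 500,
) -> dict[int, tuple[int, int]]:
    """Fixation counts for the two-allele drift scenario per habitat
    size.

    For each habitat size, runs replicates of the loci-as-cells drift
    setup (global mixing) and counts those in which one allele has been
    lost by the horizon. Returns ``{n_cells: (n_fixed, n_replicates)}``;
    the fixed fraction decreases with habitat size, quantifying how
    larger populations buffer random genetic drift.
    """
    results: dict[int, tuple[int, int]] = {}
    for n_cells in cell_counts:
        cfg = make_scenario("Deri", cells=n_cells, generations=generations)
        summary = run_replicates(
            cfg,
            n=n_replicates,
            base_seed=base_seed,
            generations=generations,
            runner=engine.run_counts,
        )
        fixed = sum(
            1
            for s in summary.series
            if (s.counts[-1] == 0).any()
        )
        results[int(n_cells)] = (fixed, n_replicates)
    return results


def per_cell_variance(
    state: HabitatState, cfg: HabitatConfig
) -> dict[str, float]:
    """Variance of per-cell counts for every species (population
    variance over cells)."""
    n_cells = len(state.cells)
    per_cell = {s.id: np.zeros(n_cells, dtype=np.int64) for s in cfg.species}
    for i, cell in enumerate(state.cells):
        for org in cell.organisms:
            per_cell[org.species][i] += 1
    return {sid: float(np.var(v)) for sid, v in per_cell.items()}


def series_to_csv(series_list: Sequence[PopulationSeries], path: str) -> None:
    """Write replicate series as one tidy CSV (replicate, generation,
    species, count)."""
    pd.concat([s.to_dataframe() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )
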