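"""Dispersal of newborns across the linear lattice.

Three strategies, each parameterized by an intensity 0-100:

``n`` (neighbours)
    Local dispersal. Each newborn moves from its origin cell to a cell
    drawn uniformly from a window of neighbouring cells; the window
    half-width grows with the intensity, from 0 (stay home) to the whole
    lattice (uniform mixing).

``r`` (global random parcels)
    Global dispersal ignoring origin. At intensity 0 the pooled total is
    split exactly evenly over cells (zero variance); at 100 it is dealt
    out entirely as random-sized parcels to random cells (high
    variance); intermediate intensities split the total between the two
    regimes.

``h`` (global, reduced target cells)
    As ``r``, but the organisms land only on a subset of cells whose
    size shrinks with the intensity — at 100 a single cell receives
    everything, at 50 about half the cells stay empty.

The lattice is linear without wrap-around; edge cells simply have
truncated neighbour windows.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .config import DistributionSpec, HabitatConfig, Strategy

__all__ = [
    "neighbour_window",
    "neighbour_destinations",
    "distribute_neighbours",
    "distribute_global_avg",
    "distribute_global_by_cell",
    "disperse_counts",
    "do_distribute",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def neighbour_window(value: int, n_cells: int) -> int:
    """Window half-width for the ``n`` strategy."""
    return _round_half_up(value / 100.0 * (n_cells - 1))


def neighbour_destinations(
    origins: np.ndarray, value: int, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Destination cell for each organism under the ``n`` strategy.

    ``origins`` is an integer array of origin cell indices. Each
    organism draws uniformly from ``[max(0, i-w), min(C-1, i+w)]``.
    """
    origins = np.asarray(origins, dtype=np.int64)
    w = neighbour_window(value, n_cells)
    if w == 0 or n_cells == 1:
        return origins.copy()
    lo = np.maximum(origins - w, 0)
    hi = np.minimum(origins + w, n_cells - 1)
    return rng.integers(lo, hi + 1)


def distribute_neighbours(
    per_cell_newborns: Sequence[int],
    value: int,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-cell counts after local dispersal of per-cell newborn counts."""
    counts = np.asarray(per_cell_newborns, dtype=np.int64)
    if len(counts) != n_cells:
        raise ValueError("per_cell_newborns length must equal n_cells")
    origins = np.repeat(np.arange(n_cells), counts)
    dests = neighbour_destinations(origins, value, n_cells, rng)
    return np.bincount(dests, minlength=n_cells).astype(np.int64)


def _even_split(total: int, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Exact even split: quota everywhere, remainder dealt round-robin
    from a random start cell."""
    base, rem = divmod(total, n_cells)
    counts = np.full(n_cells, base, dtype=np.int64)
    if rem:
        start = int(rng.integers(0, n_cells))
        counts[(start + np.arange(rem)) % n_cells] += 1
    return counts


def distribute_global_avg(
    total: int, value: int, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell counts under the ``r`` strategy (origin ignored)."""
    if total < 0:
        raise ValueError("total must be >= 0")
    if total == 0:
        return np.zeros(n_cells, dtype=np.int64)
    if value == 0 or n_cells == 1:
        return _even_split(total, n_cells, rng)
    frac = value / 100.0
    n_random = _round_half_up(frac * total)
    counts = _even_split(total - n_random, n_cells, rng)
    max_parcel = max(1, math.ceil(frac * total / n_cells))
    remaining = n_random
    while remaining > 0:
        size = min(int(rng.integers(1, max_parcel + 1)), remaining)
        cell = int(rng.integers(0, n_cells))
        counts[cell] += size
        remaining -= size
    return counts


def distribute_global_by_cell(
    total: int, value: int, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell counts under the ``h`` strategy: the ``r`` distribution
    restricted to a shrinking random subset of target cells."""
    n_targets = max(1, _round_half_up((1.0 - value / 100.0) * n_cells))
    counts = np.zeros(n_cells, dtype=np.int64)
    if total == 0:
        return counts
    if n_targets >= n_cells:
        return distribute_global_avg(total, value, n_cells, rng)
    targets = rng.choice(n_cells, size=n_targets, replace=False)
    counts[targets] = distribute_global_avg(total, value, n_targets, rng)
    return counts


def disperse_counts(
    per_cell_newborns: Sequence[int],
    spec: DistributionSpec,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dispatch one species' per-cell newborn counts to its strategy."""
    counts = np.asarray(per_cell_newborns, dtype=np.int64)
    if spec.strategy is Strategy.NEIGHBOURS:
        return distribute_neighbours(counts, spec.value, n_cells, rng)
    total = int(counts.sum())
    if spec.strategy is Strategy.GLOBAL_AVG:
        return distribute_global_avg(total, spec.value, n_cells, rng)
    return distribute_global_by_cell(total, spec.value, n_cells, rng)


def do_distribute(
    per_cell_newborns: list[dict[str, int]],
    cfg: HabitatConfig,
    rng: np.random.Generator,
) -> list[dict[str, int]]:
    """Disperse every species' newborns, honouring per-species codes.

    Takes and returns one ``{species id: count}`` mapping per cell.
    Species are processed in declaration order; totals are conserved
    exactly per species.
    """
    n_cells = cfg.NumberOfCells
    out: list[dict[str, int]] = [{} for _ in range(n_cells)]
    for sp in cfg.species:
        origin = np.fromiter(
            (cell.get(sp.id, 0) for cell in per_cell_newborns),
            dtype=np.int64,
            count=n_cells,
        )
        if origin.sum() == 0:
            continue
        spec = cfg.effective_distribution(sp.id)
        placed = disperse_counts(origin, spec, n_cells, rng)
        for i in np.flatnonzero(placed):
            out[i][sp.id] = int(placed[i])
    return out
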