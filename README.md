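# evocell

A stochastic lattice simulator of coevolving digital organisms — an
evolutionary cellular automaton for studying how biological interactions
(cooperation, parasitism, symbiosis, sex) fare under natural selection
with nothing but resource competition and sampling noise.

## The model in one paragraph

A habitat is a line of cells, each renewed with a fixed resource budget
every generation. Digital organisms live in cells, belong to species,
and reproduce by consuming resources: **one consumed unit is one
descendant**, parents never survive, and when a cell's demand exceeds
its budget the organisms queue in random order. Species interact in two
ways. An **association** pairs organisms one-to-one within a cell; an
*actor* spends extra units (`IndirectOffspring`) that become descendants
of its partner's species, which is how altruism, parasitism and sexual
reproduction are encoded. A **grouping** fuses two organisms into a
composite species (`"A|B"`) with its own parameters, which is how
eusocial colonies, symbionts and infections are encoded;
`PhenotypicFlexibility` controls how readily organisms group and how
many newborn groups stay fused. Finally newborns disperse under one of
three strategies — `n` (neighbour windows), `r` (global, from exactly
even to random parcels), `h` (global onto a shrinking subset of cells) —
each with an intensity from 0 to 100. Everything downstream — genetic
drift, Fisher's 1:1 sex ratio, the collapse of eusociality in uniformly
fragmented habitats, the Red Queen advantage of sex under pathogens —
emerges from these rules.

## Worked example: competitive exclusion

Two species share one niche; the more fecund excludes the other.

```sh
evocell scenario Exclu --run --seed 5 --out Exclu.json
```

This writes the generated configuration to `Exclu.json` and runs the
ten-replicate protocol, producing `Exclu-out/populations.csv` (tidy
per-generation counts), `summary.json` and `run.json`. With seed 5 the
summary reports

```
"fixation_fraction": {"Efficient": 1.0, "Inefficient": 0.0}
```

and the first replicate's series shows the exclusion and the Law of
Constant Final Yield (30 cells × 10 units = 300 organisms at
saturation):

```
 generation     species  count
          0   Efficient     50
          0 Inefficient     50
         50   Efficient    300
         50 Inefficient      0
```

The same from Python:

```python
from evocell import analysis, make_scenario

cfg = make_scenario("Exclu")
summary = analysis.run_replicates(cfg, n=10, base_seed=5)
print(summary.fixation_fraction)   # {'Efficient': 1.0, 'Inefficient': 0.0}
```

## Scenario catalogue

`evocell scenario x --list` prints all bundled study scenarios with
their expected qualitative outcome. Highlights:

| name | question | expected outcome |
| --- | --- | --- |
| `Deri` / `DeriSP` / `Hardy` | genetic & ecological drift | fixation at small habitat sizes; allele balance at ≥1000 loci |
| `Colab` | solitary vs collaborative vs eusocial bees | uniform fragmentation penalizes eusociality |
| `Eu2` | kin-selection vs multilevel-selection encodings | functionally equivalent |
| `Symb` (variants 1–5) | free-living → obligate endosymbiosis | symbiosis prevails as group flexibility grows |
| `Fish` | competing sex-ratio strategies | 1:1 prevails (≈1.005 measured) |
| `Sex2` (variants 1–8) | sex vs asex ± Red Queen pathogen | asexuals win unless pathogens hit them harder |
| `Squi`, `Pavo` | kin adoption; male coalitions | cooperative lineage prevails |

Custom experiments use a small JSON dialect (see `docs/methods.md`);
`evocell run config.json` executes it, and `evocell resume` continues a
saved checkpoint deterministically.

## Tests and reproduction

```sh
python -m pytest tests        # ~2 minutes; includes the acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the package's quantitative target: the
long-run male:female ratio of the surviving strategy in the
Fisher's-principle scenario (10 replicates × 600 generations ×
100 cells, pooled over the last 100 generations). With `--seed 1` it
reports `{"t2": {"value": 1.0047, "n": 1000}}`, within the documented
±0.05 tolerance of the predicted 1.0 (seed 77 gives 0.9992).

Runs are reproducible end to end: replicate seeds derive from the base
seed via `numpy.random.SeedSequence`, and `run.json` records the seed,
package version and a configuration hash.

## Layout

```
src/evocell/
  config.py      JSON dialect, species/habitat parameters, validation
  accounting.py  association roles, consumption demand, offspring realization
  dispersal.py   the n / r / h dispersal strategies
  engine.py      the per-generation transition function and runners
  scenarios.py   programmatic generators for the study scenarios
  analysis.py    replicate protocol, outcome labels, drift/sex-ratio stats
  cli.py         evocell run / scenario / resume
docs/methods.md  model definition, numerical choices, limitations
```
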