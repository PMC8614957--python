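# Methods

This document defines the simulation model exactly as implemented,
records the numerical and design choices, and lists known limitations.

## 1. Model definition

### 1.1 Habitat and organisms

The habitat is a linear lattice of `NumberOfCells` cells without
wrap-around. Every cell receives `NumberOfRsrcsInEachCell` resource
units at the start of each generation; unconsumed units vanish. A
digital organism occupies one slot in one cell, belongs to a species,
and carries a direct-offspring count `Df`, an indirect-offspring count
`If`, a per-generation association role, and (for donors) the partner
species of its pairing. The sum `F = Df + If` — the inclusive fitness —
is a fixed property of the species definition and is never changed by
any operation.

Fixed characteristics: one consumed unit always yields exactly one
descendant; every cell has the same budget; interactions are one-to-one
within a cell; resources are accessed by queueing in uniformly random
order with no hierarchy; generational change is simultaneous across the
habitat; parents never survive; there are no mutations (checkpoint
save/edit/resume substitutes for them); habitat parameters do not change
during a run.

### 1.2 The transition function

Each generation applies, in order:

1. **doGrouping** — per cell, every species with a non-empty
   `GroupPartner` list may fuse with partners into composite organisms
   of species `"Initiator|Partner"`. The number of groups formed with a
   partner is `stochastic_round(PF × quorum)`, where `PF` is the
   *initiator's* `PhenotypicFlexibility` and the quorum is the number of
   feasible pairs (for self-partnering, `floor(available / 2)`). With
   several partners the initiator's organisms are apportioned to
   partners proportionally to partner populations (largest-remainder
   method). Species are processed components-first, so composites can
   themselves group where configured.
2. **doAssociation** — per cell, organisms pair one-to-one with their
   `AssociatedSpecies`. Pairing is exhaustive: couples per cell equal
   the lower quorum of the two populations (the *quorum-decreasing
   effect*). A one-way listing makes the lister an **actor** and its
   partner a **recipient**; mutual listings make both **reciprocal**
   (intra- or inter-specific). Leftover organisms stay individuals.
3. **doEnqueuingConsumeAndOffspring** — per cell, organisms demand
   `Df` units (individuals, recipients) or `Df + If` units (actors,
   reciprocals). If total demand fits the budget everyone is fully fed;
   otherwise organisms consume in a uniformly random queue order, each
   taking `min(demand, remaining)`. Consumed units are realized
   **direct-first**: the first `min(consumed, Df)` units become
   descendants of the organism's own species, the remainder become
   descendants of the *partner's* species (the transfer). Unit
   conservation — own + transferred = consumed ≤ budget — is exact.
4. **doUngroup** — newborn composites split back into components, most
   complex first. A composite keeps a `stochastic_round(PF_group × n)`
   share of its newborns fused; the rest split one level,
   left-associatively (`"X|Y" → "X" + "Y"`), and split products may
   split again in the same sweep.
5. **varia** (optional) — every newborn of a species with
   `FitnessVariationLimit = L > 0` draws `U ~ uniform{-L..L}` and gets
   `direct = clamp(Df + U, 0, F)`, `indirect = F − direct`. Draws are
   per-newborn and not heritable.
6. **doDistribute** — each species' newborns disperse under the
   species' `Distribution` code if set (vagility), else the habitat's
   (permeability). Codes are `<intensity 0–100><strategy n|r|h>`:
   * `n`: each newborn moves from its origin cell uniformly within a
     window of half-width `round_half_up(intensity/100 × (C−1))`,
     truncated at the edges;
   * `r`: origins are ignored; a `1 − intensity/100` share of the pooled
     total is split exactly evenly (remainder dealt round-robin from a
     random start), the rest lands as random parcels of uniform size
     `1..max(1, ceil(intensity/100 × total/C))` on random cells;
   * `h`: the `r` procedure restricted to
     `max(1, round((1 − intensity/100) × C))` randomly chosen target
     cells — at 100, one cell receives everything.
   Species totals are conserved exactly by every strategy.

The study protocol runs ten independently seeded replicates per
configuration and records per-generation, per-species totals.

### 1.3 Fitness encodings used by the scenario suite

* solitary reproduction: `Df` alone;
* altruism/cooperation: association with `If > 0` spent on the partner;
* sexual reproduction: a mutual male/female association with `Df = 0` —
  all descendants arise from transfers, the female's `If` are her sons
  and the male's his daughters, so a fed couple with `If = 4/4` leaves
  8 children, 4 like each parent (no twofold cost of sex in
  like-parent fitness);
* eusociality/symbiosis: grouping into a composite with its own
  fitness; the composite's own `PhenotypicFlexibility` sets colony
  persistence;
* infection: grouping with a pathogen species; the host's flexibility is
  the infection probability, the infected group's `Df` the surviving
  brood (lethality), and group flexibility 0 means offspring are born
  uninfected while the free-living pathogen re-emerges each generation.

## 2. Numerical choices

* **RNG.** `numpy.random.default_rng` (PCG64) throughout; one stream per
  replicate. Replicate seeds derive from the base seed through
  `SeedSequence.generate_state`, masked to 31 bits. Checkpoints
  serialize the exact bit-generator state, so a resumed run reproduces
  the uninterrupted one bit for bit.
* **Stochastic rounding.** Fractional expectations (groups formed,
  groups staying fused) are realized as `floor(x) + Bernoulli(frac(x))`
  — unbiased, integer-valued.
* **Apportionment.** Multi-target splits (several group partners or
  associates) use the largest-remainder method over target populations,
  ties broken by declaration order.
* **Fast paths.** Three distributionally exact shortcuts keep large
  experiments cheap: (i) when a cell's demand fits its budget, the
  queue is skipped; (ii) in a shortage cell whose organisms are all
  solitary with one common demand, the fed set is a uniform random
  subset and is drawn via a multivariate hypergeometric instead of an
  explicit queue; (iii) `engine.run_counts` steps whole habitats of such
  configurations as count matrices (used for the 100- vs 1000-cell
  drift comparison). Equivalence with the explicit queue is verified in
  the test suite against an exhaustive enumeration of queue orders for
  the heterozygous single-cell drift state, whose exact law is 1/6
  fixation to either allele and 4/6 heterozygote.

## 3. Scenario realism and validation

Scenario generators encode classic questions with the smallest faithful
parameter set; where source parameterizations are not published, knobs
are exposed with documented defaults and the validation is qualitative.
Representative measured outcomes (fixed seeds, ten replicates unless
noted):

* drift: 68/100 replicates fixed at 100 cells vs 0/100 at 1000 cells
  after 500 generations (Fisher exact p ≈ 5 × 10⁻²⁹);
* Fisher's principle: surviving-strategy sex ratio 1.0047 (seed 1,
  n = 1000 pooled generation samples; 0.9992 with seed 77);
* bees: with equal per-capita fitness under uniform local mixing the
  solitary strategy wins and the eusocial one dies out (the dissolving
  two-bee colony wastes an odd bee per cell per generation); handicapping
  the solitary bee rescues it only under aggregated (`100r`) dispersal;
* eusociality encodings: association-based and persistent-colony-based
  cooperation coexist while solitary bees go extinct (9/10 replicates);
* sex: without pathogens the asexual clone fixes 10/10 despite equal
  like-parent fitness (quorum-decreasing effect); with a pathogen that
  infects asexuals more and kills their brood harder (variant 8) the
  sexual pair prevails 10/10.

## 4. Design decisions

* **Donor demand.** An actor or reciprocal demands `Df + If`; an
  individual or recipient demands `Df`. Transfers become descendants of
  the recipient's species, realized only after the donor's own brood
  (direct-first). This makes transfer-based strategies sensitive to
  shortage by construction.
* **Varia is non-heritable** and applied at materialization of each
  newborn, so placement order cannot change the law of the next state.
* **Ungrouping order** is most-complex-first with one-level,
  left-associative splits; split products can split again within the
  sweep, so full dissolution is expressible.
* **Self-sustaining pathogen.** The free-living pathogen in the Red
  Queen scenarios has `Df = 2`: a bare-replacement pathogen burns out
  after the first epidemic wave under resource competition, which
  contradicts the intended persistent epidemic.
* **Parasitism under direct-first.** Because shortage starves transfers
  first, a high-demand host never delivers its parasite's brood at
  saturation; the brood-parasitism scenario therefore uses a
  single-chick host (`Df = 1, If = 1`), the boundary case where the
  second consumed unit is always the transfer.

## 5. Limitations

* The lattice is strictly 1-D and non-toroidal; 2-D habitats are out of
  scope.
* No mutation, learning or adaptation operators; parameter changes
  mid-run go through checkpoint save/edit/resume.
* Grouping is pairwise per operation; larger colonies arise only through
  nested composites explicitly declared as species.
* In the Red Queen suite the single-factor variants (higher infection
  *or* higher lethality for asexuals alone) sit near a threshold that
  depends on unpublished pathogen parameters; with this package's
  defaults the asexual clone still prevails in those intermediate
  variants, while the no-pathogen and both-factors variants behave as
  expected. Treat intermediate-variant outcomes as parameter-sensitive.
* Squirrel-adoption and turkey-coalition scenarios are qualitative: the
  source populations' exact parameters are not published, so the
  scenarios demonstrate the mechanism (cooperative lineage beats drift)
  rather than reproduce specific tallies.
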