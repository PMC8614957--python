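"""Programmatic generators for the named study scenarios.

Each scenario builds a complete, validated :class:`HabitatConfig` for a
classic eco-evolutionary question: competitive exclusion, genetic and
ecological drift, Hardy-Weinberg equilibrium, the evolution of
eusociality, host-symbiont mutualism, kin-selected cooperation, sex-ratio
evolution (Fisher's principle) and the maintenance of sex under pathogen
pressure (Red Queen). Parameters that matter are exposed as keyword
knobs with documented defaults; everything returned passes
``validate_config``.

Fitness encodings used throughout:

* a solitary species reproduces via ``DirectOffspring``;
* intra-specific cooperation is a mutual self-association: each paired
  member spends ``IndirectOffspring`` extra units that become partner's
  (same-species) descendants;
* sexual reproduction is a mutual male/female association with
  ``DirectOffspring = 0``: all descendants arise from the transfers, so
  the female's ``IndirectOffspring`` sets the number of sons and the
  male's the number of daughters;
* eusociality/symbiosis is grouping: two organisms fuse into a
  composite species with its own fitness; the composite's
  ``PhenotypicFlexibility`` sets how many newborn groups stay grouped;
* infection is grouping with a pathogen: the host's
  ``PhenotypicFlexibility`` is the infection probability and the
  infected group's ``DirectOffspring`` the surviving brood size
  (lethality); the group's flexibility of 0 means offspring are born
  uninfected while the pathogen re-emerges for the next generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from .config import (
    DistributionSpec,
    HabitatConfig,
    SpeciesDef,
    parse_distribution_code,
    validate_config,
)

__all__ = [
    "ScenarioSpec",
    "make_scenario",
    "list_scenarios",
    "scenario_names",
    "generations_for_years",
]


@dataclass
class ScenarioSpec:
    """Catalogue entry: generator name, knobs, and the qualitative
    outcome the scenario is expected to show."""

    name: str
    description: str
    expected: str
    variant: Optional[int] = None
    parameters: dict[str, Any] = field(default_factory=dict)

    def build(self, **overrides: Any) -> HabitatConfig:
        kwargs = dict(self.parameters)
        kwargs.update(overrides)
        if self.variant is not None:
            kwargs.setdefault("variant", self.variant)
        return make_scenario(self.name, **kwargs)


def generations_for_years(years: float, generation_time: float) -> int:
    """Number of whole generations elapsed in a span of years."""
    if generation_time <= 0:
        raise ValueError(f"generation time must be > 0, got {generation_time}")
    return int(math.floor(years / generation_time))


def _species(sid: str, items: int = 0, direct: int = 0, indirect: int = 0,
             partners: Optional[list[str]] = None, pf: float = 0.0,
             associates: Optional[list[str]] = None, varia_limit: int = 0,
             distribution: Optional[str] = None) -> SpeciesDef:
    return SpeciesDef(
        id=sid,
        NumberOfItems=items,
        DirectOffspring=direct,
        IndirectOffspring=indirect,
        Distribution=parse_distribution_code(distribution) if distribution else None,
        GroupPartner=list(partners or []),
        PhenotypicFlexibility=pf,
        AssociatedSpecies=list(associates or []),
        FitnessVariationLimit=varia_limit,
    )


def _config(cells: int, resources: int, code: str, species: list[SpeciesDef],
            generations: int, seed: int = 0, replicates: int = 10,
            varia: bool = False) -> HabitatConfig:
    cfg = HabitatConfig(
        NumberOfCells=cells,
        NumberOfRsrcsInEachCell=resources,
        Distribution=parse_distribution_code(code),
        species=species,
        generations=generations,
        replicates=replicates,
        seed=seed,
        varia=varia,
    )
    diags = validate_config(cfg)
    if diags:  # pragma: no cover - generator bug guard
        raise AssertionError(f"scenario produced invalid config: {diags}")
    return cfg


# ---------------------------------------------------------------------------
# generators


def _lcfy(cells: int = 20, resources: int = 10, direct: int = 5,
          items: int = 10, generations: int = 50, code: str = "100n",
          **_: Any) -> HabitatConfig:
    """Law of Constant Final Yield: one species, finite resources; the
    total population plateaus at cells x resources regardless of seed
    density."""
    return _config(cells, resources, code,
                   [_species("Plant", items, direct)], generations)


def _pred(cells: int = 30, resources: int = 12, direct: int = 3,
          items: int = 30, generations: int = 100, **_: Any) -> HabitatConfig:
    """Predation read as consumption: cell resources are the prey; the
    predator's numbers track resource availability (numerical
    response)."""
    return _config(cells, resources, "100n",
                   [_species("Predator", items, direct)], generations)


def _amen(cells: int = 30, resources: int = 15, generations: int = 150,
          **_: Any) -> HabitatConfig:
    """Amensalism without actor cost: the eucalyptus pre-empts shared
    resources with a higher reproductive draw; the understory plant is
    crowded out at no expense to the tree."""
    return _config(cells, resources, "100n",
                   [_species("Eucalyptus", 50, 5), _species("Plant", 50, 3)],
                   generations)


def _amen2(cells: int = 30, resources: int = 15, harm_rate: float = 0.5,
           generations: int = 150, **_: Any) -> HabitatConfig:
    """Amensalism with actor cost: plants caught under a eucalyptus fuse
    into a sterile pair (group fitness 0), so the harming tree in the
    pair also forfeits its own offspring."""
    return _config(cells, resources, "100n", [
        _species("Eucalyptus", 50, 4),
        _species("Plant", 50, 3, partners=["Eucalyptus"], pf=harm_rate),
        _species("Plant|Eucalyptus", 0, 0, pf=0.0),
    ], generations)


def _para(cells: int = 30, resources: int = 20, generations: int = 100,
          **_: Any) -> HabitatConfig:
    """Brood parasitism: the host is an unwitting actor that splits its
    budget between one own chick and one cuckoo chick. Because realized
    offspring are direct-first, a host with a large own brood would keep
    every scarce unit for itself; the single-chick host keeps the
    transfer flowing even under shortage, so the rare cuckoo multiplies
    at the host's expense."""
    return _config(cells, resources, "100n", [
        _species("Host", 120, 1, 1, associates=["Cuckoo"]),
        _species("Cuckoo", 20, 1),
    ], generations)


def _exclu(cells: int = 30, resources: int = 10, generations: int = 200,
           **_: Any) -> HabitatConfig:
    """Competitive exclusion: two species on one niche; the more
    fecund excludes the other."""
    return _config(cells, resources, "100n",
                   [_species("Efficient", 50, 5), _species("Inefficient", 50, 4)],
                   generations)


def _intra(cells: int = 20, resources: int = 8, generations: int = 100,
           **_: Any) -> HabitatConfig:
    """Intra-specific competition with fitness variability: one species,
    tight resources, varia on — only organisms drawing high direct
    offspring convert scarce units into descendants."""
    cfg = _config(cells, resources, "100n",
                  [_species("Competitor", 60, 3, varia_limit=2)],
                  generations, varia=True)
    return cfg


def _neu(cells: int = 50, resources: int = 30, generations: int = 100,
         **_: Any) -> HabitatConfig:
    """Neutralism: two non-interacting species under ample resources
    keep in balance."""
    return _config(cells, resources, "100n",
                   [_species("First", 50, 3), _species("Second", 50, 3)],
                   generations)


def _comm(cells: int = 30, resources: int = 30, generations: int = 100,
          **_: Any) -> HabitatConfig:
    """Commensalism: the host spends one indirect unit that becomes a
    commensal descendant; under ample resources the host's own output is
    unaffected while the commensal benefits."""
    return _config(cells, resources, "100n", [
        _species("Host", 40, 4, 1, associates=["Commensal"]),
        _species("Commensal", 20, 3),
    ], generations)


def _proto(cells: int = 25, resources: int = 20, generations: int = 200,
           **_: Any) -> HabitatConfig:
    """Protocooperation: a mutual inter-specific reciprocal pair whose
    members each net four descendants when paired, against a solitary
    competitor netting three."""
    return _config(cells, resources, "100n", [
        _species("PartnerA", 50, 2, 2, associates=["PartnerB"]),
        _species("PartnerB", 50, 2, 2, associates=["PartnerA"]),
        _species("Loner", 50, 3),
    ], generations)


def _colab(cells: int = 100, resources: int = 20, items: int = 200,
           solitary_direct: int = 5, code: str = "100n",
           generations: int = 150, **_: Any) -> HabitatConfig:
    """Three bee life-histories in competition, equal per-capita
    fitness: solitary A (5 direct), intra-specific collaborator B
    (4 direct + 1 shared with its partner), and eusocial C whose bees
    are sterile alone and fuse into pairs that reproduce as one unit.

    Eusocial pairs dissolve every generation (group flexibility 0), so
    in fragmented, uniformly mixed habitats an odd bee per cell is
    wasted each generation — the parity cost of sociality. Knobs:
    ``solitary_direct`` (lower it to 4 to handicap A) and ``code``
    (``"100r"`` for an aggregated redistribution)."""
    return _config(cells, resources, code, [
        _species("A", items, solitary_direct),
        _species("B", items, 4, 1, associates=["B"]),
        _species("C", items, 0, partners=["C"], pf=1.0),
        _species("C|C", 0, 5, pf=0.0),
    ], generations)


def _eu2(cells: int = 10, resources: int = 240, items: int = 300,
         generations: int = 150, **_: Any) -> HabitatConfig:
    """Eusociality two ways: kin-selection bees cooperate by mutual
    intra-specific association (2 direct + 4 donated each, inclusive 6),
    multilevel-selection bees fuse into persistent two-bee colonies
    (group fitness 6, flexibility 1 so newborn colonies stay grouped).
    Both carry the +1 cooperation bonus over solitary bees (5), and the
    two encodings are functionally equivalent."""
    return _config(cells, resources, "100n", [
        _species("Solitary", items, 5),
        _species("Ham", items, 2, 4, associates=["Ham"]),
        _species("Wil", items, 0, partners=["Wil"], pf=1.0),
        _species("Wil|Wil", 0, 6, pf=1.0),
    ], generations)


def _symb(cells: int = 30, resources: int = 20, flexibility: float = 0.9,
          infection: float = 0.5, group_direct: int = 5,
          generations: int = 100, variant: Optional[int] = None,
          **_: Any) -> HabitatConfig:
    """Host-bacterium symbiosis: stinkbugs acquire bacteria by grouping;
    the fused pair gains a vertical-transmission fitness bonus. The
    group's flexibility (persistence of the symbiotic state) is the
    knob: at low values associations dissolve back to free life, at high
    values symbiosis prevails and free-living bacteria dwindle.
    ``variant`` 1-5 sweeps flexibility over 0.1, 0.3, 0.5, 0.7, 0.9."""
    if variant is not None:
        if not 1 <= variant <= 5:
            raise ValueError(f"Symb variant must be 1-5, got {variant}")
        flexibility = [0.1, 0.3, 0.5, 0.7, 0.9][variant - 1]
    return _config(cells, resources, "100n", [
        _species("Stinkbug", 60, 4, partners=["Bacterium"], pf=infection),
        _species("Bacterium", 60, 2),
        _species("Stinkbug|Bacterium", 0, group_direct, pf=flexibility),
    ], generations)


def _deri(cells: int = 100, resources: int = 4, generations: int = 100,
          **_: Any) -> HabitatConfig:
    """Random genetic drift: each cell is a locus, each organism an
    allele. Four resources per cell limit the reproducing alleles to two
    per locus, each replicating twofold, so a heterozygous locus can
    move to either homozygote or stay mixed purely by queue luck.
    Habitat size (the number of loci, with global mixing) sets the
    strength of drift."""
    return _config(cells, resources, "100n", [
        _species("A", cells, 2),
        _species("B", cells, 2),
    ], generations)


def _derisp(cells: int = 10, resources: int = 4, items: int = 20,
            generations: int = 200, **_: Any) -> HabitatConfig:
    """Ecological drift: two species with identical parameters in a
    small habitat; sampling error alone extinguishes one of them."""
    return _config(cells, resources, "100n", [
        _species("Sp1", items, 2),
        _species("Sp2", items, 2),
    ], generations)


def _hardy(cells: int = 1000, resources: int = 4, generations: int = 100,
           **_: Any) -> HabitatConfig:
    """Hardy-Weinberg: the drift setup scaled up until allele
    frequencies hold steady over the horizon — equilibrium without
    selection. Shrink the habitat (or resources) to find the scale at
    which the principle starts to fail."""
    return _config(cells, resources, "100n", [
        _species("A", cells, 2),
        _species("B", cells, 2),
    ], generations)


def _fish(cells: int = 100, resources: int = 16, items: int = 200,
          biased_sons: int = 6, generations: int = 600,
          **_: Any) -> HabitatConfig:
    """Fisher's principle: two sex-ratio strategies compete, each a
    mutual male/female association with direct offspring 0 (no couple,
    no brood). A female's indirect offspring are her sons and a male's
    his daughters, so the balanced strategy begets 4 sons + 4 daughters
    per couple while the biased strategy begets ``biased_sons`` sons and
    ``8 - biased_sons`` daughters. Couples per cell are capped by the
    scarcer sex, so the 1:1 strategy wastes fewer partners and
    prevails."""
    if not 0 <= biased_sons <= 8:
        raise ValueError("biased_sons must be within a brood of 8")
    return _config(cells, resources, "100n", [
        _species("MaleEven", items, 0, 4, associates=["FemaleEven"]),
        _species("FemaleEven", items, 0, 4, associates=["MaleEven"]),
        _species("MaleBiased", items, 0, 8 - biased_sons,
                 associates=["FemaleBiased"]),
        _species("FemaleBiased", items, 0, biased_sons,
                 associates=["MaleBiased"]),
    ], generations)


# Red Queen variants: (asexual infection, sexual infection,
#                      infected-asexual brood, infected-sexual brood)
_SEX2_VARIANTS: dict[int, tuple[float, float, int, int]] = {
    2: (0.50, 0.50, 2, 2),
    3: (0.80, 0.50, 2, 2),
    4: (0.75, 0.50, 2, 2),
    5: (0.50, 0.50, 1, 2),
    7: (0.50, 0.50, 1, 3),
    8: (0.80, 0.50, 1, 3),
}


def _sex2(variant: int = 1, cells: int = 100, resources: int = 16,
          items: int = 200, pathogen_items: int = 500,
          generations: int = 200, **_: Any) -> HabitatConfig:
    """Sex versus asex, optionally under pathogen pressure.

    The sexual species is a male/female reciprocal pair (0 direct, 4
    indirect each: a fed couple leaves 4 sons and 4 daughters); the
    asexual clone leaves 4 — like-parent fitness is equal, removing the
    twofold cost of sex. Variant 1 has no pathogen: sampling error in
    per-cell sex ratios (the quorum-decreasing effect) alone sinks the
    sexuals. Variants 2-8 add a pathogen that infects hosts by grouping;
    the host's flexibility is its infection probability and the infected
    group's direct offspring its surviving brood. The free-living
    pathogen's own fitness of 2 keeps it self-sustaining, so it stays
    active across generations instead of burning out after the first
    epidemic wave. Variant 8 (asexuals both more infected and more
    harmed) lets the sexuals prevail.
    Variant 6 is the polygamy setup (see the Sex3 scenario)."""
    if variant == 6:
        return _sex3(cells=cells, resources=resources, items=items,
                     generations=generations)
    if variant == 1:
        return _config(cells, resources, "100n", [
            _species("Male", items, 0, 4, associates=["Female"]),
            _species("Female", items, 0, 4, associates=["Male"]),
            _species("Asexual", items, 4),
        ], generations)
    if variant not in _SEX2_VARIANTS:
        raise ValueError(f"Sex2 variant must be 1-8, got {variant}")
    inf_a, inf_s, brood_a, brood_s = _SEX2_VARIANTS[variant]
    return _config(cells, resources, "100n", [
        _species("Male", items, 0, 4, associates=["Female"],
                 partners=["Pathogen"], pf=inf_s),
        _species("Female", items, 0, 4, associates=["Male"],
                 partners=["Pathogen"], pf=inf_s),
        _species("Asexual", items, 4, partners=["Pathogen"], pf=inf_a),
        _species("Pathogen", pathogen_items, 2),
        _species("Male|Pathogen", 0, brood_s, pf=0.0),
        _species("Female|Pathogen", 0, brood_s, pf=0.0),
        _species("Asexual|Pathogen", 0, brood_a, pf=0.0),
    ], generations)


def _sex3(cells: int = 100, resources: int = 16, items: int = 200,
          generations: int = 200, **_: Any) -> HabitatConfig:
    """Polygamy by grouping: males fuse with a female into a breeding
    group that reproduces as one unit and dissolves each generation.
    The quorum-decreasing effect applies to the scarcer sex exactly as
    in the monogamous association, and the asexual clone prevails."""
    return _config(cells, resources, "100n", [
        _species("Male", items, 0, partners=["Female"], pf=1.0),
        _species("Female", items, 0),
        _species("Male|Female", 0, 4, pf=0.0),
        _species("Asexual", items, 4),
    ], generations)


def _squi(cells: int = 20, resources: int = 20, items: int = 50,
          adoption_benefit: int = 1, generations: int = 300,
          q_enabled: bool = True, **_: Any) -> HabitatConfig:
    """Kin adoption in squirrels: the adopting lineage gains extra kin
    (an intra-specific association worth ``adoption_benefit`` indirect
    offspring per paired adopter) while the competing lineage relies on
    drift alone. With the benefit disabled both lineages are equal and
    only ecological drift separates them."""
    adopter = (
        _species("Adopter", items, 4, adoption_benefit, associates=["Adopter"])
        if q_enabled
        else _species("Adopter", items, 4)
    )
    return _config(cells, resources, "100n",
                   [adopter, _species("NonAdopter", items, 4)], generations)


def _pavo(cells: int = 20, resources: int = 20, items: int = 50,
          coalition_bonus: int = 1, generations: int = 200,
          **_: Any) -> HabitatConfig:
    """Turkey coalitions: partnered males (mutual intra-specific
    association, each donating ``coalition_bonus`` to the partnership)
    out-reproduce solitary males and exclude them within a few
    generations."""
    return _config(cells, resources, "100n", [
        _species("Coalition", items, 4, coalition_bonus,
                 associates=["Coalition"]),
        _species("SolitaryMale", items, 4),
    ], generations)


_GENERATORS: dict[str, Callable[..., HabitatConfig]] = {
    "LCFY": _lcfy, "Pred": _pred, "Amen": _amen, "Amen2": _amen2,
    "Para": _para, "Exclu": _exclu, "Intra": _intra, "Neu": _neu,
    "Comm": _comm, "Proto": _proto, "Colab": _colab, "Eu2": _eu2,
    "Symb": _symb, "Deri": _deri, "DeriSP": _derisp, "Hardy": _hardy,
    "Fish": _fish, "Sex2": _sex2, "Sex3": _sex3, "Squi": _squi,
    "Pavo": _pavo,
}

_EXPECTED: dict[str, str] = {
    "LCFY": "Resources control population",
    "Pred": "Resources grow, the population grows",
    "Amen": "Eucalyptus crowds out other plants at no cost",
    "Amen2": "Eucalyptus kills other plants",
    "Para": "The cuckoo survives",
    "Exclu": "The most efficient excludes the other",
    "Intra": "Only the fittest live",
    "Neu": "They keep in balance",
    "Comm": "Only one benefits",
    "Proto": "Proto-cooperation prevails",
    "Colab": "Social bees prevail only when habitat favours interaction",
    "Eu2": "Kin-selection and multilevel-selection bees are equivalent",
    "Symb": "Symbiosis prevails at high flexibility",
    "Deri": "It tends towards homozygosity",
    "DeriSP": "Populations are extinct due to sampling errors",
    "Hardy": "Allele balance without natural selection",
    "Fish": "The sex ratio 1:1 prevails",
    "Sex2": "Asexuals prevail unless pathogens hit them harder",
    "Sex3": "In polygamy, asexual organisms also prevail",
    "Squi": "The adopting lineage prevails slightly over drift",
    "Pavo": "Coalitions exclude solitary males",
}

_DESCRIPTIONS: dict[str, str] = {
    "LCFY": "Law of Constant Final Yield: resource budget caps the population",
    "Pred": "Numerical response of a consumer to its resource supply",
    "Amen": "Amensalism by resource pre-emption, no actor cost",
    "Amen2": "Amensalism by sterile grouping, actor pays a cost",
    "Para": "Brood parasitism: host raises the parasite's offspring",
    "Exclu": "Competitive exclusion on a single niche",
    "Intra": "Intra-specific competition with fitness variability",
    "Neu": "Neutral coexistence under ample resources",
    "Comm": "Commensalism: one benefits, the other unaffected",
    "Proto": "Facultative mutual benefit beats a solitary strategy",
    "Colab": "Solitary, collaborative and eusocial bees under fragmentation",
    "Eu2": "Kin-selection vs multilevel-selection encodings of eusociality",
    "Symb": "From free-living bacteria to obligate endosymbiosis",
    "Deri": "Random genetic drift at loci-as-cells",
    "DeriSP": "Ecological drift: extinction by sampling error",
    "Hardy": "Hardy-Weinberg equilibrium at large habitat scale",
    "Fish": "Competing sex-ratio strategies (Fisher's principle)",
    "Sex2": "Sexual vs asexual reproduction, optional Red Queen pathogen",
    "Sex3": "Sexual reproduction via breeding groups (polygamy)",
    "Squi": "Kin adoption benefit vs ecological drift",
    "Pavo": "Male coalitions under Hamilton's rule",
}

# scenarios whose study design enumerates printed variants
_VARIANTS: dict[str, list[int]] = {
    "Sex2": [1, 2, 3, 4, 5, 6, 7, 8],
    "Symb": [1, 2, 3, 4, 5],
}


def scenario_names() -> list[str]:
    return list(_GENERATORS)


def make_scenario(name: str, **knobs: Any) -> HabitatConfig:
    """Build the named scenario's configuration.

    Unknown names raise ``KeyError`` listing the valid ones; scenario
    knobs (cells, resources, fitness values, variant, ...) are keyword
    arguments with documented defaults.
    """
    try:
        gen = _GENERATORS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {', '.join(_GENERATORS)}"
        ) from None
    return gen(**knobs)


def list_scenarios() -> list[ScenarioSpec]:
    """The full catalogue with descriptions and expected outcomes."""
    specs = []
    for name in _GENERATORS:
        for variant in _VARIANTS.get(name, [None]):
            specs.append(
                ScenarioSpec(
                    name=name,
                    description=_DESCRIPTIONS[name],
                    expected=_EXPECTED[name],
                    variant=variant,
                )
            )
    return specs
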