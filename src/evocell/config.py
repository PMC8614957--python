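"""Configuration data model for habitat simulations.

A run is described by a single JSON document with three blocks::

    {
      "habitat": {"NumberOfCells": 100,
                  "NumberOfRsrcsInEachCell": 20,
                  "Distribution": "100n"},
      "species": [
        {"id": "A", "NumberOfItems": 200, "DirectOffspring": 5,
         "IndirectOffspring": 0, "GroupPartner": [],
         "PhenotypicFlexibility": 0.0, "AssociatedSpecies": [],
         "FitnessVariationLimit": 0},
        ...
      ],
      "run": {"generations": 200, "replicates": 10, "seed": 1,
              "varia": false}
    }

Habitat and species field names follow the simulator's established
parameter vocabulary (``NumberOfCells``, ``DirectOffspring``, ...) so
configurations remain readable across tools; the ``run`` block
(generations, replicates, seed, varia) is this package's addition for
reproducible batch execution.

Species identifiers may be composite: a group of species ``A`` and ``B``
is itself a species with id ``"A|B"``, which must be declared explicitly
with its own parameters. Dispersal codes are strings such as ``"100n"``:
an intensity 0-100 followed by a strategy letter (``n`` neighbours,
``r`` global random parcels, ``h`` global with reduced target cells).
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

__all__ = [
    "Strategy",
    "DistributionSpec",
    "SpeciesDef",
    "HabitatConfig",
    "ConfigError",
    "parse_distribution_code",
    "parse_species_id",
    "join_species_id",
    "load_config",
    "loads_config",
    "validate_config",
]


class ConfigError(ValueError):
    """Raised when a configuration document violates the dialect."""


class Strategy(enum.Enum):
    """Dispersal strategy letters."""

    NEIGHBOURS = "n"
    GLOBAL_AVG = "r"
    GLOBAL_BY_CELL = "h"


_CODE_RE = re.compile(r"^(\d{1,3})([a-zA-Z])$")


@dataclass(frozen=True)
class DistributionSpec:
    """A parsed dispersal code: strategy plus intensity in [0, 100]."""

    strategy: Strategy
    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 100:
            raise ConfigError(
                f"distribution intensity {self.value} outside [0, 100]"
            )

    @property
    def code(self) -> str:
        return f"{self.value}{self.strategy.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_distribution_code(code: str) -> DistributionSpec:
    """Parse a dispersal code such as ``"100n"`` or ``"50r"``.

    Raises :class:`ConfigError` on a malformed string, an intensity
    outside [0, 100], or an unknown strategy letter.
    """
    if not isinstance(code, str):
        raise ConfigError(f"distribution code must be a string, got {code!r}")
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ConfigError(f"malformed distribution code {code!r}")
    value = int(m.group(1))
    letter = m.group(2)
    try:
        strategy = Strategy(letter)
    except ValueError:
        raise ConfigError(
            f"unknown dispersal strategy letter {letter!r} in {code!r} "
            f"(expected one of n, r, h)"
        ) from None
    if not 0 <= value <= 100:
        raise ConfigError(f"distribution intensity {value} outside [0, 100] in {code!r}")
    return DistributionSpec(strategy, value)


def parse_species_id(species_id: str) -> list[str]:
    """Split a (possibly composite) species id on ``"|"``.

    ``"A|B"`` -> ``["A", "B"]``; a simple id yields a one-element list.
    Empty components (as in ``"A||B"``) are configuration errors.
    """
    if not isinstance(species_id, str) or not species_id:
        raise ConfigError(f"species id must be a non-empty string, got {species_id!r}")
    parts = species_id.split("|")
    if any(p == "" for p in parts):
        raise ConfigError(f"species id {species_id!r} contains an empty component")
    return parts


def join_species_id(components: Iterable[str]) -> str:
    """Inverse of :func:`parse_species_id`."""
    parts = list(components)
    if not parts:
        raise ConfigError("cannot join an empty component list")
    return "|".join(parts)


@dataclass
class SpeciesDef:
    """Per-species parameters.

    ``DirectOffspring`` is the number of descendants credited to the
    organism's own species per generation; ``IndirectOffspring`` the
    units transferred to an associate's species. Their sum, the
    inclusive fitness, is a fixed property of the species definition.
    ``PhenotypicFlexibility`` is the proportion of eligible organisms
    that group (and, for a composite species, the proportion of newborn
    groups that stay grouped).
    """

    id: str
    NumberOfItems: int = 0
    DirectOffspring: int = 0
    IndirectOffspring: int = 0
    Distribution: Optional[DistributionSpec] = None
    GroupPartner: list[str] = field(default_factory=list)
    PhenotypicFlexibility: float = 0.0
    AssociatedSpecies: list[str] = field(default_factory=list)
    FitnessVariationLimit: int = 0

    @property
    def inclusive_fitness(self) -> int:
        return self.DirectOffspring + self.IndirectOffspring

    @property
    def components(self) -> list[str]:
        return parse_species_id(self.id)

    @property
    def is_composite(self) -> bool:
        return "|" in self.id

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "id": self.id,
            "NumberOfItems": self.NumberOfItems,
            "DirectOffspring": self.DirectOffspring,
            "IndirectOffspring": self.IndirectOffspring,
            "GroupPartner": list(self.GroupPartner),
            "PhenotypicFlexibility": self.PhenotypicFlexibility,
            "AssociatedSpecies": list(self.AssociatedSpecies),
            "FitnessVariationLimit": self.FitnessVariationLimit,
        }
        if self.Distribution is not None:
            d["Distribution"] = self.Distribution.code
        return d


@dataclass
class HabitatConfig:
    """Habitat parameters, the species table, and run controls."""

    NumberOfCells: int
    NumberOfRsrcsInEachCell: int
    Distribution: DistributionSpec
    species: list[SpeciesDef] = field(default_factory=list)
    generations: int = 100
    replicates: int = 10
    seed: int = 0
    varia: bool = False

    def __post_init__(self) -> None:
        self._index = {s.id: i for i, s in enumerate(self.species)}

    # -- lookups -------------------------------------------------------

    def species_by_id(self, species_id: str) -> SpeciesDef:
        try:
            return self.species[self._index[species_id]]
        except KeyError:
            raise KeyError(f"undeclared species {species_id!r}") from None

    def has_species(self, species_id: str) -> bool:
        return species_id in self._index

    def effective_distribution(self, species_id: str) -> DistributionSpec:
        """Species dispersal code (vagility) if set, else the habitat's
        default (permeability)."""
        sp = self.species_by_id(species_id)
        return sp.Distribution if sp.Distribution is not None else self.Distribution

    @property
    def any_grouping(self) -> bool:
        return any(s.GroupPartner for s in self.species)

    @property
    def any_association(self) -> bool:
        return any(s.AssociatedSpecies for s in self.species)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "habitat": {
                "NumberOfCells": self.NumberOfCells,
                "NumberOfRsrcsInEachCell": self.NumberOfRsrcsInEachCell,
                "Distribution": self.Distribution.code,
            },
            "species": [s.to_dict() for s in self.species],
            "run": {
                "generations": self.generations,
                "replicates": self.replicates,
                "seed": self.seed,
                "varia": self.varia,
            },
        }

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _require(mapping: dict, key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required field {path}.{key}")
    return mapping[key]


def _species_from_dict(d: dict[str, Any], path: str) -> SpeciesDef:
    if not isinstance(d, dict):
        raise ConfigError(f"{path} must be an object")
    sid = _require(d, "id", path)
    parse_species_id(sid)  # syntax check
    dist = d.get("Distribution")
    spec = SpeciesDef(
        id=sid,
        NumberOfItems=int(d.get("NumberOfItems", 0)),
        DirectOffspring=int(d.get("DirectOffspring", 0)),
        IndirectOffspring=int(d.get("IndirectOffspring", 0)),
        Distribution=parse_distribution_code(dist) if dist is not None else None,
        GroupPartner=list(d.get("GroupPartner", [])),
        PhenotypicFlexibility=float(d.get("PhenotypicFlexibility", 0.0)),
        AssociatedSpecies=list(d.get("AssociatedSpecies", [])),
        FitnessVariationLimit=int(d.get("FitnessVariationLimit", 0)),
    )
    return spec


def config_from_dict(doc: dict[str, Any]) -> HabitatConfig:
    """Build a validated :class:`HabitatConfig` from a parsed document."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a JSON object")
    habitat = _require(doc, "habitat", "$")
    species_docs = _require(doc, "species", "$")
    run = doc.get("run", {})
    cfg = HabitatConfig(
        NumberOfCells=int(_require(habitat, "NumberOfCells", "$.habitat")),
        NumberOfRsrcsInEachCell=int(
            _require(habitat, "NumberOfRsrcsInEachCell", "$.habitat")
        ),
        Distribution=parse_distribution_code(
            _require(habitat, "Distribution", "$.habitat")
        ),
        species=[
            _species_from_dict(s, f"$.species[{i}]")
            for i, s in enumerate(species_docs)
        ],
        generations=int(run.get("generations", 100)),
        replicates=int(run.get("replicates", 10)),
        seed=int(run.get("seed", 0)),
        varia=bool(run.get("varia", False)),
    )
    diagnostics = validate_config(cfg)
    if diagnostics:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(diagnostics))
    return cfg


def loads_config(text: str) -> HabitatConfig:
    """Parse and validate a configuration from a JSON string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"not well-formed JSON: {exc}") from exc
    return config_from_dict(doc)


def load_config(path: str) -> HabitatConfig:
    """Parse and validate a configuration from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def validate_config(cfg: HabitatConfig) -> list[str]:
    """Check all configuration invariants.

    Returns a list of human-readable diagnostics; empty iff valid.
    """
    diags: list[str] = []
    if cfg.NumberOfCells < 1:
        diags.append(f"habitat.NumberOfCells must be >= 1, got {cfg.NumberOfCells}")
    if cfg.NumberOfRsrcsInEachCell < 0:
        diags.append(
            "habitat.NumberOfRsrcsInEachCell must be >= 0, got "
            f"{cfg.NumberOfRsrcsInEachCell}"
        )
    if cfg.generations < 0:
        diags.append(f"run.generations must be >= 0, got {cfg.generations}")
    if cfg.replicates < 1:
        diags.append(f"run.replicates must be >= 1, got {cfg.replicates}")

    seen: set[str] = set()
    ids = set()
    for s in cfg.species:
        if s.id in seen:
            diags.append(f"duplicate species id {s.id!r}")
        seen.add(s.id)
        ids.add(s.id)

    for i, s in enumerate(cfg.species):
        path = f"species[{i}] ({s.id!r})"
        try:
            comps = parse_species_id(s.id)
        except ConfigError as exc:
            diags.append(f"{path}: {exc}")
            continue
        if s.NumberOfItems < 0:
            diags.append(f"{path}: NumberOfItems must be >= 0")
        if s.DirectOffspring < 0:
            diags.append(f"{path}: DirectOffspring must be >= 0")
        if s.IndirectOffspring < 0:
            diags.append(f"{path}: IndirectOffspring must be >= 0")
        if s.FitnessVariationLimit < 0:
            diags.append(f"{path}: FitnessVariationLimit must be >= 0")
        if not 0.0 <= s.PhenotypicFlexibility <= 1.0:
            diags.append(
                f"{path}: PhenotypicFlexibility {s.PhenotypicFlexibility} "
                "outside [0, 1]"
            )
        for ref in s.GroupPartner:
            if ref not in ids:
                diags.append(f"{path}: GroupPartner references undeclared species {ref!r}")
            else:
                gid = f"{s.id}|{ref}"
                if gid not in ids:
                    diags.append(
                        f"{path}: group species {gid!r} must be declared "
                        "(every possible group is itself a species)"
                    )
        for ref in s.AssociatedSpecies:
            if ref not in ids:
                diags.append(
                    f"{path}: AssociatedSpecies references undeclared species {ref!r}"
                )
        # composite species must be splittable one level: "X|Y" -> "X", "Y"
        if len(comps) > 1:
            left = join_species_id(comps[:-1])
            right = comps[-1]
            for part in (left, right):
                if part not in ids:
                    diags.append(
                        f"{path}: ungrouping requires species {part!r} to be declared"
                    )
    return diags
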