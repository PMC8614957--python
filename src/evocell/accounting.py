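"""Fitness bookkeeping for association roles.

Every consumed resource unit yields exactly one descendant. An organism's
role decides how many units it demands and where its descendants are
credited:

* a solitary *individual* demands and realizes its direct offspring Df;
* a *recipient* demands only its own Df (what it receives arrives as a
  transfer from its actor, at the actor's expense);
* an *actor* or *reciprocal* partner demands Df + If — the indirect
  offspring it donates are paid for by extra consumption — and its
  descendants split into Df of its own species plus If transferred to
  the partner's species.

Under shortage, direct offspring are filled before transfers (an
organism provisions itself before donating).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Role",
    "InteractionAccount",
    "consumption_demand",
    "realized_offspring",
    "pair_offspring_totals",
]


class Role(enum.Enum):
    """The five association roles an organism can take in a generation."""

    INDIVIDUAL = "individual"
    ACTOR = "actor"
    RECIPIENT = "recipient"
    RECIPROCAL_INTRA = "reciprocal_intra"
    RECIPROCAL_INTER = "reciprocal_inter"


_DONOR_ROLES = frozenset(
    {Role.ACTOR, Role.RECIPROCAL_INTRA, Role.RECIPROCAL_INTER}
)


def is_donor(role: Role) -> bool:
    """True for roles that spend indirect offspring on a partner."""
    return role in _DONOR_ROLES


def consumption_demand(role: Role, direct: int, indirect: int) -> int:
    """Resource units an organism of the given role tries to consume.

    Individuals and recipients demand their direct offspring; actors and
    reciprocal partners additionally pay for the indirect offspring they
    donate.
    """
    if direct < 0 or indirect < 0:
        raise ValueError(f"offspring counts must be >= 0, got {direct}, {indirect}")
    if is_donor(role):
        return direct + indirect
    return direct


def realized_offspring(
    role: Role, consumed: int, direct: int, indirect: int
) -> tuple[int, int]:
    """Turn consumed units into descendants.

    Returns ``(own_species, transfer)``: descendants credited to the
    organism's own species, and units transferred to the associated
    partner's species. Each consumed unit yields exactly one descendant;
    the first ``min(consumed, direct)`` units are credited to the own
    species, the remainder (donor roles only) to the partner.
    """
    demand = consumption_demand(role, direct, indirect)
    if consumed < 0 or consumed > demand:
        raise ValueError(
            f"consumed {consumed} outside [0, demand={demand}] for role {role}"
        )
    own = min(consumed, direct)
    transfer = consumed - own
    return own, transfer


@dataclass
class InteractionAccount:
    """Ledger for one organism's generation: role, units, descendants."""

    role: Role
    direct: int
    indirect: int
    consumed: int = 0
    received: int = 0  # transfers arriving from this organism's actor

    @property
    def demand(self) -> int:
        return consumption_demand(self.role, self.direct, self.indirect)

    @property
    def own_offspring(self) -> int:
        return realized_offspring(self.role, self.consumed, self.direct, self.indirect)[0]

    @property
    def transferred(self) -> int:
        return realized_offspring(self.role, self.consumed, self.direct, self.indirect)[1]

    @property
    def personal(self) -> int:
        """Personal offspring: descendants of this organism's species
        attributable to it (own direct plus received transfers)."""
        return self.own_offspring + self.received

    @property
    def inclusive(self) -> int:
        """Inclusive offspring: descendants this organism caused (own
        direct plus what it donated)."""
        return self.own_offspring + self.transferred


def pair_offspring_totals(
    a_species: str,
    a_direct: int,
    a_indirect: int,
    b_species: str,
    b_direct: int,
    b_indirect: int,
) -> dict[str, int]:
    """Per-species descendants of one fully fed reciprocal pair.

    Species of ``a`` receives ``a_direct + b_indirect`` descendants and
    vice versa — transfers become descendants of the recipient's
    species. For an intra-specific pair the two contributions add up on
    the single species.
    """
    totals: dict[str, int] = {}
    totals[a_species] = totals.get(a_species, 0) + a_direct + b_indirect
    totals[b_species] = totals.get(b_species, 0) + b_direct + a_indirect
    return totals
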