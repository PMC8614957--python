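import pytest
from hypothesis import given
from hypothesis import strategies as st

from evocell.accounting import (
    InteractionAccount,
    Role,
    consumption_demand,
    is_donor,
    pair_offspring_totals,
    realized_offspring,
)

DONORS = [Role.ACTOR, Role.RECIPROCAL_INTRA, Role.RECIPROCAL_INTER]
NON_DONORS = [Role.INDIVIDUAL, Role.RECIPIENT]


class TestDemand:
    @pytest.mark.parametrize("role", NON_DONORS)
    def test_non_donor_demand_is_direct(self, role):
        assert consumption_demand(role, 3, 2) == 3

    @pytest.mark.parametrize("role", DONORS)
    def test_donor_demand_includes_indirect(self, role):
        assert consumption_demand(role, 3, 2) == 5
        assert is_donor(role)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            consumption_demand(Role.INDIVIDUAL, -1, 0)


class TestRealizedOffspring:
    def test_full_fed_actor(self):
        assert realized_offspring(Role.ACTOR, 5, 3, 2) == (3, 2)

    def test_direct_first_under_shortage(self):
        # a partially fed donor keeps its own brood before transferring
        assert realized_offspring(Role.ACTOR, 3, 3, 2) == (3, 0)
        assert realized_offspring(Role.ACTOR, 4, 3, 2) == (3, 1)
        assert realized_offspring(Role.ACTOR, 2, 3, 2) == (2, 0)

    def test_individual_never_transfers(self):
        assert realized_offspring(Role.INDIVIDUAL, 2, 3, 4) == (2, 0)

    def test_consumed_bounds(self):
        with pytest.raises(ValueError):
            realized_offspring(Role.INDIVIDUAL, 4, 3, 0)
        with pytest.raises(ValueError):
            realized_offspring(Role.ACTOR, -1, 3, 2)

    @given(
        st.sampled_from(list(Role)),
        st.integers(0, 10),
        st.integers(0, 10),
        st.data(),
    )
    def test_unit_conservation(self, role, direct, indirect, data):
        demand = consumption_demand(role, direct, indirect)
        consumed = data.draw(st.integers(0, demand))
        own, transfer = realized_offspring(role, consumed, direct, indirect)
        assert own + transfer == consumed
        assert own <= direct
        if not is_donor(role):
            assert transfer == 0


class TestInteractionAccount:
    def test_personal_vs_inclusive(self):
        acc = InteractionAccount(Role.ACTOR, direct=3, indirect=2,
                                 consumed=5, received=1)
        assert acc.demand == 5
        assert acc.own_offspring == 3
        assert acc.transferred == 2
        assert acc.personal == 4  # own + what its partner sent over
        assert acc.inclusive == 5  # own + what it donated


class TestPairTotals:
    def test_transfers_go_to_recipient_species(self):
        totals = pair_offspring_totals("Host", 3, 2, "Cuckoo", 1, 0)
        assert totals == {"Host": 3, "Cuckoo": 3}

    def test_intra_pair_adds_up(self):
        totals = pair_offspring_totals("Bee", 2, 4, "Bee", 2, 4)
        assert totals == {"Bee": 12}
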