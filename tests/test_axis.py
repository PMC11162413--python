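"""Signal-axis model: additivity, activation partitions, realizability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macchiato.axis import (
    ACTIVATION_KINDS,
    ActivationFunction,
    ReceiverAxisSpec,
    admissible_orders,
    apply_activation,
    enumerate_realizable,
    induced_truth_table,
    is_realizable_single,
    min_blocks,
    random_witness_codes,
    realizable_codes,
    state_concentration,
)
from macchiato.logic import DC, TruthTable, tt_from_hex


class TestStateConcentration:
    @pytest.mark.parametrize(
        "c,bits,expected",
        [((1, 2), (1, 1), 3), ((1, 2), (0, 0), 0), ((1, 2, 4), (1, 0, 1), 5)],
    )
    def test_subset_sums(self, c, bits, expected):
        assert state_concentration(c, bits) == expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            state_concentration((1, 2), (1, 0, 1))

    @given(
        c=st.lists(st.floats(0, 10), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=50)
    def test_subset_monotonicity(self, c, data):
        n = len(c)
        s = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        t = [max(a, b) for a, b in zip(s, data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))]
        assert state_concentration(c, s) <= state_concentration(c, t) + 1e-12


class TestActivation:
    def test_highpass_and_bandpass(self):
        hp = ActivationFunction("highpass", 1.0)
        assert hp(2.0) == 1 and hp(0.5) == 0
        bp = ActivationFunction("bandpass", 1.0, 3.0)
        assert bp(2.0) == 1 and bp(4.0) == 0

    def test_zero_concentration_polarity(self):
        # inverting receivers are ON with no signal: the NOR-from-lowpass rule
        assert apply_activation(ActivationFunction("lowpass", 1.0), 0.0) == 1
        assert apply_activation(ActivationFunction("bandstop", 1.0, 2.0), 0.0) == 1
        assert apply_activation(ActivationFunction("highpass", 1.0), 0.0) == 0
        assert apply_activation(ActivationFunction("bandpass", 1.0, 2.0), 0.0) == 0

    def test_bandstop_complements_bandpass(self):
        bp = ActivationFunction("bandpass", 1.0, 3.0)
        bs = ActivationFunction("bandstop", 1.0, 3.0)
        for v in (0.0, 0.5, 2.0, 3.5, 10.0):
            assert bp(v) + bs(v) == 1

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ActivationFunction("highpass", 0.0)
        with pytest.raises(ValueError):
            ActivationFunction("bandpass", 2.0, 1.0)


class TestInducedTable:
    def test_symmetric_bandpass_is_xor(self):
        spec = ReceiverAxisSpec(ActivationFunction("bandpass", 0.5, 1.5), (1.0, 1.0))
        assert induced_truth_table(spec).to_hex() == 0x6

    def test_symmetric_highpass_is_and(self):
        spec = ReceiverAxisSpec(ActivationFunction("highpass", 1.5), (1.0, 1.0))
        assert induced_truth_table(spec).to_hex() == 0x1

    def test_asymmetric_bandpass_is_nimply(self):
        spec = ReceiverAxisSpec(ActivationFunction("bandpass", 0.5, 1.5), (1.0, 2.0))
        # only state 10 lands inside the band: A AND NOT B
        assert set(induced_truth_table(spec).on_states()) == {0b10}

    def test_margin_violation_names_state(self):
        spec = ReceiverAxisSpec(
            ActivationFunction("highpass", 1.0), (1.0, 2.0), margin=0.1
        )
        with pytest.raises(ValueError, match="10"):
            induced_truth_table(spec)

    def test_scale_invariance_of_witnesses(self):
        for code, spec in enumerate_realizable(2).items():
            for lam in (0.1, 7.3):
                assert induced_truth_table(spec.scaled(lam)).to_hex() == code


class TestAdmissibleOrders:
    def test_counts(self):
        assert len(admissible_orders(1)) == 1
        assert len(admissible_orders(2)) == 2
        assert len(admissible_orders(3)) == 12

    def test_orders_start_at_zero_state_and_end_at_full(self):
        for ao in admissible_orders(3):
            assert ao.order[0] == 0
            assert ao.order[-1] == 0b111
            sums = np.array(ao.sums)
            assert (np.diff(sums) > 0).all()


class TestRealizability:
    def test_xor_needs_bandpass(self):
        xor = tt_from_hex(0x6, 2)
        assert is_realizable_single(xor, {"bandpass"}).realizable
        assert not is_realizable_single(xor, {"highpass", "lowpass"}).realizable

    def test_mux_not_single_receiver(self):
        mux = tt_from_hex(0x1B, 3)
        assert not is_realizable_single(mux, {"highpass", "bandpass"}).realizable
        assert not is_realizable_single(mux, ACTIVATION_KINDS).realizable

    def test_b_and_c_highpass_witness(self):
        # derived check: c=(0.1, 1, 1) with theta=1.9 induces B AND C
        spec = ReceiverAxisSpec(ActivationFunction("highpass", 1.9), (0.1, 1.0, 1.0))
        assert induced_truth_table(spec).to_hex() == 0x11
        res = is_realizable_single(tt_from_hex(0x11, 3), {"highpass"})
        assert res.realizable
        assert induced_truth_table(res.witness).to_hex() == 0x11

    def test_witnesses_reencode_to_their_code(self):
        for code, spec in enumerate_realizable(3).items():
            assert induced_truth_table(spec).to_hex() == code

    def test_dc_states_are_free(self):
        # ON at 11, DC elsewhere: any suffix containing 11 works for highpass
        tt = TruthTable(2, (DC, DC, DC, 1))
        res = is_realizable_single(tt, {"highpass"})
        assert res.realizable
        assert induced_truth_table(res.witness).outputs[0b11] == 1


class TestEnumerateRealizable:
    def test_two_input_all_sixteen_with_band_kinds(self):
        assert len(realizable_codes(2, {"bandpass", "bandstop"})) == 16

    def test_three_input_full_set_count(self):
        assert len(realizable_codes(3)) == 152

    def test_one_input_highpass(self):
        assert realizable_codes(1, {"highpass"}) == frozenset({0x0, 0x1})

    def test_monotone_in_kinds(self):
        kinds_sets = [
            {"highpass"},
            {"highpass", "bandpass"},
            {"highpass", "bandpass", "lowpass"},
            set(ACTIVATION_KINDS),
        ]
        prev = frozenset()
        for ks in kinds_sets:
            cur = realizable_codes(3, ks)
            assert prev <= cur
            prev = cur

    def test_zero_state_rule(self):
        # output 1 at the all-absent state is unreachable for activating kinds
        for code in realizable_codes(3, {"highpass", "bandpass"}):
            assert tt_from_hex(code, 3).outputs[0] == 0

    def test_complement_duality_exhaustive_n3(self):
        activating = realizable_codes(3, {"highpass", "bandpass"})
        inverting = realizable_codes(3, {"lowpass", "bandstop"})
        assert inverting == frozenset(0xFF ^ c for c in activating)

    def test_random_witness_oracle_subset_n2(self):
        exact = realizable_codes(2)
        sampled = random_witness_codes(2, n_samples=2000, seed=0)
        assert sampled <= exact
        assert sampled == exact


class TestMinBlocks:
    def test_examples(self):
        assert min_blocks(tt_from_hex(0xFF, 3)) == 1  # constant TRUE
        assert min_blocks(tt_from_hex(0x6, 2)) == 3  # XOR: OFF-ON-OFF
        assert min_blocks(tt_from_hex(0x1B, 3)) >= 4  # the MUX needs 2 colonies

    def test_three_blocks_iff_single_receiver_full_kinds(self):
        # every <=3-block pattern matches one of the four response shapes
        realizable = realizable_codes(3)
        for code in range(256):
            blocks = min_blocks(tt_from_hex(code, 3))
            assert (blocks <= 3) == (code in realizable)

    def test_dc_joins_any_block(self):
        tt = TruthTable(2, (0, DC, DC, 1))
        assert min_blocks(tt) == 2
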