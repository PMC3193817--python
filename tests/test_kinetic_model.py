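"""Scheme structure, rate-set validation, generator and steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2x3kin.kinetic_model import (
    LIGAND_DEPENDENT,
    RATE_NAMES,
    KineticScheme,
    RateSet,
    RateSetError,
    SchemeValidationError,
    Transition,
    build_generator,
    load_rate_set,
    steady_state,
)
from p2x3kin.simulator import PulseProtocol, simulate


class TestScheme:
    def test_canonical_structure(self, scheme):
        assert len(scheme.states) == 10
        assert len(scheme.transitions) == 26
        names = {t.rate for t in scheme.transitions}
        assert names == set(RATE_NAMES)
        # every edge is one half of a reversible pair
        pairs = {(t.source, t.target) for t in scheme.transitions}
        assert all((d, s) in pairs for s, d in pairs)

    def test_ligand_dependence_marks_exactly_the_binding_steps(self, scheme):
        flagged = {t.rate for t in scheme.transitions if t.ligand_order == 1}
        assert flagged == LIGAND_DEPENDENT

    def test_textual_wiring_of_desensitization_exits(self, scheme):
        """d5 leaves the open state for A3Df; n4 returns A3Df toward A3D."""
        by_rate = {t.rate: t for t in scheme.transitions}
        assert (by_rate["d5"].source, by_rate["d5"].target) == ("A3Ro", "A3Df")
        assert (by_rate["n4"].source, by_rate["n4"].target) == ("A3Df", "A3D")
        assert (by_rate["k4"].source, by_rate["k4"].target) == ("A3R", "A3Ro")

    def test_serialization_round_trip(self, scheme, tmp_path):
        path = tmp_path / "scheme.yaml"
        scheme.to_yaml(path)
        again = KineticScheme.from_yaml(path)
        assert again.states == scheme.states
        assert again.transitions == scheme.transitions

    def test_broken_wiring_rejected(self, scheme):
        # drop one direction of a reversible pair
        broken = [t for t in scheme.transitions if t.rate != "r5"]
        broken.append(Transition("A3Ro", "A3Df", "r5", 0))  # duplicates d5 edge
        with pytest.raises(SchemeValidationError):
            KineticScheme(states=scheme.states, transitions=tuple(broken))


class TestRateSets:
    @pytest.mark.parametrize(
        "condition, name, value",
        [
            ("control", "k1", 24000.0),
            ("control", "k4", 75.0),
            ("control", "d5", 9.0),
            ("control", "n4", 0.44),
            ("control", "m4", 0.001),
            ("control", "d1", 1e-5),
            ("MbCD", "k4", 40.0),
            ("MbCD", "d5", 13.0),
            ("MbCD", "n4", 0.68),
            ("MbCD", "n1", 0.019),
            ("MbCD", "n2", 0.038),
            ("MbCD", "n3", 0.057),
            ("MbCD", "k1", 24000.0),
        ],
    )
    def test_packaged_values(self, condition, name, value):
        assert load_rate_set(condition)[name] == pytest.approx(value)

    def test_missing_constant_named_in_error(self, control_rates):
        doc = control_rates.to_dict()
        del doc["rates"]["r5"]
        with pytest.raises(RateSetError, match="r5"):
            load_rate_set(doc)

    def test_negative_value_rejected(self, control_rates):
        with pytest.raises(RateSetError, match="negative"):
            control_rates.replace(k4=-1.0)

    def test_unit_mismatch_rejected(self, control_rates):
        doc = control_rates.to_dict()
        doc["rates"]["k1"]["units"] = "s^-1"  # binding step must be second order
        with pytest.raises(RateSetError, match="k1"):
            load_rate_set(doc)

    def test_unknown_name_rejected(self, control_rates):
        with pytest.raises(RateSetError, match="k9"):
            control_rates.replace(k9=1.0)

    def test_round_trip(self, control_rates, tmp_path):
        path = tmp_path / "rates.yaml"
        control_rates.to_yaml(path)
        again = load_rate_set(path)
        assert again.values == control_rates.values
        assert again.label == control_rates.label


class TestGenerator:
    def test_binding_entry_scales_with_concentration(self, scheme, control_rates):
        q = build_generator(scheme, control_rates, 0.01)
        i_r, i_ar = scheme.index("R"), scheme.index("AR")
        assert q[i_ar, i_r] == pytest.approx(24000 * 0.01)  # k1 * c = 240 /s

    def test_zero_concentration_silences_binding(self, scheme, control_rates):
        q = build_generator(scheme, control_rates, 0.0)
        for t in scheme.transitions:
            if t.ligand_order == 1:
                assert q[scheme.index(t.target), scheme.index(t.source)] == 0.0

    def test_negative_concentration_rejected(self, scheme, control_rates):
        with pytest.raises(ValueError):
            build_generator(scheme, control_rates, -0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        conc=st.floats(0.0, 10.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_columns_sum_to_zero_for_any_rates(self, scheme, conc, scale):
        rates = load_rate_set("control")
        scaled = rates.replace(**{n: rates[n] * scale for n in RATE_NAMES})
        q = build_generator(scheme, scaled, conc)
        assert np.abs(q.sum(axis=0)).max() < 1e-12 * max(np.abs(q).max(), 1.0)


class TestSteadyState:
    def test_zero_agonist_split_between_rest_and_desensitized(
        self, scheme, control_rates
    ):
        """At c=0 only R and D are occupied, split by d1*R = r1*D."""
        ss = steady_state(scheme, control_rates, 0.0)
        d1, r1 = control_rates["d1"], control_rates["r1"]
        assert ss["D"] == pytest.approx(d1 / (d1 + r1), rel=1e-6)
        assert ss["R"] == pytest.approx(r1 / (d1 + r1), rel=1e-6)
        others = [s for s in scheme.states if s not in ("R", "D")]
        assert all(ss[s] < 1e-12 for s in others)

    def test_occupancies_normalized(self, scheme, control_rates):
        for conc in (0.0, 0.001, 0.01, 1.0):
            ss = steady_state(scheme, control_rates, conc)
            assert ss.occupancies.sum() == pytest.approx(1.0, abs=1e-12)
            assert ss.occupancies.min() >= 0.0

    def test_matches_long_time_ode_limit(self, scheme, control_rates):
        """The stationary solve agrees with integrating the ODEs for 10^4 s."""
        ss = steady_state(scheme, control_rates, 0.01)
        protocol = PulseProtocol(
            segments=((1e4, 0.01),), sampling_interval=1e4 / 2
        )
        trace = simulate(control_rates, protocol, scheme=scheme)
        final = trace.states[:, -1]
        assert np.abs(final - ss.occupancies).max() < 1e-8
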