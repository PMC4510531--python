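"""Kinetics engine: closed forms, conservation, superposition, solver oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import lactodose as ld
from lactodose.errors import (
    ConfigurationError,
    RangeError,
    StabilityError,
    ValidationError,
)
from lactodose.model_core import Segment, _propagators

LAM = ld.I131_DECAY_CONSTANT


def _single(decay=LAM):
    return ld.CompartmentModel(["A"], {}, decay_constant=decay)


def test_zero_schedule_gives_identically_zero_trajectory(simple_two_compartment):
    sched = ld.IntakeSchedule({"ingestion": []})
    traj = ld.integrate(simple_two_compartment, sched, {"ingestion": {"A": 1.0}}, 10.0)
    assert np.all(traj.data == 0.0)
    assert ld.total_system_activity(traj, 7.0) == 0.0


def test_acute_intake_pure_decay_matches_exponential():
    traj = ld.integrate(
        _single(), ld.IntakeSchedule({}), {}, 10.0, initial={"A": 1.0}
    )
    for t in (1.0, 5.0, 10.0):
        assert traj.activity("A", t) == pytest.approx(math.exp(-LAM * t), rel=1e-9)


@pytest.mark.parametrize("t", [1.0, 5.0, 10.0])
def test_two_compartment_chain_matches_bateman_closed_form(t, simple_two_compartment):
    # A -> B at rate k with common decay: B(t) = exp(-lam t) (1 - exp(-k t))
    k = 0.5
    traj = ld.integrate(
        simple_two_compartment, ld.IntakeSchedule({}), {}, 10.0, initial={"A": 1.0}
    )
    expected = math.exp(-LAM * t) * (1.0 - math.exp(-k * t))
    assert traj.activity("B", t) == pytest.approx(expected, rel=1e-6)
    # independent matrix-exponential oracle on the same system
    m = simple_two_compartment.matrix()
    oracle = expm(m * t) @ np.array([1.0, 0.0])
    assert traj.activity("B", t) == pytest.approx(oracle[1], rel=1e-6)


def test_decay_corrected_total_is_conserved_for_acute_intake():
    model = ld.CompartmentModel(
        ["A", "B", "C"],
        {("A", "B"): 2.0, ("B", "C"): 0.3, ("B", "A"): 0.1},
        decay_constant=LAM,
        sinks=["C"],
    )
    traj = ld.integrate(
        model, ld.IntakeSchedule.acute("r", 1000.0), {"r": {"A": 1.0}}, 30.0
    )
    for t in (0.5, 1.0, 10.0, 30.0):
        assert traj.total(t) * math.exp(LAM * t) == pytest.approx(1000.0, rel=1e-3)


def test_chronic_mass_balance_without_decay():
    # 100 Bq/d for 10 d with negligible decay: total at day 10 is 1000
    model = ld.CompartmentModel(["A", "B"], {("A", "B"): 1.0}, 1e-12, sinks=["B"])
    sched = ld.IntakeSchedule({"r": [Segment(0.0, 10.0, 100.0)]})
    traj = ld.integrate(model, sched, {"r": {"A": 1.0}}, 10.0)
    assert traj.total(10.0) == pytest.approx(1000.0, rel=1e-3)
    assert traj.administered_to(10.0) == pytest.approx(1000.0, rel=1e-12)


def test_snapped_schedule_preserves_administered_integral():
    # boundaries deliberately off-grid; totals must match to well within 0.01%
    model = _single(1e-12)
    sched = ld.IntakeSchedule({"r": [Segment(0.12345, 0.6789, 37.5), Segment(2.0001, 2.3456, 11.0)]})
    traj = ld.integrate(model, sched, {"r": {"A": 1.0}}, 5.0)
    assert traj.administered_to(5.0) == pytest.approx(sched.total(), rel=1e-9)
    assert traj.activity("A", 5.0) == pytest.approx(sched.total(), rel=1e-4)


def test_superposition_of_schedules():
    model = ld.CompartmentModel(
        ["A", "B", "C"], {("A", "B"): 1.3, ("B", "C"): 0.2}, LAM, sinks=["C"]
    )
    entry = {"r": {"A": 0.7, "B": 0.3}}
    s1 = ld.IntakeSchedule({"r": [Segment(0.0, 2.0, 50.0)]})
    s2 = ld.IntakeSchedule({"r": [Segment(1.0, 4.0, 20.0)]})
    t1 = ld.integrate(model, s1, entry, 6.0)
    t2 = ld.integrate(model, s2, entry, 6.0)
    t12 = ld.integrate(model, s1 + s2, entry, 6.0)
    assert np.allclose(t12.data, t1.data + t2.data, rtol=1e-8, atol=1e-12)


def test_rk4_agrees_with_fine_step_euler_oracle(lactating_model, registry):
    sched = ld.IntakeSchedule.acute("vapour_inhalation", 1.0)
    entry = {"vapour_inhalation": ld.entry_distribution("vapour_inhalation", registry)}
    rk4 = ld.integrate(lactating_model, sched, entry, 30.0)
    euler = ld.integrate(
        lactating_model, sched, entry, 30.0,
        ld.SolverConfig(step=0.0001, output_spacing=0.01, method="euler"),
    )
    for t in (1.0, 5.0, 15.0, 30.0):
        a, b = rk4._row(t), euler._row(t)
        scale = max(a.max(), 1e-12)
        assert np.all(np.abs(a - b) <= 1e-3 * scale + 1e-3 * np.maximum(a, b))


def test_collapsed_rk4_propagator_equals_stagewise_form():
    rng = np.random.default_rng(7)
    m = -np.diag([3.0, 1.0, 0.5]) + rng.uniform(0, 0.4, (3, 3))
    h = 0.01
    p, q = _propagators(m, h, "rk4")
    y = rng.uniform(0, 5, 3)
    b = rng.uniform(0, 2, 3)
    k1 = m @ y + b
    k2 = m @ (y + h / 2 * k1) + b
    k3 = m @ (y + h / 2 * k2) + b
    k4 = m @ (y + h * k3) + b
    stagewise = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    assert np.allclose(p @ y + q @ b, stagewise, rtol=1e-13)


def test_total_system_activity_range_error(simple_two_compartment):
    traj = ld.integrate(
        simple_two_compartment,
        ld.IntakeSchedule.acute("r", 1.0),
        {"r": {"A": 1.0}},
        5.0,
    )
    with pytest.raises(RangeError):
        ld.total_system_activity(traj, 6.0)
    with pytest.raises(RangeError):
        ld.total_system_activity(traj, -1.0)


def test_entry_map_validation_errors(simple_two_compartment):
    sched = ld.IntakeSchedule.acute("r", 1.0)
    with pytest.raises(ConfigurationError):
        ld.integrate(simple_two_compartment, sched, {"r": {"nope": 1.0}}, 5.0)
    with pytest.raises(ConfigurationError):
        ld.integrate(simple_two_compartment, sched, {"r": {"A": 0.7, "B": 0.5}}, 5.0)
    with pytest.raises(ConfigurationError):
        ld.integrate(simple_two_compartment, sched, {}, 5.0)


def test_step_size_stability_error():
    model = ld.CompartmentModel(["A", "B"], {("A", "B"): 2000.0}, LAM, sinks=["B"])
    with pytest.raises(StabilityError, match="stability"):
        ld.integrate(
            model, ld.IntakeSchedule.acute("r", 1.0), {"r": {"A": 1.0}}, 1.0
        )


def test_model_invariant_violations_rejected():
    with pytest.raises(ValidationError):
        ld.CompartmentModel(["A"], {}, decay_constant=0.0)
    with pytest.raises(ValidationError):
        ld.CompartmentModel(["A", "B"], {("A", "B"): -1.0}, LAM)
    with pytest.raises(ValidationError):
        ld.CompartmentModel(["A", "B"], {("B", "A"): 1.0}, LAM, sinks=["B"])
    with pytest.raises(ValidationError):
        ld.CompartmentModel(["A"], {("A", "A"): 1.0}, LAM)


def test_model_yaml_round_trip(tmp_path, simple_two_compartment):
    path = tmp_path / "model.yaml"
    simple_two_compartment.to_yaml(path)
    back = ld.CompartmentModel.from_yaml(path)
    assert back.compartments == simple_two_compartment.compartments
    assert back.transfers == simple_two_compartment.transfers
    assert back.sinks == simple_two_compartment.sinks
    assert back.decay_constant == pytest.approx(simple_two_compartment.decay_constant)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    rates=st.lists(st.floats(0.0, 5.0), min_size=2, max_size=2),
    amount=st.floats(1.0, 1e4),
)
def test_nonnegativity_and_conservation_property(rates, amount):
    """Any admissible two-rate chain conserves decay-corrected activity and
    never produces negative activities."""
    k1, k2 = rates
    model = ld.CompartmentModel(
        ["A", "B", "C"], {("A", "B"): k1, ("B", "C"): k2}, LAM, sinks=["C"]
    )
    traj = ld.integrate(
        model, ld.IntakeSchedule.acute("r", amount), {"r": {"A": 1.0}}, 10.0
    )
    assert traj.data.min() >= 0.0
    assert traj.total(10.0) * math.exp(LAM * 10.0) == pytest.approx(amount, rel=1e-3)
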