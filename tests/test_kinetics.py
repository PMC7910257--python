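"""Kinetic model: gamma input, ODE propagation, sampling, ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from hpdhac import (
    AcquisitionSchedule,
    ConfigurationError,
    InputFunction,
    MetabolicNetwork,
    PulseEvent,
    SimulationError,
    default_network,
    default_schedule,
    gamma_input,
    ratios_at_time,
    simulate_timecourses,
)
from tests.helpers import expm_timecourses


# ---------------------------------------------------------------------------
# gamma input
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t,expected", [(0.0, 1.0), (1.0, math.exp(-1))])
def test_exponential_bolus_closed_form(t, expected):
    p = InputFunction(alpha=1.0, beta=1.0, amplitude=1.0, t0=0.0)
    assert gamma_input(p, t) == pytest.approx(expected, rel=1e-12)


def test_gamma_mode_at_shape_minus_one_times_scale():
    p = InputFunction(alpha=2.0, beta=2.0)
    t = np.linspace(0.0, 20.0, 4001)
    assert t[np.argmax(gamma_input(p, t))] == pytest.approx(2.0, abs=0.01)


def test_gamma_integral_equals_amplitude():
    p = InputFunction(alpha=2.5, beta=1.7, amplitude=3.2)
    val, _ = quad(lambda t: gamma_input(p, t), 0.0, 200.0)
    assert val == pytest.approx(3.2, rel=1e-8)


def test_gamma_zero_before_injection_start():
    p = InputFunction(alpha=2.0, beta=1.0, t0=5.0)
    assert gamma_input(p, 4.999) == 0.0
    assert gamma_input(p, -3.0) == 0.0


@given(alpha=st.floats(0.5, 5.0), beta=st.floats(0.1, 5.0),
       t=st.floats(-10.0, 50.0))
@settings(derandomize=True, max_examples=50)
def test_gamma_input_nonnegative_everywhere(alpha, beta, t):
    p = InputFunction(alpha=alpha, beta=beta, amplitude=1.0)
    assert gamma_input(p, t) >= 0.0


@pytest.mark.parametrize("alpha,beta", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
def test_invalid_gamma_parameters_rejected(alpha, beta):
    with pytest.raises(ConfigurationError):
        InputFunction(alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# ODE propagation
# ---------------------------------------------------------------------------

def test_isolated_pool_t1_decay(quiet_schedule):
    """A single pool with T1 = 40 s decays mono-exponentially."""
    net = MetabolicNetwork(pool_names=["A"], rates={}, t1={"A": 40.0},
                           shift_ppm={"A": 0.0}, substrate="A")
    tc = simulate_timecourses(net, InputFunction(amplitude=0.0),
                              quiet_schedule, m0=np.array([1.0]))
    m20 = np.interp(20.0, tc.time_grid, tc.magnetization[0])
    assert m20 == pytest.approx(math.exp(-0.5), rel=1e-6)


def test_two_pool_transfer_closed_form(two_pool_network, quiet_schedule):
    """A -> B with no relaxation: B(t) = 1 - exp(-k t)."""
    k = two_pool_network.rates["A->B"]
    tc = simulate_timecourses(two_pool_network, InputFunction(amplitude=0.0),
                              quiet_schedule, m0=np.array([1.0, 0.0]))
    for t in (5.0, 15.0, 30.0):
        b = np.interp(t, tc.time_grid, tc.magnetization[1])
        assert b == pytest.approx(1.0 - math.exp(-k * t), abs=1e-8)


def _random_network(rng, n_pools):
    names = [f"P{i}" for i in range(n_pools)]
    rates = {}
    for i in range(n_pools):
        for j in range(n_pools):
            if i != j and rng.random() < 0.5:
                rates[f"P{i}->P{j}"] = float(rng.uniform(0.0, 0.3))
    return MetabolicNetwork(
        pool_names=names, rates=rates,
        t1={p: float(rng.uniform(5.0, 60.0)) for p in names},
        shift_ppm={p: float(i) for i, p in enumerate(names)},
        substrate="P0",
    )


@pytest.mark.parametrize("n_pools,seed", [(3, 0), (5, 1), (6, 2)])
def test_ode_matches_matrix_exponential_oracle(n_pools, seed, quiet_schedule):
    """Driven trajectories agree with exact expm propagation to < 1e-6."""
    rng = np.random.default_rng(seed)
    net = _random_network(rng, n_pools)
    inp = InputFunction(alpha=1.0, beta=1.0, amplitude=1.0)
    tc = simulate_timecourses(net, inp, quiet_schedule)
    times = np.array([1.0, 5.0, 10.0, 20.0, 30.0])
    oracle = expm_timecourses(
        net.system_matrix(), times, np.zeros(n_pools),
        sub_index=0, alpha=1, beta=1.0, amplitude=1.0)
    sim = np.vstack([
        np.interp(times, tc.time_grid, tc.magnetization[i])
        for i in range(n_pools)
    ])
    scale = np.abs(oracle).max()
    assert np.max(np.abs(sim - oracle)) / scale < 1e-6


def test_ode_matches_oracle_with_erlang_input(quiet_schedule):
    """The alpha = 2 gamma bolus also matches the augmented-chain oracle."""
    rng = np.random.default_rng(7)
    net = _random_network(rng, 4)
    inp = InputFunction(alpha=2.0, beta=2.0, amplitude=1.5)
    tc = simulate_timecourses(net, inp, quiet_schedule)
    times = np.array([2.0, 10.0, 25.0])
    oracle = expm_timecourses(net.system_matrix(), times, np.zeros(4),
                              sub_index=0, alpha=2, beta=2.0, amplitude=1.5)
    sim = np.vstack([np.interp(times, tc.time_grid, tc.magnetization[i])
                     for i in range(4)])
    assert np.max(np.abs(sim - oracle)) / np.abs(oracle).max() < 1e-6


def test_mass_balance_closed_network():
    """With T1 = inf and a closed network, total magnetization is conserved
    once the bolus has been delivered."""
    net = MetabolicNetwork(
        pool_names=["A", "B", "C"],
        rates={"A->B": 0.1, "B->A": 0.05, "B->C": 0.2, "C->B": 0.02},
        t1={p: np.inf for p in "ABC"},
        shift_ppm={p: 0.0 for p in "ABC"}, substrate="A",
    )
    sched = AcquisitionSchedule(start_delay=40.0, frames=0, events_per_frame=())
    tc = simulate_timecourses(net, InputFunction(alpha=1.0, beta=0.5), sched)
    late = tc.time_grid > 15.0
    totals = tc.magnetization[:, late].sum(axis=0)
    assert np.ptp(totals) < 1e-7
    assert totals[-1] == pytest.approx(1.0, abs=1e-7)


def test_linearity_in_input_amplitude(quiet_schedule):
    net = default_network()
    tc1 = simulate_timecourses(net, InputFunction(amplitude=1.0), quiet_schedule)
    tc3 = simulate_timecourses(net, InputFunction(amplitude=3.0), quiet_schedule)
    assert np.allclose(3.0 * tc1.magnetization, tc3.magnetization,
                       rtol=1e-6, atol=1e-9)
    r1 = ratios_at_time(tc1, 20.0)
    r3 = ratios_at_time(tc3, 20.0)
    for p in r1:
        assert r1[p] == pytest.approx(r3[p], rel=1e-6, abs=1e-10)


def test_magnetization_never_negative(quiet_schedule):
    tc = simulate_timecourses(default_network(), InputFunction(), quiet_schedule)
    assert tc.magnetization.min() >= -1e-9


# ---------------------------------------------------------------------------
# RF sampling
# ---------------------------------------------------------------------------

def test_sampled_signal_zero_for_unexcited_pools():
    net = default_network()
    sched = default_schedule(frames=3)
    tc = simulate_timecourses(net, InputFunction(), sched)
    excited = {p for ev in sched.events_per_frame for p in ev.excited_pools}
    for i, pool in enumerate(net.pool_names):
        if pool not in excited:
            assert np.all(tc.sampled_signal[i] == 0.0)
        else:
            assert tc.sampled_signal[i].max() > 0.0


def test_ninety_degree_pulse_nulls_pool_each_frame():
    """A 90 deg event consumes all Mz, so the next frame's signal reflects
    only one TR of inflow."""
    net = default_network()
    sched = default_schedule(frames=4)
    tc = simulate_timecourses(net, InputFunction(), sched)
    i = net.index("G3P")
    # pre-event magnetization one grid step after the frame-1 event is
    # far below the pre-event value at frame 1 (pool was nulled)
    t_ev = sched.event_times()[2][0]  # pulse 3 of frame 0
    m_before = np.interp(t_ev, tc.time_grid, tc.magnetization[i])
    m_after = np.interp(t_ev + 0.05, tc.time_grid, tc.magnetization[i])
    assert m_after < 0.05 * m_before


def test_increasing_flip_never_increases_later_signal():
    net = default_network()

    def sampled(flip):
        events = (PulseEvent(1, ("DHAc",), 15.0),
                  PulseEvent(2, ("PEP",), 90.0),
                  PulseEvent(3, ("G3P",), flip))
        sched = AcquisitionSchedule(start_delay=20.0, tr=1.0, frames=5,
                                    events_per_frame=events, n_transients=9)
        tc = simulate_timecourses(net, InputFunction(), sched)
        return tc.sampled_signal[net.index("G3P")]

    lo, hi = sampled(30.0), sampled(80.0)
    # later frames: the larger flip consumed more magnetization
    assert np.all(hi[1:] <= lo[1:] + 1e-12)


def test_transient_averaging_consumes_cos_theta_per_transient():
    """n averages at flip theta leave cos(theta)^n of Mz and sum the
    per-transient sin(theta) signals."""
    net = MetabolicNetwork(pool_names=["A"], rates={}, t1={"A": np.inf},
                           shift_ppm={"A": 0.0}, substrate="A")
    theta, n_tr = 25.0, 4
    ev = (PulseEvent(1, ("A",), theta),)
    sched = AcquisitionSchedule(start_delay=5.0, tr=1.0, frames=1,
                                events_per_frame=ev, n_transients=n_tr)
    tc = simulate_timecourses(net, InputFunction(amplitude=0.0), sched,
                              m0=np.array([1.0]))
    c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
    expected = s * (1 - c**n_tr) / (1 - c)
    assert tc.sampled_signal[0, 0] == pytest.approx(expected, rel=1e-9)
    m_end = tc.magnetization[0, -1]
    assert m_end == pytest.approx(c**n_tr, rel=1e-7)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def test_substrate_ratio_is_one(quiet_schedule):
    tc = simulate_timecourses(default_network(), InputFunction(), quiet_schedule)
    assert ratios_at_time(tc, 20.0)["DHAc"] == 1.0


def test_zero_rates_give_zero_metabolite_ratios(quiet_schedule):
    net = default_network()
    zeroed = net.with_rates({k: 0.0 for k in net.rates})
    tc = simulate_timecourses(zeroed, InputFunction(), quiet_schedule)
    r = ratios_at_time(tc, 20.0)
    for p, v in r.items():
        assert v == (1.0 if p == "DHAc" else pytest.approx(0.0, abs=1e-12))


def test_two_pool_ratio_matches_closed_form(two_pool_network, quiet_schedule):
    """B/A for a single link with equal T1 is exp(k t) - 1."""
    k = two_pool_network.rates["A->B"]
    tc = simulate_timecourses(two_pool_network, InputFunction(amplitude=0.0),
                              quiet_schedule, m0=np.array([1.0, 0.0]))
    r = ratios_at_time(tc, 20.0, substrate="A")
    assert r["B"] == pytest.approx(math.exp(k * 20.0) - 1.0, rel=1e-6)


def test_ratio_errors():
    net = MetabolicNetwork(pool_names=["A"], rates={}, t1={"A": 40.0},
                           shift_ppm={"A": 0.0}, substrate="A")
    sched = AcquisitionSchedule(start_delay=5.0, frames=0, events_per_frame=())
    tc = simulate_timecourses(net, InputFunction(amplitude=0.0), sched,
                              m0=np.array([0.0]))
    with pytest.raises(SimulationError):
        ratios_at_time(tc, 3.0, substrate="A")
    with pytest.raises(ConfigurationError):
        ratios_at_time(tc, 99.0, substrate="A")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_default_network_has_14_pools_and_substrate_shift():
    net = default_network()
    assert net.n_pools == 14
    assert net.shift_ppm["DHAc"] == 212.9
    assert all(t > 0 for t in net.t1.values())


@pytest.mark.parametrize("bad", [
    dict(rates={"A->A": 0.1}),
    dict(rates={"A->C": 0.1}),
    dict(rates={"A->B": -0.1}),
    dict(t1={"A": -1.0, "B": 10.0}),
])
def test_network_validation_rejects_bad_input(bad):
    kwargs = dict(pool_names=["A", "B"], rates={"A->B": 0.1},
                  t1={"A": 10.0, "B": 10.0},
                  shift_ppm={"A": 0.0, "B": 1.0}, substrate="A")
    kwargs.update(bad)
    with pytest.raises(ConfigurationError):
        MetabolicNetwork(**kwargs)


def test_schedule_requires_ordered_pulse_ids():
    with pytest.raises(ConfigurationError):
        AcquisitionSchedule(events_per_frame=(
            PulseEvent(2, ("DHAc",), 15.0), PulseEvent(1, ("PEP",), 90.0)))
    with pytest.raises(ConfigurationError):
        PulseEvent(1, ("DHAc",), 0.0)
    with pytest.raises(ConfigurationError):
        PulseEvent(1, ("DHAc",), 95.0)
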