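"""SPSP pulse design, Bloch simulation and verification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpdhac import (
    ConfigurationError,
    PulseSpec,
    SPSPPulse,
    assemble_spsp_pulse,
    bloch_simulate,
    design_flyback_gradient,
    design_pulse,
    design_spectral_envelope,
    envelope_response,
    reference_pulse_specs,
    verify_spec,
)
from hpdhac.constants import GAMMA_13C_HZ_PER_G
from hpdhac.errors import DesignError
from hpdhac.kinetics import DEFAULT_SHIFTS
from hpdhac.pulses import (
    ExcitationProfile,
    _bloch_core,
    non_target_shifts_outside_passband,
    read_pulse,
    write_pulse,
)
from tests.helpers import measure_fwhm, polyval_envelope, quaternion_bloch


# ---------------------------------------------------------------------------
# gradient design
# ---------------------------------------------------------------------------

def test_slew_limit_respected_everywhere(designed_pulses):
    for pulse in designed_pulses.values():
        g = np.concatenate([[0.0], pulse.gradient, [0.0]])
        worst = np.abs(np.diff(g)).max() / pulse.spec.raster_s
        assert worst <= pulse.spec.max_slew * (1 + 1e-9)


def test_plateau_amplitude_matches_small_tip_relation():
    """G = BW_spatial / (gamma * slab thickness) within 1 percent."""
    for spec in reference_pulse_specs().values():
        grad = design_flyback_gradient(spec)
        expected = spec.spatial_bandwidth_hz / (
            GAMMA_13C_HZ_PER_G * spec.slab_thickness_mm / 10.0)
        assert grad.plateau_amp == pytest.approx(expected, rel=0.01)


def test_flyback_net_area_is_zero_per_period():
    for spec in reference_pulse_specs().values():
        grad = design_flyback_gradient(spec)
        assert abs(grad.samples.sum() * grad.raster_s) < 1e-12


def test_doubling_slew_never_lengthens_flyback():
    spec = reference_pulse_specs()[1]
    base = design_flyback_gradient(spec)
    import dataclasses
    fast = design_flyback_gradient(
        dataclasses.replace(spec, max_slew=2 * spec.max_slew))
    assert fast.samples.size <= base.samples.size


def test_infeasible_period_names_binding_constraint():
    spec = reference_pulse_specs()[1]
    with pytest.raises(DesignError, match="slew"):
        design_flyback_gradient(spec, target_period_s=100e-6)


def test_refocusing_lobe_has_half_trapezoid_area(designed_pulses):
    """The final lobe's area magnitude is ~half the excitation lobe's."""
    for pulse in designed_pulses.values():
        grad = design_flyback_gradient(
            pulse.spec, target_period_s=pulse.subpulse_period_s)
        n_per = grad.samples.size
        n_sub = pulse.taps.size
        # everything after the last trapezoid is the refocus lobe
        tail = pulse.gradient[(n_sub - 1) * n_per +
                              2 * grad.n_ramp + grad.n_plateau:]
        area = tail.sum() * pulse.spec.raster_s
        assert abs(area) == pytest.approx(grad.trapezoid_area / 2.0, rel=0.1)


# ---------------------------------------------------------------------------
# spectral envelope
# ---------------------------------------------------------------------------

def test_envelope_response_matches_polynomial_oracle():
    rng = np.random.default_rng(0)
    taps = rng.normal(size=15)
    period = 520e-6
    freqs = np.linspace(-3000, 3000, 257)
    direct = envelope_response(taps, freqs, period)
    oracle = polyval_envelope(taps, freqs, period)
    assert np.max(np.abs(direct - oracle)) < 1e-10


@given(n=st.integers(5, 25), seed=st.integers(0, 1000))
@settings(derandomize=True, max_examples=25)
def test_envelope_response_periodic(n, seed):
    taps = np.random.default_rng(seed).normal(size=n)
    period = 600e-6
    fs = 1.0 / period
    f = np.linspace(-fs / 2, fs / 2, 64)
    a = np.abs(envelope_response(taps, f, period))
    b = np.abs(envelope_response(taps, f + fs, period))
    assert np.allclose(a, b, atol=1e-9)


def test_designed_envelope_meets_ripple_targets():
    spec = reference_pulse_specs()[1]
    grad = design_flyback_gradient(spec)
    fs = grad.replica_spacing_hz
    taps = design_spectral_envelope(spec, 17, fs)
    f = np.linspace(0, spec.spectral_passband_hz / 2, 200)
    resp = np.abs(envelope_response(taps, f, 1.0 / fs))
    assert resp.min() >= 1 - spec.pass_ripple
    assert resp.max() <= 1 + spec.pass_ripple


def test_allpass_spec_degenerates_to_single_subpulse():
    import dataclasses
    spec = dataclasses.replace(reference_pulse_specs()[1],
                               spectral_passband_hz=5000.0)
    taps = design_spectral_envelope(spec, 9, 1700.0)
    resp = np.abs(envelope_response(taps, np.linspace(-800, 800, 101),
                                    1 / 1700.0))
    assert np.allclose(resp, 1.0, atol=1e-12)


def test_unattainable_ripple_reports_achieved():
    spec = reference_pulse_specs()[3]
    grad = design_flyback_gradient(spec)
    with pytest.raises(DesignError, match="achieved"):
        design_spectral_envelope(spec, 4, grad.replica_spacing_hz)


def test_envelope_requires_four_subpulses():
    with pytest.raises(ConfigurationError):
        design_spectral_envelope(reference_pulse_specs()[1], 3, 1700.0)


# ---------------------------------------------------------------------------
# Bloch simulation
# ---------------------------------------------------------------------------

def _hard_pulse(flip_deg, n=250, raster=4e-6):
    """Constant on-resonance RF with area gamma*B1*tau = flip."""
    b1 = math.radians(flip_deg) / (2 * math.pi * GAMMA_13C_HZ_PER_G * n * raster)
    return np.full(n, b1, dtype=complex), np.zeros(n)


def test_hard_pulse_identity_90_degrees():
    rf, grad = _hard_pulse(90.0)
    mxy, mz = _bloch_core(rf, grad, 4e-6, np.array([0.0]), np.array([0.0]))
    assert abs(mxy[0, 0]) == pytest.approx(1.0, abs=1e-9)
    assert mz[0, 0] == pytest.approx(0.0, abs=1e-9)


def test_rotation_matrix_agrees_with_quaternion_oracle(designed_pulses):
    pulse = designed_pulses[1]
    for f, z in [(0.0, 0.0), (-82.5, 0.12), (700.0, -0.3), (1644.7, 0.05)]:
        mxy, mz = _bloch_core(pulse.rf, pulse.gradient, pulse.spec.raster_s,
                              np.array([f]), np.array([z]))
        qxy, qz = quaternion_bloch(pulse.rf, pulse.gradient,
                                   pulse.spec.raster_s, f, z,
                                   gamma=GAMMA_13C_HZ_PER_G)
        assert abs(mxy[0, 0] - qxy) < 1e-9
        assert abs(mz[0, 0] - qz) < 1e-9


def test_transverse_magnetization_bounded(designed_pulses):
    prof = bloch_simulate(designed_pulses[3],
                          np.linspace(-2000, 2000, 81),
                          np.linspace(-12, 12, 41))
    assert np.abs(prof.mxy).max() <= 1.0 + 1e-9


def test_far_off_resonance_excitation_below_stopband_ripple(designed_pulses):
    """Flip in the inter-replica stop region stays below the ripple target."""
    pulse = designed_pulses[1]
    fs = pulse.replica_spacing_hz
    prof = bloch_simulate(pulse, np.arange(450.0, fs - 450.0, 25.0), [0.0])
    assert prof.flip_deg.max() <= pulse.spec.stop_ripple * pulse.spec.nominal_flip_deg


def test_empty_grids_rejected(designed_pulses):
    with pytest.raises(ConfigurationError):
        bloch_simulate(designed_pulses[1], [], [0.0])


# ---------------------------------------------------------------------------
# assembly and calibration
# ---------------------------------------------------------------------------

def test_calibrated_flip_within_half_degree(designed_pulses):
    for pulse in designed_pulses.values():
        f_cal = pulse.spec.flip_calibration_offset_hz
        prof = bloch_simulate(pulse, [f_cal], [0.0])
        assert prof.flip_deg[0, 0] == pytest.approx(
            pulse.spec.nominal_flip_deg, abs=0.5)


def test_zero_taps_zero_excitation():
    spec = reference_pulse_specs()[1]
    grad = design_flyback_gradient(spec)
    pulse = assemble_spsp_pulse(spec, grad, np.zeros(8))
    assert np.all(pulse.rf == 0.0)
    prof = bloch_simulate(pulse, [0.0, 100.0], [0.0, 2.0])
    assert np.abs(prof.mxy).max() == 0.0


def test_small_tip_scaling_of_transverse_signal():
    """Scaling the RF by s scales |Mxy| like sin(s*theta)/sin(theta)."""
    spec = reference_pulse_specs()[1]
    pulse = design_pulse(spec)
    s = 1.5
    scaled = SPSPPulse(rf=s * pulse.rf, gradient=pulse.gradient,
                       subpulse_period_s=pulse.subpulse_period_s,
                       spec=pulse.spec, taps=pulse.taps)
    f = pulse.spec.flip_calibration_offset_hz
    m1 = abs(bloch_simulate(pulse, [f], [0.0]).mxy[0, 0])
    m2 = abs(bloch_simulate(scaled, [f], [0.0]).mxy[0, 0])
    th = math.radians(spec.nominal_flip_deg)
    assert m2 / m1 == pytest.approx(math.sin(s * th) / math.sin(th), rel=0.01)


def test_replicas_at_multiples_of_inverse_period(designed_pulses):
    """Excitation bands recur at the sub-pulse repetition frequency."""
    pulse = designed_pulses[1]
    fs = pulse.replica_spacing_hz
    for mult in (-1, 1):
        f = np.arange(mult * fs - 200.0, mult * fs + 201.0, 10.0)
        prof = bloch_simulate(pulse, f, [0.0])
        # a band at >= 80 percent of nominal flip surrounds the replica
        assert prof.flip_deg.max() >= 0.8 * pulse.spec.nominal_flip_deg
        band = f[prof.flip_deg[:, 0] >= 0.5 * pulse.spec.nominal_flip_deg]
        center = 0.5 * (band.min() + band.max())
        assert center == pytest.approx(mult * fs, abs=0.05 * fs)


def test_pulse3_second_band_at_configured_shift(designed_pulses):
    """Pulse #3's replica covers the second metabolite band (50 ppm) with
    a near-nominal flip."""
    pulse = designed_pulses[3]
    spec = pulse.spec
    off = (spec.band2_shift_ppm - spec.center_shift_ppm) * spec.hz_per_ppm
    prof = bloch_simulate(pulse, [off], [0.0])
    assert prof.flip_deg[0, 0] >= 0.8 * spec.nominal_flip_deg


def test_refocused_phase_flat_across_slab(designed_pulses):
    """Across the central 80 percent of the slab the Mxy phase varies by
    less than 10 degrees."""
    for pulse in designed_pulses.values():
        prof = bloch_simulate(pulse, [0.0],
                              np.linspace(-3.2, 3.2, 65))
        ph = np.unwrap(np.angle(prof.mxy[0]))
        assert math.degrees(ph.max() - ph.min()) < 10.0


def test_other_windows_resonances_outside_replica_passbands(designed_pulses):
    """With the in-vivo shift table, each pulse's periodic passbands avoid
    the observed resonances belonging to the other two windows (so no
    window's excitation consumes another window's polarization)."""
    observed = {1: {"DHAc"}, 2: {"PEP"},
                3: {"G3P", "Gly", "Ga3P", "3PG", "Lac", "Ala", "G6P", "Glc"}}
    for pid, pulse in designed_pulses.items():
        protected = set().union(*(observed[o] for o in observed if o != pid))
        shifts = {k: v for k, v in DEFAULT_SHIFTS.items() if k in protected}
        res = non_target_shifts_outside_passband(pulse, shifts, targets=set())
        assert all(res.values()), f"pulse {pid}: leaked {res}"


# ---------------------------------------------------------------------------
# verification and reporting
# ---------------------------------------------------------------------------

def test_rectangular_profile_fwhm_measured_exactly():
    """An ideal rectangular flip profile measures its own width."""
    z = np.linspace(-20.0, 20.0, 801)
    flip = np.where(np.abs(z) <= 4.0, 90.0, 0.0)
    assert measure_fwhm(z, flip) == pytest.approx(8.0, abs=0.1)


def test_verify_spec_report_fields(designed_pulses):
    pulse = designed_pulses[2]
    fs = pulse.replica_spacing_hz
    prof_f = bloch_simulate(pulse, np.arange(-0.45 * fs, 0.45 * fs, 5.0), [0.0])
    prof_z = bloch_simulate(pulse, [0.0], np.linspace(-16, 16, 201))
    rep = verify_spec(prof_f, prof_z, pulse)
    assert rep.flip_ok
    assert rep.spatial_ok
    assert rep.duration_ms == pytest.approx(pulse.duration_ms)
    assert rep.passband_width_hz > 0


def test_pulse_durations_close_to_nominal_targets(designed_pulses):
    """Achieved durations are reported and land near (not on) the nominal
    values; pulse 3 runs longer because its wide passband needs more
    sub-pulses at the replica-locked period."""
    assert designed_pulses[1].duration_ms == pytest.approx(10.44, abs=0.6)
    assert designed_pulses[2].duration_ms == pytest.approx(10.18, abs=0.6)
    assert 2.0 < designed_pulses[3].duration_ms < 6.0


def test_waveform_roundtrip(tmp_path, designed_pulses):
    path = tmp_path / "p1.txt"
    write_pulse(designed_pulses[1], path)
    back = read_pulse(path)
    assert np.allclose(back.rf, designed_pulses[1].rf)
    assert np.allclose(back.gradient, designed_pulses[1].gradient)
    assert back.subpulse_period_s == designed_pulses[1].subpulse_period_s
    assert back.spec.center_shift_ppm == 214.0


def test_b1_cap_enforced():
    import dataclasses
    spec = dataclasses.replace(reference_pulse_specs()[3], b1_max=0.05)
    with pytest.raises(DesignError, match="B1"):
        design_pulse(spec)
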