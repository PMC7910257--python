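"""Flyback spectral-spatial (SPSP) RF pulse design and Bloch verification.

A flyback SPSP pulse is a train of identical slab-selective sub-pulses
played on same-sign trapezoidal gradient lobes, with fast rewinder
("flyback") lobes in between.  The sub-pulse spacing T makes the spectral
response periodic with replica spacing 1/T; an FIR tap sequence weighting
the sub-pulses shapes the spectral envelope (passband on the resonances of
interest, stopband elsewhere); the sub-pulse kernel (a windowed sinc whose
half-amplitude bandwidth equals the spec's spatial bandwidth) shapes the
slab profile.  A final negative gradient lobe with half the excitation
lobe's area refocuses spins across the slab.

Design proceeds small-tip with Bloch-simulated verification: the RF is
globally scaled so the simulated on-resonance flip at slab centre matches
the nominal flip angle.  Achieved pulse durations are reported, not
asserted, because they depend on the slew/raster-feasible gradient rather
than on a target duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import firwin

from .constants import (
    GAMMA_13C_HZ_PER_G,
    HZ_PER_PPM,
    MAX_B1_GAUSS,
    MAX_GRAD_G_CM,
    MAX_SLEW_G_CM_S,
    RASTER_S,
)
from .errors import ConfigurationError, DesignError, SimulationError

__all__ = [
    "PulseSpec",
    "GradientPeriod",
    "SPSPPulse",
    "ExcitationProfile",
    "PulseReport",
    "reference_pulse_specs",
    "design_flyback_gradient",
    "design_spectral_envelope",
    "envelope_response",
    "assemble_spsp_pulse",
    "design_pulse",
    "bloch_simulate",
    "verify_spec",
    "write_pulse",
    "read_pulse",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Design targets for one SPSP pulse.

    ``band2_shift_ppm`` requests a second excitation band realized through
    the periodic replica mechanism: the sub-pulse period is stretched so
    that the band separation is an integer number of replica spacings.
    ``flip_reference_ppm`` is the chemical shift at which the nominal flip
    is calibrated (defaults to the passband centre).
    """

    name: str
    center_shift_ppm: float
    spectral_passband_hz: float
    spectral_stopband_hz: float
    spatial_bandwidth_hz: float
    nominal_flip_deg: float
    slab_thickness_mm: float = 8.0
    duration_target_ms: float | None = None
    band2_shift_ppm: float | None = None
    flip_reference_ppm: float | None = None
    max_slew: float = MAX_SLEW_G_CM_S
    raster_s: float = RASTER_S
    max_grad: float = MAX_GRAD_G_CM
    b1_max: float = MAX_B1_GAUSS
    kernel_tbw: float = 2.0
    pass_ripple: float = 0.05
    stop_ripple: float = 0.05
    hz_per_ppm: float = HZ_PER_PPM

    def __post_init__(self) -> None:
        if self.slab_thickness_mm <= 0:
            raise ConfigurationError("slab_thickness_mm must be > 0")
        if self.raster_s <= 0 or self.max_slew <= 0:
            raise ConfigurationError("raster and slew must be > 0")
        if self.spectral_passband_hz <= 0 or self.spatial_bandwidth_hz <= 0:
            raise ConfigurationError("bandwidths must be > 0")
        if not (0 < self.nominal_flip_deg <= 90):
            raise ConfigurationError("nominal flip must be in (0, 90] deg")

    @property
    def flip_calibration_offset_hz(self) -> float:
        """Frequency offset (Hz from passband centre) of the flip reference."""
        if self.flip_reference_ppm is None:
            return 0.0
        return (self.flip_reference_ppm - self.center_shift_ppm) * self.hz_per_ppm


def reference_pulse_specs() -> dict[int, PulseSpec]:
    """The three reference pulse specifications.

    Pulse #1 targets the substrate (DHAc) at 214 ppm with a 250 Hz
    passband and a 15 deg nominal flip calibrated at the DHAc resonance
    (212.9 ppm); pulse #2 targets PEP (150.5 ppm, 250 Hz, 90 deg); pulse
    #3 excites the 72 and 50 ppm metabolite bands (780 Hz passbands,
    90 deg) using the replica mechanism for the second band.
    """
    return {
        1: PulseSpec(
            name="pulse1_dhac", center_shift_ppm=214.0,
            spectral_passband_hz=250.0, spectral_stopband_hz=1908.0,
            spatial_bandwidth_hz=6757.0, nominal_flip_deg=15.0,
            duration_target_ms=10.44, flip_reference_ppm=212.9,
        ),
        2: PulseSpec(
            name="pulse2_pep", center_shift_ppm=150.5,
            spectral_passband_hz=250.0, spectral_stopband_hz=1724.0,
            spatial_bandwidth_hz=7813.0, nominal_flip_deg=90.0,
            duration_target_ms=10.18,
        ),
        3: PulseSpec(
            name="pulse3_metab", center_shift_ppm=72.0, band2_shift_ppm=50.0,
            spectral_passband_hz=780.0, spectral_stopband_hz=1634.0,
            spatial_bandwidth_hz=8929.0, nominal_flip_deg=90.0,
            duration_target_ms=2.98,
        ),
    }


# ---------------------------------------------------------------------------
# Gradient design
# ---------------------------------------------------------------------------

def _min_time_lobe(area: float, slew: float, raster: float, gmax: float,
                   n_samples: int | None = None) -> np.ndarray:
    """Triangular/trapezoidal gradient lobe with exactly the given area.

    Built sample-wise under the slew and amplitude limits, then uniformly
    scaled (scale <= 1 keeps both limits satisfied) to hit the area
    exactly.  If ``n_samples`` is given the lobe is stretched to that
    length; otherwise the shortest feasible lobe is returned.
    """
    sign = 1.0 if area >= 0 else -1.0
    target = abs(area)
    dg = slew * raster

    def shape(n: int) -> np.ndarray:
        k = np.arange(1, n + 1, dtype=float)
        return np.minimum(np.minimum(k, n + 1 - k) * dg, gmax)

    if n_samples is None:
        n = max(int(2.0 * math.sqrt(target / slew) / raster) - 2, 1)
        while shape(n).sum() * raster < target:
            n += 1
    else:
        n = int(n_samples)
        if shape(n).sum() * raster < target - 1e-15:
            raise DesignError(
                f"gradient lobe of {n} samples cannot reach area {target:.3e} "
                f"G*s/cm under slew {slew:.3g} and gmax {gmax:.3g}"
            )
    s = shape(n)
    return sign * s * (target / (s.sum() * raster))


@dataclass
class GradientPeriod:
    """One flyback sub-pulse period: ramp up, plateau, ramp down, flyback."""

    samples: np.ndarray
    n_ramp: int
    n_plateau: int
    plateau_amp: float
    raster_s: float
    trapezoid_area: float

    @property
    def period_s(self) -> float:
        return self.samples.size * self.raster_s

    @property
    def plateau_slice(self) -> slice:
        return slice(self.n_ramp, self.n_ramp + self.n_plateau)

    @property
    def replica_spacing_hz(self) -> float:
        return 1.0 / self.period_s


def design_flyback_gradient(
    spec: PulseSpec, target_period_s: float | None = None
) -> GradientPeriod:
    """Design one sub-pulse gradient period for the given spec.

    The plateau amplitude follows from the small-tip relation
    G = BW_spatial / (gamma * slab thickness); the plateau duration from
    the kernel time-bandwidth product; ramps and the flyback rewinder are
    slew-limited.  A requested period longer than the minimum is absorbed
    by stretching the flyback lobe.
    """
    raster, slew = spec.raster_s, spec.max_slew
    slab_cm = spec.slab_thickness_mm / 10.0
    g_plat = spec.spatial_bandwidth_hz / (GAMMA_13C_HZ_PER_G * slab_cm)
    if g_plat > spec.max_grad:
        raise DesignError(
            f"plateau amplitude {g_plat:.2f} G/cm exceeds gradient cap "
            f"{spec.max_grad} G/cm: slab too thin for the spatial bandwidth"
        )
    n_ramp = max(int(math.ceil(g_plat / (slew * raster))), 1)
    n_plat = int(round(spec.kernel_tbw / spec.spatial_bandwidth_hz / raster))
    if n_plat < 8:
        raise DesignError(
            "sub-pulse plateau shorter than 8 raster samples: spatial "
            "bandwidth too large for the raster time"
        )
    ramp_up = g_plat * np.arange(1, n_ramp + 1) / n_ramp
    ramp_down = g_plat * np.arange(n_ramp - 1, -1, -1) / n_ramp  # ends at 0
    trap = np.concatenate([ramp_up, np.full(n_plat, g_plat), ramp_down])
    area = trap.sum() * raster

    # trailing zero isolates the flyback from the next period's ramp so
    # consecutive-sample steps never exceed one slew increment
    fly_min = np.append(_min_time_lobe(-area, slew, raster, spec.max_grad), 0.0)
    n_core = trap.size
    if target_period_s is not None:
        n_total = int(round(target_period_s / raster))
        n_fly = n_total - n_core
        if n_fly < fly_min.size:
            raise DesignError(
                f"requested sub-pulse period {target_period_s*1e6:.0f} us is "
                f"shorter than the minimum feasible "
                f"{(n_core + fly_min.size) * raster * 1e6:.0f} us "
                "(binding constraint: flyback slew rate)"
            )
        fly = np.append(
            _min_time_lobe(-area, slew, raster, spec.max_grad,
                           n_samples=n_fly - 1),
            0.0,
        )
    else:
        fly = fly_min

    samples = np.concatenate([trap, fly])
    _check_slew(samples, slew, raster)
    return GradientPeriod(
        samples=samples, n_ramp=n_ramp, n_plateau=n_plat,
        plateau_amp=g_plat, raster_s=raster, trapezoid_area=area,
    )


def _check_slew(grad: np.ndarray, slew: float, raster: float) -> None:
    steps = np.abs(np.diff(np.concatenate([[0.0], grad, [0.0]])))
    worst = steps.max() / raster
    if worst > slew * (1 + 1e-9):
        raise DesignError(f"slew limit violated: {worst:.3e} > {slew:.3e} G/cm/s")


# ---------------------------------------------------------------------------
# Spectral envelope (FIR taps)
# ---------------------------------------------------------------------------

def envelope_response(taps: np.ndarray, freqs_hz, period_s: float) -> np.ndarray:
    """Complex spectral envelope H(f) = sum_k h_k exp(-i 2 pi f k T).

    Direct discrete-time Fourier sum; the sub-pulse index k advances in
    units of the sub-pulse period T.
    """
    taps = np.asarray(taps, dtype=float)
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    k = np.arange(taps.size)
    ph = np.exp(-2j * np.pi * np.outer(f, k) * period_s)
    out = ph @ taps
    return out if np.ndim(freqs_hz) else out[0]


def design_spectral_envelope(
    spec: PulseSpec, n_subpulses: int, replica_hz: float
) -> np.ndarray:
    """Weighted least-squares FIR taps for the periodic spectral envelope.

    The response is designed >= (1 - pass_ripple) of nominal across the
    passband and <= stop_ripple across the stopband; an unattainable
    ripple raises a design error reporting what was achieved.  A passband
    covering the whole replica band degenerates to a single sub-pulse
    (spectrally flat response).
    """
    if n_subpulses < 4:
        raise ConfigurationError("n_subpulses must be >= 4")
    fs = replica_hz
    pb = spec.spectral_passband_hz / 2.0
    if pb >= fs / 2.0:
        taps = np.zeros(n_subpulses)
        taps[(n_subpulses - 1) // 2] = 1.0
        return taps

    # transition width set by the tap-sequence frequency resolution
    trans = 2.2 * fs / n_subpulses
    stop = min(pb + trans, 0.48 * fs)
    if stop <= pb:
        raise DesignError(
            f"{spec.name}: passband half-width {pb:.0f} Hz leaves no "
            f"transition room within half the replica spacing {fs/2:.0f} Hz"
        )

    grid = np.linspace(0.0, fs / 2.0, 1024)
    w = np.where(grid <= pb, 1.0, np.where(grid >= stop, 2.0, 0.0))
    d = np.where(grid <= pb, 1.0, 0.0)
    k = np.arange(n_subpulses) - (n_subpulses - 1) / 2.0
    a = np.exp(-2j * np.pi * np.outer(grid, k) / fs)
    ws = np.sqrt(w)[:, None]
    amat = np.vstack([np.real(a) * ws, np.imag(a) * ws])
    rhs = np.concatenate([d * ws[:, 0], np.zeros_like(d)])
    taps, *_ = np.linalg.lstsq(amat, rhs, rcond=None)

    # normalize to unit response at band centre and check ripple
    period = 1.0 / fs
    taps = taps / np.real(envelope_response(taps, 0.0, period))
    resp = np.abs(envelope_response(taps, grid, period))
    pass_err = np.max(np.abs(resp[grid <= pb] - 1.0))
    stop_err = np.max(resp[grid >= stop]) if np.any(grid >= stop) else 0.0
    if pass_err > spec.pass_ripple or stop_err > spec.stop_ripple:
        raise DesignError(
            f"{spec.name}: ripple targets unattainable with {n_subpulses} "
            f"sub-pulses (achieved passband {pass_err:.3f}, stopband "
            f"{stop_err:.3f}; targets {spec.pass_ripple}/{spec.stop_ripple})"
        )
    return taps


# ---------------------------------------------------------------------------
# Sub-pulse kernel
# ---------------------------------------------------------------------------

def _kernel_fwhm_hz(kernel: np.ndarray, raster: float, fmax: float) -> float:
    """Full width at half maximum of |FT(kernel)| via direct evaluation."""
    f = np.linspace(0.0, fmax, 600)
    t = np.arange(kernel.size) * raster
    h = np.abs(np.exp(-2j * np.pi * np.outer(f, t)) @ kernel)
    h = h / h[0]
    below = np.nonzero(h < 0.5)[0]
    if below.size == 0:
        return 2.0 * fmax  # wider than the probed range
    i = below[0]
    # linear interpolation of the half crossing
    f_half = f[i - 1] + (0.5 - h[i - 1]) * (f[i] - f[i - 1]) / (h[i] - h[i - 1])
    return 2.0 * f_half


def design_subpulse_kernel(n_plateau: int, bw_hz: float, raster: float) -> np.ndarray:
    """Hamming-windowed sinc whose response FWHM equals ``bw_hz``.

    The firwin cutoff is calibrated by bisection so that the measured
    half-amplitude full width of the kernel's Fourier response matches the
    requested spatial bandwidth (the raw cutoff is only approximate at
    small time-bandwidth products).
    """
    nyq = 0.5 / raster

    def fwhm_err(cut_hz: float) -> float:
        k = firwin(n_plateau, cut_hz, fs=1.0 / raster, window="hamming")
        return _kernel_fwhm_hz(k, raster, 3.0 * bw_hz) - bw_hz

    lo, hi = 0.02 * bw_hz, min(1.5 * bw_hz, 0.95 * nyq)
    if fwhm_err(lo) > 0:
        raise DesignError(
            "sub-pulse too short to realize the requested spatial bandwidth"
        )
    if fwhm_err(hi) < 0:
        raise DesignError("spatial bandwidth beyond the sub-pulse Nyquist range")
    cut = brentq(fwhm_err, lo, hi, xtol=bw_hz * 1e-5)
    kernel = firwin(n_plateau, cut, fs=1.0 / raster, window="hamming")
    return kernel / kernel.sum()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class SPSPPulse:
    """RF and gradient waveforms on the fixed raster, with design info."""

    rf: np.ndarray  # complex Gauss per raster sample
    gradient: np.ndarray  # Gauss/cm per raster sample
    subpulse_period_s: float
    spec: PulseSpec
    taps: np.ndarray = field(default_factory=lambda: np.array([]))
    kernel: np.ndarray = field(default_factory=lambda: np.array([]))
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.rf.size != self.gradient.size:
            raise ConfigurationError("rf and gradient waveforms differ in length")
        _check_slew(self.gradient, self.spec.max_slew, self.spec.raster_s)

    @property
    def duration_ms(self) -> float:
        return self.rf.size * self.spec.raster_s * 1e3

    @property
    def replica_spacing_hz(self) -> float:
        return 1.0 / self.subpulse_period_s


def _small_point_flip(rf, grad, raster, freq_hz, z_cm) -> float:
    mxy, mz = _bloch_core(rf, grad, raster, np.array([freq_hz]), np.array([z_cm]))
    return math.degrees(math.atan2(abs(mxy[0, 0]), mz[0, 0]))


def assemble_spsp_pulse(
    spec: PulseSpec,
    grad_period: GradientPeriod,
    taps: np.ndarray,
    n_subpulses: int | None = None,
) -> SPSPPulse:
    """Place tap-weighted kernels on the gradient plateaus and calibrate.

    The final flyback is dropped and replaced by a refocusing lobe whose
    area is minus half the excitation trapezoid's, which zeroes the
    residual phase of spins excited at any sub-pulse centre.  The RF is
    globally scaled (Brent root-finding on the Bloch-simulated flip at the
    calibration offset and slab centre) so the achieved flip matches the
    nominal within 0.5 deg.
    """
    taps = np.asarray(taps, dtype=float)
    n_sub = taps.size if n_subpulses is None else int(n_subpulses)
    if n_sub != taps.size:
        raise ConfigurationError("n_subpulses must equal the number of taps")
    per = grad_period.samples
    n_per = per.size
    n_trap = 2 * grad_period.n_ramp + grad_period.n_plateau

    refocus_area = -grad_period.trapezoid_area / 2.0
    kernel = design_subpulse_kernel(
        grad_period.n_plateau, spec.spatial_bandwidth_hz, spec.raster_s
    )
    sl = grad_period.plateau_slice

    def build(area: float) -> tuple[np.ndarray, np.ndarray]:
        refocus = _min_time_lobe(area, spec.max_slew, spec.raster_s,
                                 spec.max_grad)
        grad = np.concatenate(
            [np.tile(per, n_sub)[: (n_sub - 1) * n_per + n_trap], refocus])
        rf_ = np.zeros(grad.size, dtype=complex)
        for k in range(n_sub):
            rf_[k * n_per + sl.start:k * n_per + sl.stop] = taps[k] * kernel
        return rf_, grad

    rf, gradient = build(refocus_area)

    if np.abs(taps).max() == 0.0:
        # degenerate all-zero envelope: zero RF, zero excitation
        return SPSPPulse(
            rf=rf, gradient=gradient, subpulse_period_s=grad_period.period_s,
            spec=spec, taps=taps, kernel=kernel, scale=0.0,
        )

    # global amplitude calibration against the Bloch simulator
    f_cal = spec.flip_calibration_offset_hz
    raster = spec.raster_s
    unit = np.abs(rf).sum() * raster * GAMMA_13C_HZ_PER_G * 360.0  # deg upper bound
    s0 = spec.nominal_flip_deg / max(unit, 1e-12)

    def err(s: float) -> float:
        return _small_point_flip(s * rf, gradient, raster, f_cal, 0.0) - spec.nominal_flip_deg

    lo, hi = 0.1 * s0, 2.0 * s0
    tries = 0
    while err(hi) < 0 and tries < 30:
        hi *= 1.6
        tries += 1
    if err(hi) < 0:
        raise DesignError("flip calibration failed to bracket the nominal flip")
    scale = brentq(err, lo, hi, xtol=s0 * 1e-6)

    # trim the refocus-lobe area against the Bloch-simulated residual
    # phase slope across the slab (the half-area rule is a small-tip
    # result; large flips leave a few degrees of linear phase)
    z_probe = 0.03 * spec.slab_thickness_mm  # cm (0.3 * thickness, in cm)
    for _ in range(3):
        mxy, _mz = _bloch_core(
            scale * rf, gradient, raster,
            np.array([f_cal]), np.array([-z_probe, z_probe]))
        dphi = np.angle(mxy[0, 1] / mxy[0, 0])  # rad across 2*z_probe
        slope = dphi / (2.0 * z_probe)  # rad/cm
        if abs(slope) * (0.4 * spec.slab_thickness_mm / 10.0) < np.deg2rad(1.0):
            break
        refocus_area += slope / (2.0 * np.pi * GAMMA_13C_HZ_PER_G)
        rf, gradient = build(refocus_area)

    rf = rf * scale
    peak = np.abs(rf).max()
    if peak > spec.b1_max:
        raise DesignError(
            f"required peak B1 {peak:.3f} G exceeds hardware cap {spec.b1_max} G"
        )
    return SPSPPulse(
        rf=rf, gradient=gradient, subpulse_period_s=grad_period.period_s,
        spec=spec, taps=taps, kernel=kernel, scale=scale,
    )


def design_pulse(spec: PulseSpec, n_subpulses: int | None = None) -> SPSPPulse:
    """End-to-end design: gradient, taps (growing the sub-pulse count until
    the ripple targets are met), assembly and flip calibration."""
    target_period = None
    if spec.band2_shift_ppm is not None:
        gap_hz = abs(spec.center_shift_ppm - spec.band2_shift_ppm) * spec.hz_per_ppm
        natural = design_flyback_gradient(spec).period_s
        m = max(1, math.ceil(gap_hz * natural - 1e-9))
        target_period = m / gap_hz
    grad = design_flyback_gradient(spec, target_period_s=target_period)

    if n_subpulses is not None:
        candidates = [n_subpulses]
    else:
        base = 4
        if spec.duration_target_ms is not None:
            base = max(4, round(spec.duration_target_ms * 1e-3 / grad.period_s))
        candidates = list(range(base, base + 26, 2))
    last_err: Exception | None = None
    for n in candidates:
        try:
            taps = design_spectral_envelope(spec, n, grad.replica_spacing_hz)
            return assemble_spsp_pulse(spec, grad, taps)
        except DesignError as exc:
            last_err = exc
    raise DesignError(
        f"{spec.name}: no feasible design found ({last_err})"
    )


# ---------------------------------------------------------------------------
# Bloch simulation
# ---------------------------------------------------------------------------

def _bloch_core(
    rf: np.ndarray, grad: np.ndarray, raster: float,
    freqs_hz: np.ndarray, z_cm: np.ndarray,
    gamma: float = GAMMA_13C_HZ_PER_G,
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-pulse (piecewise-constant rotation) propagation from M = +z.

    Returns (mxy, mz) with shape (n_freq, n_z).  Off-resonance enters as
    f + gamma * G(t) * z (Hz); relaxation is neglected over the few-ms
    pulse.  Consecutive RF-free samples are merged into single z-rotations.
    """
    nf, nz = freqs_hz.size, z_cm.size
    fgrid = np.repeat(freqs_hz, nz)
    zgrid = np.tile(z_cm, nf)
    mx = np.zeros(nf * nz)
    my = np.zeros(nf * nz)
    mz = np.ones(nf * nz)

    active = np.abs(rf) > 0.0
    two_pi_dt = 2.0 * np.pi * raster
    i = 0
    n = rf.size
    while i < n:
        if not active[i]:
            j = i
            g_area = 0.0
            while j < n and not active[j]:
                g_area += grad[j]
                j += 1
            phi = -two_pi_dt * (fgrid * (j - i) + gamma * g_area * zgrid)
            c, s = np.cos(phi), np.sin(phi)
            mx, my = mx * c - my * s, mx * s + my * c
            i = j
        else:
            bx = gamma * rf[i].real
            by = gamma * rf[i].imag
            bz = fgrid + gamma * grad[i] * zgrid
            bn = np.sqrt(bx * bx + by * by + bz * bz)
            bn = np.where(bn == 0.0, 1e-30, bn)
            theta = -two_pi_dt * bn
            nx_, ny_ = bx / bn, by / bn
            nz_ = bz / bn
            c, s = np.cos(theta), np.sin(theta)
            ndm = nx_ * mx + ny_ * my + nz_ * mz
            cx = ny_ * mz - nz_ * my
            cy = nz_ * mx - nx_ * mz
            cz = nx_ * my - ny_ * mx
            omc = 1.0 - c
            mx = mx * c + cx * s + nx_ * ndm * omc
            my = my * c + cy * s + ny_ * ndm * omc
            mz = mz * c + cz * s + nz_ * ndm * omc
            i += 1
    mxy = (mx + 1j * my).reshape(nf, nz)
    return mxy, mz.reshape(nf, nz)


@dataclass
class ExcitationProfile:
    """Bloch-simulated transverse magnetization over frequency x position."""

    freq_hz: np.ndarray
    pos_mm: np.ndarray
    mxy: np.ndarray  # complex, (n_freq, n_pos)
    mz: np.ndarray
    nominal_flip_deg: float

    @property
    def flip_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(np.abs(self.mxy), self.mz))


def bloch_simulate(
    pulse: SPSPPulse,
    freqs_hz,
    pos_mm,
) -> ExcitationProfile:
    """Simulate the pulse's excitation profile on a frequency x position grid.

    Frequencies are offsets from the pulse's passband centre (Hz);
    positions are through-slab offsets in mm.  Starting magnetization is
    fully longitudinal.
    """
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    pos = np.atleast_1d(np.asarray(pos_mm, dtype=float))
    if freqs.size == 0 or pos.size == 0:
        raise ConfigurationError("frequency and position grids must be non-empty")
    mxy, mz = _bloch_core(
        pulse.rf, pulse.gradient, pulse.spec.raster_s, freqs, pos / 10.0
    )
    if np.abs(mxy).max() > 1.0 + 1e-9:  # pragma: no cover - unitarity guard
        raise SimulationError("Bloch propagation produced |Mxy| > 1")
    return ExcitationProfile(
        freq_hz=freqs, pos_mm=pos, mxy=mxy, mz=mz,
        nominal_flip_deg=pulse.spec.nominal_flip_deg,
    )


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def _interp_crossings(x: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """x positions where the piecewise-linear y crosses the level."""
    out = []
    s = y - level
    for i in range(len(x) - 1):
        if s[i] == 0.0:
            out.append(float(x[i]))
        elif s[i] * s[i + 1] < 0:
            out.append(float(x[i] + s[i] / (s[i] - s[i + 1]) * (x[i + 1] - x[i])))
    if s[-1] == 0.0:
        out.append(float(x[-1]))
    return out


def _contiguous_band(x: np.ndarray, y: np.ndarray, level: float,
                     center: float) -> tuple[float, float]:
    """The contiguous interval containing ``center`` where y >= level."""
    ic = int(np.argmin(np.abs(x - center)))
    if y[ic] < level:
        return (math.nan, math.nan)
    lo = ic
    while lo > 0 and y[lo - 1] >= level:
        lo -= 1
    hi = ic
    while hi < len(x) - 1 and y[hi + 1] >= level:
        hi += 1
    left = x[lo] if lo == 0 else _interp_crossings(x[lo - 1:lo + 1], y[lo - 1:lo + 1], level)[0]
    right = x[hi] if hi == len(x) - 1 else _interp_crossings(x[hi:hi + 2], y[hi:hi + 2], level)[0]
    return (float(left), float(right))


@dataclass
class PulseReport:
    """Measured pulse characteristics against the design spec."""

    center_flip_deg: float
    flip_at_reference_deg: float
    passband_width_hz: float
    passband_edges_hz: tuple[float, float]
    spatial_fwhm_mm: float
    replica_positions_hz: list[float]
    duration_ms: float
    passband_ok: bool
    flip_ok: bool
    spatial_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.passband_ok and self.flip_ok and self.spatial_ok


def verify_spec(
    profile_spectral: ExcitationProfile,
    profile_spatial: ExcitationProfile,
    pulse: SPSPPulse,
    flip_threshold: float = 0.95,
    spatial_tol: float = 0.05,
) -> PulseReport:
    """Measure passband width, spatial FWHM, replicas and centre flip.

    ``profile_spectral`` must sample z = 0 over frequency;
    ``profile_spatial`` the passband centre frequency over position.
    """
    spec = pulse.spec
    nominal = spec.nominal_flip_deg

    fz = profile_spectral.flip_deg[:, int(np.argmin(np.abs(profile_spectral.pos_mm)))]
    f = profile_spectral.freq_hz
    lo, hi = _contiguous_band(f, fz, flip_threshold * nominal, 0.0)
    width = hi - lo if math.isfinite(lo) else 0.0
    center_flip = float(fz[np.argmin(np.abs(f))])
    flip_ref = float(fz[np.argmin(np.abs(f - spec.flip_calibration_offset_hz))])

    # replica band centres: contiguous segments above half the nominal flip
    above = fz >= 0.5 * nominal
    replicas = []
    i = 0
    while i < f.size:
        if above[i]:
            j = i
            while j + 1 < f.size and above[j + 1]:
                j += 1
            replicas.append(float(0.5 * (f[i] + f[j])))
            i = j + 1
        else:
            i += 1

    zf = profile_spatial.flip_deg[int(np.argmin(np.abs(profile_spatial.freq_hz))), :]
    z = profile_spatial.pos_mm
    half = 0.5 * zf.max()
    crossings = _interp_crossings(z, zf, half)
    fwhm = max(crossings) - min(crossings) if len(crossings) >= 2 else math.nan

    return PulseReport(
        center_flip_deg=center_flip,
        flip_at_reference_deg=flip_ref,
        passband_width_hz=float(width),
        passband_edges_hz=(lo, hi),
        spatial_fwhm_mm=float(fwhm),
        replica_positions_hz=replicas,
        duration_ms=pulse.duration_ms,
        passband_ok=width >= spec.spectral_passband_hz,
        flip_ok=abs(flip_ref - nominal) <= 0.5,
        spatial_ok=abs(fwhm - spec.slab_thickness_mm) <= spatial_tol * spec.slab_thickness_mm,
    )


def non_target_shifts_outside_passband(
    pulse: SPSPPulse, shifts_ppm: dict[str, float], targets: set[str]
) -> dict[str, bool]:
    """Design check: non-target resonances fall outside replica passbands.

    A shift is "outside" when its offset from the nearest replica centre
    exceeds half the spectral passband.
    """
    fs = pulse.replica_spacing_hz
    half_pb = pulse.spec.spectral_passband_hz / 2.0
    out = {}
    for name, ppm in shifts_ppm.items():
        if name in targets:
            continue
        off = (ppm - pulse.spec.center_shift_ppm) * pulse.spec.hz_per_ppm
        dist = abs(off - fs * round(off / fs))
        out[name] = dist > half_pb
    return out


# ---------------------------------------------------------------------------
# Waveform I/O
# ---------------------------------------------------------------------------

def write_pulse(pulse: SPSPPulse, path) -> None:
    """Two-column raster file (RF Gauss, gradient G/cm) + YAML sidecar."""
    import yaml
    from pathlib import Path

    path = Path(path)
    cols = np.column_stack([pulse.rf.real, pulse.rf.imag, pulse.gradient])
    np.savetxt(path, cols, header="rf_real_gauss rf_imag_gauss grad_g_per_cm")
    meta = {
        "schema": "hpdhac-pulse-1",
        "subpulse_period_s": float(pulse.subpulse_period_s),
        "scale": float(pulse.scale),
        "taps": [float(t) for t in pulse.taps],
        "spec": {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool)
                     else v)
                 for k, v in vars(pulse.spec).items()},
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_pulse(path) -> SPSPPulse:
    import yaml
    from pathlib import Path

    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    if meta.get("schema") != "hpdhac-pulse-1":
        raise ConfigurationError(f"unrecognized pulse file schema in {path}")
    cols = np.loadtxt(path)
    spec_kwargs = dict(meta["spec"])
    spec = PulseSpec(**spec_kwargs)
    return SPSPPulse(
        rf=cols[:, 0] + 1j * cols[:, 1],
        gradient=cols[:, 2],
        subpulse_period_s=meta["subpulse_period_s"],
        spec=spec,
        taps=np.asarray(meta["taps"], dtype=float),
        scale=meta["scale"],
    )
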