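"""Hyperpolarized magnetization kinetics for a metabolic pool network.

The model is a linear first-order exchange network driven by a
gamma-variate substrate input:

    dM/dt = A M + u(t) e_sub,
    A = K^T - diag(sum_j k[i->j]) - diag(1/T1),

where ``K[i, j] = k[i->j]`` is the (off-diagonal) rate-constant matrix in
1/s, T1 the per-pool longitudinal relaxation times, and ``u(t)`` a
gamma-variate bolus delivered into the substrate pool.  RF excitation is
modelled as instantaneous sampling events: each event reads out transverse
signal proportional to ``Mz sin(theta)`` and consumes longitudinal
magnetization by ``cos(theta)`` per transient.

The default 14-pool network mirrors hepatic dihydroxyacetone (DHAc)
metabolism -- phosphorylation to DHAP and onward flux into glycerol
synthesis (G3P, glycerol), lower glycolysis (Ga3P, 3PG, PEP, pyruvate,
lactate, alanine) and gluconeogenesis (FBP, G6P, glucose), plus the
DHAc-hydrate exchange.  Its rate constants are documented placeholders:
the published perfused-liver rate set is not reproduced here, so the
network is fully configuration-driven and the shipped numbers exist only
to make every simulation runnable and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, SimulationError

__all__ = [
    "InputFunction",
    "MetabolicNetwork",
    "PulseEvent",
    "AcquisitionSchedule",
    "TimeCourses",
    "gamma_input",
    "simulate_timecourses",
    "ratios_at_time",
    "default_network",
    "default_schedule",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunction:
    """Gamma-variate bolus u(t) = A * gamma_pdf(t - t0; alpha, beta).

    Normalized so that the time integral of the input equals ``amplitude``
    (arbitrary magnetization units).  ``alpha`` is the dimensionless shape,
    ``beta`` the scale in seconds, ``t0`` the injection start.
    """

    alpha: float = 1.0
    beta: float = 1.0
    amplitude: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError(
                f"gamma input requires alpha > 0 and beta > 0, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )
        if self.amplitude < 0:
            raise ConfigurationError("input amplitude must be >= 0")


def gamma_input(params: InputFunction, t):
    """Evaluate the gamma-variate input rate (a.u./s) at time(s) ``t``.

    Returns ``amplitude * (t-t0)^(alpha-1) exp(-(t-t0)/beta) /
    (beta^alpha Gamma(alpha))`` for ``t >= t0`` and 0 before the injection.
    For ``alpha = 1`` this is the exponential bolus used by default.
    """
    t = np.asarray(t, dtype=float)
    tau = t - params.t0
    out = np.zeros_like(tau)
    pos = tau >= 0
    a, b = params.alpha, params.beta
    norm = params.amplitude / (b**a * math.gamma(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        val = norm * np.power(tau[pos], a - 1.0) * np.exp(-tau[pos] / b)
    # alpha < 1 diverges at tau=0; alpha == 1 gives norm exactly.
    val = np.where(np.isfinite(val), val, norm if a == 1.0 else 0.0)
    out[pos] = val
    return out if out.ndim else float(out)


@dataclass
class MetabolicNetwork:
    """Named metabolite pools with first-order exchange and relaxation.

    ``rates`` maps ``"A->B"`` edge names to rate constants in 1/s.  The
    diagonal of the system matrix is derived (negative outflow sums plus
    relaxation), never user-set.
    """

    pool_names: list[str]
    rates: dict[str, float]
    t1: dict[str, float]
    shift_ppm: dict[str, float]
    j_couplings: dict[str, list[float]] = field(default_factory=dict)
    substrate: str = "DHAc"

    def __post_init__(self) -> None:
        if len(set(self.pool_names)) != len(self.pool_names):
            raise ConfigurationError("pool names must be unique")
        if self.substrate not in self.pool_names:
            raise ConfigurationError(
                f"substrate pool {self.substrate!r} not in network"
            )
        for name, k in self.rates.items():
            src, dst = self._parse_edge(name)
            if k < 0:
                raise ConfigurationError(f"rate {name} must be >= 0, got {k}")
            if src == dst:
                raise ConfigurationError(
                    f"self-rate {name} not allowed: diagonal is derived"
                )
        for p in self.pool_names:
            if p not in self.t1:
                raise ConfigurationError(f"missing T1 for pool {p}")
            if self.t1[p] <= 0:
                raise ConfigurationError(f"T1 of {p} must be > 0")
            if p not in self.shift_ppm:
                raise ConfigurationError(f"missing chemical shift for pool {p}")

    def _parse_edge(self, name: str) -> tuple[str, str]:
        try:
            src, dst = name.split("->")
        except ValueError as exc:
            raise ConfigurationError(
                f"rate name {name!r} must have the form 'A->B'"
            ) from exc
        for p in (src, dst):
            if p not in self.pool_names:
                raise ConfigurationError(f"rate {name!r} references unknown pool {p!r}")
        return src, dst

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    def index(self, pool: str) -> int:
        return self.pool_names.index(pool)

    def rate_matrix(self) -> np.ndarray:
        """K[i, j] = k(pool_i -> pool_j), zero diagonal."""
        K = np.zeros((self.n_pools, self.n_pools))
        for name, k in self.rates.items():
            src, dst = self._parse_edge(name)
            K[self.index(src), self.index(dst)] = k
        return K

    def system_matrix(self, include_relaxation: bool = True) -> np.ndarray:
        """A = K^T - diag(outflow) [- diag(1/T1)]."""
        K = self.rate_matrix()
        A = K.T - np.diag(K.sum(axis=1))
        if include_relaxation:
            r = np.array([1.0 / self.t1[p] for p in self.pool_names])
            A = A - np.diag(r)
        return A

    def with_rates(self, rates: dict[str, float]) -> "MetabolicNetwork":
        """Copy of the network with (some) rate constants replaced."""
        new = dict(self.rates)
        new.update(rates)
        return MetabolicNetwork(
            pool_names=list(self.pool_names),
            rates=new,
            t1=dict(self.t1),
            shift_ppm=dict(self.shift_ppm),
            j_couplings={k: list(v) for k, v in self.j_couplings.items()},
            substrate=self.substrate,
        )


@dataclass(frozen=True)
class PulseEvent:
    """One RF excitation applied within a frame."""

    pulse_id: int
    excited_pools: tuple[str, ...]
    flip_angle_deg: float

    def __post_init__(self) -> None:
        if not (0.0 < self.flip_angle_deg <= 90.0):
            raise ConfigurationError(
                f"flip angle must be in (0, 90] deg, got {self.flip_angle_deg}"
            )


@dataclass
class AcquisitionSchedule:
    """Timing of the interleaved dynamic acquisition.

    Acquisition starts ``start_delay`` seconds after the beginning of the
    injection (t = 0); each frame lasts one TR and applies its events in
    order, evenly spaced within the TR.  ``n_transients`` signal averages
    are acquired per event, each consuming cos(theta) of Mz.
    """

    start_delay: float = 20.0
    tr: float = 1.0
    frames: int = 8
    events_per_frame: tuple[PulseEvent, ...] = ()
    n_transients: int = 9

    def __post_init__(self) -> None:
        if self.start_delay < 0:
            raise ConfigurationError("start_delay must be >= 0")
        if self.tr <= 0:
            raise ConfigurationError("tr must be > 0")
        if self.frames < 0:
            raise ConfigurationError("frames must be >= 0")
        if self.n_transients < 1:
            raise ConfigurationError("n_transients must be >= 1")
        self.events_per_frame = tuple(self.events_per_frame)
        ids = [e.pulse_id for e in self.events_per_frame]
        if ids != list(range(1, len(ids) + 1)):
            raise ConfigurationError(
                f"events must apply pulses 1..n exactly once, in order; got ids {ids}"
            )

    def event_times(self) -> list[tuple[float, int, PulseEvent]]:
        """(time, frame index, event) for every excitation, time-ordered."""
        out = []
        n_ev = len(self.events_per_frame)
        for f in range(self.frames):
            for j, ev in enumerate(self.events_per_frame):
                t = self.start_delay + f * self.tr + (j * self.tr / n_ev if n_ev else 0.0)
                out.append((t, f, ev))
        return out

    @property
    def end_time(self) -> float:
        return self.start_delay + self.frames * self.tr


@dataclass
class TimeCourses:
    """Simulated longitudinal magnetization and RF-sampled signal.

    ``magnetization[i, k]`` is pool i at ``time_grid[k]``; values at event
    times are the pre-excitation magnetization.  ``sampled_signal[i, f]``
    is the transverse signal created for pool i in frame f, summed over
    transients (proportional to Mz sin(theta) (1 - cos^n theta)/(1 - cos
    theta)).
    """

    pool_names: list[str]
    time_grid: np.ndarray
    magnetization: np.ndarray
    sampled_signal: np.ndarray
    event_times: np.ndarray

    def pool(self, name: str) -> np.ndarray:
        return self.magnetization[self.pool_names.index(name)]

    def to_frame(self):
        """Columnar table: time plus one column per pool."""
        import pandas as pd

        data = {"time_s": self.time_grid}
        for i, p in enumerate(self.pool_names):
            data[p] = self.magnetization[i]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _transient_factors(flip_deg: float, n_transients: int) -> tuple[float, float]:
    """(summed sin-theta signal factor, total cos-theta Mz survival)."""
    th = math.radians(flip_deg)
    c, s = math.cos(th), math.sin(th)
    if abs(1.0 - c) < 1e-15:
        gain = n_transients * s
    else:
        gain = s * (1.0 - c**n_transients) / (1.0 - c)
    return gain, c**n_transients


def simulate_timecourses(
    net: MetabolicNetwork,
    input_fn: InputFunction,
    sched: AcquisitionSchedule,
    m0: np.ndarray | None = None,
    grid_dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> TimeCourses:
    """Integrate the network ODE with RF sampling at the scheduled events.

    Between events the continuous linear system is solved with an adaptive
    (stiff-capable) integrator; each event is handled by stopping the
    solver, applying the instantaneous transverse sampling and cos(theta)
    losses to the excited pools, and restarting.
    """
    n = net.n_pools
    A = net.system_matrix()
    e_sub = np.zeros(n)
    e_sub[net.index(net.substrate)] = 1.0

    def rhs(t, m):
        return A @ m + gamma_input(input_fn, t) * e_sub

    def jac(t, m):
        return A

    events = sched.event_times()
    t_end = max(sched.end_time, sched.start_delay)
    # time grid: regular points plus every event time (pre-event values)
    grid = np.unique(np.concatenate([
        np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt),
        np.array([t for t, _, _ in events]),
        np.array([t_end]),
    ]))

    m = np.zeros(n) if m0 is None else np.asarray(m0, dtype=float).copy()
    if m.shape != (n,):
        raise ConfigurationError(f"m0 must have shape ({n},)")

    mags = np.empty((n, grid.size))
    mags[:, 0] = m
    filled = 1  # grid[0] == 0.0 holds the initial state
    sampled = np.zeros((n, sched.frames))

    # segment boundaries: start, each event time, end of acquisition
    boundaries = [0.0] + [t for t, _, _ in events] + [t_end]
    seg_events: list[tuple[int, PulseEvent] | None] = [
        (f, ev) for _, f, ev in events
    ] + [None]

    t_cur = 0.0
    for (t_next, ev_info) in zip(boundaries[1:], seg_events):
        if t_next > t_cur:
            t_eval = grid[(grid > t_cur) & (grid <= t_next)]
            # always land exactly on the segment end
            if t_eval.size == 0 or t_eval[-1] < t_next:
                t_eval = np.append(t_eval, t_next)
            sol = solve_ivp(
                rhs, (t_cur, t_next), m, method=method, jac=jac,
                rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
            )
            if not sol.success:
                raise SimulationError(
                    f"ODE solver failed on [{t_cur:.3f}, {t_next:.3f}] s: {sol.message}"
                )
            m = sol.y[:, -1].copy()
            n_grid = int(np.sum((grid > t_cur) & (grid <= t_next)))
            if n_grid:
                mags[:, filled:filled + n_grid] = sol.y[:, :n_grid]
                filled += n_grid
            t_cur = t_next
        if ev_info is not None:
            frame, ev = ev_info
            gain, survive = _transient_factors(ev.flip_angle_deg, sched.n_transients)
            for p in ev.excited_pools:
                i = net.index(p)
                sampled[i, frame] += m[i] * gain
                m[i] *= survive

    if filled != grid.size:  # pragma: no cover - defensive
        raise SimulationError("internal grid bookkeeping error")

    neg = mags.min()
    scale = max(abs(mags).max(), 1.0)
    if neg < -1e-6 * scale:
        raise SimulationError(
            f"negative magnetization {neg:.3e} beyond solver tolerance"
        )
    return TimeCourses(
        pool_names=list(net.pool_names),
        time_grid=grid,
        magnetization=mags,
        sampled_signal=sampled,
        event_times=np.array([t for t, _, _ in events]),
    )


def ratios_at_time(tc: TimeCourses, t: float, substrate: str = "DHAc") -> dict[str, float]:
    """Metabolite-to-substrate magnetization ratios at time ``t``.

    Linear interpolation on the simulation grid; the substrate maps to 1.
    """
    if not (tc.time_grid[0] <= t <= tc.time_grid[-1]):
        raise ConfigurationError(
            f"t={t} s outside simulated range "
            f"[{tc.time_grid[0]}, {tc.time_grid[-1]}] s"
        )
    if substrate not in tc.pool_names:
        raise ConfigurationError(f"unknown substrate pool {substrate!r}")
    values = {
        p: float(np.interp(t, tc.time_grid, tc.magnetization[i]))
        for i, p in enumerate(tc.pool_names)
    }
    m_sub = values[substrate]
    if m_sub <= 0:
        raise SimulationError(
            f"substrate magnetization {m_sub:.3e} <= 0 at t={t} s; ratio undefined"
        )
    return {p: v / m_sub for p, v in values.items()}


# ---------------------------------------------------------------------------
# Default configuration (documented placeholder)
# ---------------------------------------------------------------------------

#: Placeholder first-order rate constants (1/s) for the default network.
#: The topology follows hepatic DHAc metabolism; the values are order-of-
#: magnitude stand-ins chosen so that 20 s metabolite-to-substrate ratios
#: fall in the few-percent range seen in vivo.  They are not fitted.
DEFAULT_RATES: dict[str, float] = {
    "DHAc->DHAP": 0.020,
    "DHAc->DHAc_hyd": 0.010,
    "DHAc_hyd->DHAc": 0.010,
    "DHAP->Ga3P": 0.060,
    "Ga3P->DHAP": 0.500,
    "DHAP->G3P": 0.040,
    "G3P->DHAP": 0.005,
    "G3P->Gly": 0.003,
    "Gly->G3P": 0.002,
    "Ga3P->3PG": 0.200,
    "3PG->PEP": 0.250,
    "PEP->Pyr": 0.030,
    "Pyr->Lac": 0.070,
    "Lac->Pyr": 0.020,
    "Pyr->Ala": 0.150,
    "DHAP->FBP": 0.004,
    "Ga3P->FBP": 0.004,
    "FBP->G6P": 0.060,
    "G6P->Glc": 0.030,
}

#: Placeholder longitudinal relaxation times (s).  Carbonyl/quaternary C2
#: positions (DHAc, DHAP, PEP, pyruvate) relax slowly; protonated C2
#: positions are shorter-lived.
DEFAULT_T1: dict[str, float] = {
    "DHAc": 40.0, "DHAc_hyd": 36.0, "DHAP": 30.0, "G3P": 12.0, "Gly": 12.0,
    "Ga3P": 12.0, "3PG": 12.0, "PEP": 25.0, "Pyr": 30.0, "Lac": 12.0,
    "Ala": 12.0, "FBP": 15.0, "G6P": 15.0, "Glc": 15.0,
}

#: Literature-informed in-vivo C2 chemical shifts (ppm); placeholder values
#: for pools whose shifts are not tabulated.
DEFAULT_SHIFTS: dict[str, float] = {
    "DHAc": 212.9, "DHAc_hyd": 96.3, "DHAP": 212.0, "G3P": 71.9, "Gly": 72.7,
    "Ga3P": 74.0, "3PG": 76.2, "PEP": 150.5, "Pyr": 207.9, "Lac": 69.3,
    "Ala": 51.2, "FBP": 76.5, "G6P": 75.2, "Glc": 74.9,
}

#: One-bond 13C-1H couplings (Hz) for protonated C2 carbons; carbonyl and
#: quaternary carbons carry none.
DEFAULT_J: dict[str, list[float]] = {
    "DHAc": [], "DHAc_hyd": [], "DHAP": [], "G3P": [145.0], "Gly": [145.0],
    "Ga3P": [145.0], "3PG": [145.0], "PEP": [], "Pyr": [], "Lac": [145.0],
    "Ala": [145.0], "FBP": [], "G6P": [145.0], "Glc": [145.0],
}


def default_network() -> MetabolicNetwork:
    """The documented 14-pool placeholder network."""
    pools = list(DEFAULT_T1.keys())
    return MetabolicNetwork(
        pool_names=pools,
        rates=dict(DEFAULT_RATES),
        t1=dict(DEFAULT_T1),
        shift_ppm=dict(DEFAULT_SHIFTS),
        j_couplings={k: list(v) for k, v in DEFAULT_J.items()},
        substrate="DHAc",
    )


#: Pools excited by each of the three spectral windows (window 1: substrate,
#: window 2: PEP, window 3: everything else that is observable).
DEFAULT_WINDOW_POOLS: dict[int, tuple[str, ...]] = {
    1: ("DHAc", "DHAc_hyd", "DHAP", "Pyr"),
    2: ("PEP",),
    3: ("G3P", "Gly", "Ga3P", "3PG", "Lac", "Ala", "G6P", "Glc"),
}


def default_schedule(frames: int = 8) -> AcquisitionSchedule:
    """Three interleaved windows per 1 s frame, 9 transients each."""
    events = (
        PulseEvent(1, DEFAULT_WINDOW_POOLS[1], 15.0),
        PulseEvent(2, DEFAULT_WINDOW_POOLS[2], 90.0),
        PulseEvent(3, DEFAULT_WINDOW_POOLS[3], 90.0),
    )
    return AcquisitionSchedule(
        start_delay=20.0, tr=1.0, frames=frames,
        events_per_frame=events, n_transients=9,
    )
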