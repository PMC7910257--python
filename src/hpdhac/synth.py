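"""Synthetic time-resolved 13C spectra for the three spectral windows.

Each resonance is a damped complex exponential (Lorentzian line); scalar
1H couplings split a line into two components at +-J/2 with half amplitude
unless the acquisition is 1H-decoupled, in which case the doublet
collapses to a singlet of the same integral.  Frames are generated either
from kinetic time courses (the RF-sampled signal of each pool at each
event) or from a static ground-truth ratio map, with complex white
Gaussian noise added per point.

Conventions (recorded in the series metadata): receiver bandwidth 10 kHz,
2048 complex points; forward FFT with the first FID point halved;
frequency axis in ppm, increasing right to left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HZ_PER_PPM
from .errors import ConfigurationError
from .kinetics import TimeCourses

__all__ = [
    "Resonance",
    "WindowSpec",
    "SpectrumSeries",
    "synthesize_fid",
    "generate_series",
    "write_series",
    "read_series",
    "fid_to_spectrum",
    "spectrum_axes",
    "default_windows",
    "roundtrip_resonances",
    "invivo_resonances",
    "TABLE1_RATIOS",
    "HEXOSE_MEMBERS",
]

SCHEMA_VERSION = "hpdhac-series-1"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Resonance:
    """One spectral line: pool, reporting group, shift and lineshape.

    ``metabolite`` names the quantification group the line contributes to
    (e.g. the two G6P resonances and the glucose and 3PG lines all report
    to the hexose group under different ``name``s); ``weight`` is the
    fraction of the group's amplitude carried by this line.
    """

    name: str
    pool: str
    shift_ppm: float
    linewidth_hz: float = 15.0
    j_hz: tuple[float, ...] = ()
    metabolite: str | None = None
    weight: float = 1.0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.linewidth_hz <= 0:
            raise ConfigurationError("linewidth must be > 0")
        if self.weight < 0 or self.amplitude < 0:
            raise ConfigurationError("weight and amplitude must be >= 0")

    @property
    def group(self) -> str:
        return self.metabolite if self.metabolite is not None else self.pool


@dataclass(frozen=True)
class WindowSpec:
    """One spectral acquisition window (axis geometry)."""

    window_id: int
    center_ppm: float
    sweep_hz: float = 10_000.0
    points: int = 2048
    hz_per_ppm: float = HZ_PER_PPM

    def __post_init__(self) -> None:
        if self.sweep_hz <= 0 or self.points < 2:
            raise ConfigurationError("invalid window geometry")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.sweep_hz


@dataclass
class SpectrumSeries:
    """Time-indexed complex FIDs for one spectral window.

    ``fids[f]`` is frame f.  ``ground_truth`` (metabolite-group ->
    substrate-normalized amplitude) is optional; a series read back
    without it is flagged blinded.  ``phase0_deg``/``phase1_deg`` record
    any synthetic phase applied, so processing can undo it from metadata.
    """

    window: WindowSpec
    frame_times: np.ndarray
    fids: np.ndarray  # complex, (n_frames, points)
    decoupled: bool
    noise_sd: float
    seed: int | None
    ground_truth: dict[str, float] | None = None
    phase0_deg: float = 0.0
    phase1_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.fids.ndim != 2 or self.fids.shape[1] != self.window.points:
            raise ConfigurationError("fids must be (n_frames, points)")
        if self.fids.shape[0] != len(self.frame_times):
            raise ConfigurationError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.fids.shape[0]

    @property
    def blinded(self) -> bool:
        return self.ground_truth is None


# ---------------------------------------------------------------------------
# FID / spectrum primitives
# ---------------------------------------------------------------------------

def _split_lines(shift_hz: float, amp: float, j_list, decoupled: bool):
    """Recursively apply doublet splittings (skipped when decoupled)."""
    lines = [(shift_hz, amp)]
    if decoupled:
        return lines
    for j in j_list:
        lines = [
            (f + s * j / 2.0, a / 2.0)
            for (f, a) in lines
            for s in (-1.0, +1.0)
        ]
    return lines


def synthesize_fid(
    resonances: list[Resonance],
    window: WindowSpec,
    decoupled: bool = True,
) -> np.ndarray:
    """Sum of damped complex exponentials for the window's raster.

    Frequencies are offsets from the window centre; amplitude is the time-
    domain value at t=0, so the spectral integral of a line equals its
    amplitude independent of linewidth and of the decoupled flag.
    """
    t = np.arange(window.points) * window.dwell_s
    fid = np.zeros(window.points, dtype=complex)
    for r in resonances:
        if r.amplitude == 0.0:
            continue
        off = (r.shift_ppm - window.center_ppm) * window.hz_per_ppm
        decay = np.exp(-np.pi * r.linewidth_hz * t)
        for f, a in _split_lines(off, r.amplitude, r.j_hz, decoupled):
            fid += a * np.exp(2j * np.pi * f * t) * decay
    return fid


def fid_to_spectrum(fid: np.ndarray) -> np.ndarray:
    """Forward FFT with the first point halved, frequency-shifted.

    Halving the first point of the one-sided FID removes the constant
    baseline offset that plain summation of a half-echo produces.
    """
    w = fid.copy()
    w[..., 0] = 0.5 * w[..., 0]
    return np.fft.fftshift(np.fft.fft(w, axis=-1), axes=-1)


def spectrum_axes(window: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """(freq_hz, ppm) axes matching :func:`fid_to_spectrum` ordering."""
    f = np.fft.fftshift(np.fft.fftfreq(window.points, d=window.dwell_s))
    ppm = window.center_ppm + f / window.hz_per_ppm
    return f, ppm


# ---------------------------------------------------------------------------
# Series generation
# ---------------------------------------------------------------------------

def _resolve_amplitudes(
    resonances: list[Resonance],
    source,
    frame: int,
    pool_index: dict[str, int] | None,
) -> list[Resonance]:
    """Fill per-frame amplitudes from a ratio map or TimeCourses."""
    static = isinstance(source, dict)
    if not static:
        # weights split a group ratio in static mode; in time-course mode
        # they split the pool's own signal across its lines, so renormalize
        pool_tot: dict[str, float] = {}
        for r in resonances:
            pool_tot[r.pool] = pool_tot.get(r.pool, 0.0) + r.weight
    out = []
    for r in resonances:
        if static:
            amp = source.get(r.group, 0.0) * r.weight
        else:
            tc: TimeCourses = source
            if r.pool not in tc.pool_names:
                raise ConfigurationError(f"pool {r.pool!r} absent from time courses")
            base = tc.sampled_signal[tc.pool_names.index(r.pool), frame]
            amp = base * r.weight / pool_tot[r.pool]
        out.append(
            Resonance(
                name=r.name, pool=r.pool, shift_ppm=r.shift_ppm,
                linewidth_hz=r.linewidth_hz, j_hz=r.j_hz,
                metabolite=r.metabolite, weight=r.weight,
                amplitude=float(amp),
            )
        )
    return out


def generate_series(
    source,
    windows: dict[int, WindowSpec],
    assignments: dict[str, int],
    resonances: list[Resonance],
    n_frames: int = 8,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    decoupled: bool = True,
    frame_start_s: float = 20.0,
    frame_dt_s: float = 1.0,
    phase0_deg: float = 0.0,
    phase1_deg: float = 0.0,
) -> dict[int, SpectrumSeries]:
    """Generate one SpectrumSeries per window.

    ``source`` is either a static metabolite-group -> ratio map (frames
    identical up to noise; the substrate group is implicitly 1) or a
    :class:`TimeCourses` whose RF-sampled signals drive frame amplitudes.
    ``assignments`` maps each resonance name to its window id; every
    resonance must be assigned to exactly one window.
    """
    static = isinstance(source, dict)
    if static:
        source = dict(source)
        for r in resonances:
            # the substrate group normalizes to 1 unless explicitly given
            if r.group not in source and r.pool == "DHAc":
                source[r.group] = 1.0
    for r in resonances:
        if r.name not in assignments:
            raise ConfigurationError(
                f"resonance {r.name!r} assigned to no spectral window"
            )
        if assignments[r.name] not in windows:
            raise ConfigurationError(
                f"resonance {r.name!r} assigned to unknown window "
                f"{assignments[r.name]}"
            )
    if not static and isinstance(source, TimeCourses):
        if n_frames > source.sampled_signal.shape[1]:
            raise ConfigurationError("n_frames exceeds simulated frames")

    rng = np.random.default_rng(seed)
    out: dict[int, SpectrumSeries] = {}
    for wid, window in sorted(windows.items()):
        res_w = [r for r in resonances if assignments[r.name] == wid]
        frames = np.empty((n_frames, window.points), dtype=complex)
        times = frame_start_s + frame_dt_s * np.arange(n_frames)
        fhz, _ = spectrum_axes(window)
        for fidx in range(n_frames):
            filled = _resolve_amplitudes(res_w, source, fidx, None)
            fid = synthesize_fid(filled, window, decoupled=decoupled)
            if phase0_deg or phase1_deg:
                # linear-phase ramp across the band, applied in time domain
                spec = fid_to_spectrum(fid)
                ph = np.deg2rad(phase0_deg + phase1_deg * fhz / (window.sweep_hz / 2))
                spec = spec * np.exp(1j * ph)
                w = np.fft.ifft(np.fft.ifftshift(spec))
                w[0] *= 2.0
                fid = w
            if noise_sd > 0:
                fid = fid + noise_sd * (
                    rng.standard_normal(window.points)
                    + 1j * rng.standard_normal(window.points)
                )
            frames[fidx] = fid
        gt = None
        if static:
            gt = {g: float(v) for g, v in source.items()}
        out[wid] = SpectrumSeries(
            window=window, frame_times=times, fids=frames,
            decoupled=decoupled, noise_sd=noise_sd, seed=seed,
            ground_truth=gt, phase0_deg=phase0_deg, phase1_deg=phase1_deg,
        )
    return out


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def write_series(series: dict[int, SpectrumSeries], path) -> None:
    """Lossless container: one HDF5 group per window."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = SCHEMA_VERSION
        for wid, s in series.items():
            g = h5.create_group(f"window_{wid}")
            g.create_dataset("fids", data=s.fids)
            g.create_dataset("frame_times", data=s.frame_times)
            for key in ("center_ppm", "sweep_hz", "points", "hz_per_ppm"):
                g.attrs[key] = getattr(s.window, key)
            g.attrs["window_id"] = s.window.window_id
            g.attrs["decoupled"] = s.decoupled
            g.attrs["noise_sd"] = s.noise_sd
            g.attrs["seed"] = -1 if s.seed is None else s.seed
            g.attrs["phase0_deg"] = s.phase0_deg
            g.attrs["phase1_deg"] = s.phase1_deg
            if s.ground_truth is not None:
                gt = g.create_group("ground_truth")
                for k, v in s.ground_truth.items():
                    gt.attrs[k] = v


def read_series(path) -> dict[int, SpectrumSeries]:
    """Read a series container; absent ground truth flags it blinded."""
    import h5py

    out: dict[int, SpectrumSeries] = {}
    try:
        h5 = h5py.File(path, "r")
    except OSError as exc:
        raise ConfigurationError(f"cannot read series file {path}: {exc}") from exc
    with h5:
        schema = h5.attrs.get("schema")
        if schema != SCHEMA_VERSION:
            raise ConfigurationError(
                f"series schema mismatch: found {schema!r}, expected "
                f"{SCHEMA_VERSION!r}"
            )
        for name, g in h5.items():
            wid = int(g.attrs["window_id"])
            window = WindowSpec(
                window_id=wid,
                center_ppm=float(g.attrs["center_ppm"]),
                sweep_hz=float(g.attrs["sweep_hz"]),
                points=int(g.attrs["points"]),
                hz_per_ppm=float(g.attrs["hz_per_ppm"]),
            )
            gt = None
            if "ground_truth" in g:
                gt = {k: float(v) for k, v in g["ground_truth"].attrs.items()}
            seed = int(g.attrs["seed"])
            out[wid] = SpectrumSeries(
                window=window,
                frame_times=np.asarray(g["frame_times"]),
                fids=np.asarray(g["fids"]),
                decoupled=bool(g.attrs["decoupled"]),
                noise_sd=float(g.attrs["noise_sd"]),
                seed=None if seed == -1 else seed,
                ground_truth=gt,
                phase0_deg=float(g.attrs["phase0_deg"]),
                phase1_deg=float(g.attrs["phase1_deg"]),
            )
    return out


# ---------------------------------------------------------------------------
# Default tables
# ---------------------------------------------------------------------------

#: Published in-vivo metabolite-to-substrate signal ratios (mean over three
#: animals); used as synthetic ground truth for round-trip recovery.
TABLE1_RATIOS: dict[str, float] = {
    "Ala": 0.0038,
    "G3P": 0.0605,
    "Gly": 0.0009,
    "Ga3P": 0.0102,
    "Lac": 0.0018,
    "Hex": 0.0070,
    "PEP": 0.0199,
}

#: Reported spread of the same ratios (standard deviation, n = 3).
TABLE1_SD: dict[str, float] = {
    "Ala": 0.0015,
    "G3P": 0.0200,
    "Gly": 0.0005,
    "Ga3P": 0.0016,
    "Lac": 0.0001,
    "Hex": 0.0035,
    "PEP": 0.0040,
}

#: Resonances pooled into the collective hexose value (unresolved in vivo).
HEXOSE_MEMBERS: tuple[str, ...] = ("Glc-C2", "G6P-C2", "G6P-C5", "3PG-C2")


def default_windows() -> dict[int, WindowSpec]:
    """Window 1 on the substrate, 2 on PEP, 3 on the upfield metabolites."""
    return {
        1: WindowSpec(window_id=1, center_ppm=214.0),
        2: WindowSpec(window_id=2, center_ppm=150.5),
        3: WindowSpec(window_id=3, center_ppm=61.0),
    }


def invivo_resonances(linewidth_hz: float = 15.0) -> list[Resonance]:
    """Literature-informed in-vivo shift table (placeholder values).

    Realistic C2 shifts cluster tightly (e.g. G3P, glycerol and the
    hexoses all within ~5 ppm), which is what makes the in-vivo hexose
    resonances unresolvable.  This table drives pulse-design checks and
    realistic-looking displays, not quantitative round trips.
    """
    def r(name, pool, ppm, j=(), metab=None, w=1.0):
        return Resonance(name=name, pool=pool, shift_ppm=ppm,
                         linewidth_hz=linewidth_hz, j_hz=tuple(j),
                         metabolite=metab, weight=w)

    return [
        r("DHAc-C2", "DHAc", 212.9),
        r("PEP-C2", "PEP", 150.5),
        r("G3P-C2", "G3P", 71.9, j=[145.0]),
        r("Gly-C2", "Gly", 72.7, j=[145.0]),
        r("Ga3P-C2", "Ga3P", 74.0, j=[145.0]),
        r("Lac-C2", "Lac", 69.3, j=[145.0]),
        r("Ala-C2", "Ala", 51.2, j=[145.0]),
        r("Glc-C2", "Glc", 74.9, j=[145.0], metab="Hex", w=0.35),
        r("G6P-C2", "G6P", 75.2, j=[145.0], metab="Hex", w=0.30),
        r("G6P-C5", "G6P", 76.8, j=[145.0], metab="Hex", w=0.20),
        r("3PG-C2", "3PG", 76.2, j=[145.0], metab="Hex", w=0.15),
    ]


def roundtrip_resonances(linewidth_hz: float = 15.0) -> list[Resonance]:
    """Synthetic shift table used for quantitative round-trip recovery.

    Positions are spread (several hundred Hz between integration regions,
    hexose members contiguous) so that integration-based quantification
    is limited by lineshape tails rather than outright peak overlap; the
    table is shared between generator and quantifier, so recovered ratios
    test the processing chain, not the absolute shift values, which are
    synthetic stand-ins.
    """
    def r(name, pool, ppm, j=(), metab=None, w=1.0):
        return Resonance(name=name, pool=pool, shift_ppm=ppm,
                         linewidth_hz=linewidth_hz, j_hz=tuple(j),
                         metabolite=metab, weight=w)

    return [
        r("DHAc-C2", "DHAc", 212.9),
        r("PEP-C2", "PEP", 150.5),
        r("G3P-C2", "G3P", 88.0, j=[145.0]),
        r("Ga3P-C2", "Ga3P", 80.0, j=[145.0]),
        r("3PG-C2", "3PG", 74.0, j=[145.0], metab="Hex", w=0.15),
        r("G6P-C5", "G6P", 73.2, j=[145.0], metab="Hex", w=0.20),
        r("G6P-C2", "G6P", 72.4, j=[145.0], metab="Hex", w=0.30),
        r("Glc-C2", "Glc", 71.6, j=[145.0], metab="Hex", w=0.35),
        r("Gly-C2", "Gly", 58.0, j=[145.0]),
        r("Ala-C2", "Ala", 51.2, j=[145.0]),
        r("Lac-C2", "Lac", 40.0, j=[145.0]),
    ]


def default_assignments(resonances: list[Resonance]) -> dict[str, int]:
    """Substrate -> window 1, PEP -> window 2, everything else -> window 3."""
    out = {}
    for r in resonances:
        if r.pool in ("DHAc", "DHAc_hyd", "DHAP", "Pyr"):
            out[r.name] = 1
        elif r.pool == "PEP":
            out[r.name] = 2
        else:
            out[r.name] = 3
    return out
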