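# Methods

This note documents the models, defaults and numerical choices behind
`hpdhac`, and what the synthetic-data tests do and do not establish.

## Kinetic model

Hyperpolarized magnetization in a network of metabolite pools evolves as

    dM/dt = A·M + u(t)·e_sub,      A = Kᵀ − diag(Σⱼ k[i→j]) − diag(1/T₁),

a linear first-order exchange system: `k[i→j]` (1/s) are unidirectional
rate constants, T₁ (s) the per-pool longitudinal relaxation times, and
`u(t)` a gamma-variate bolus into the substrate pool,

    u(t) = A₀ · (t−t₀)^(α−1) e^(−(t−t₀)/β) / (β^α Γ(α)),

normalized so its time integral is the injected amplitude `A₀`.  The
default input is α = 1, β = 1 s (an exponential bolus starting at t = 0,
the beginning of the injection); α = 2/β = 2 and α = 3/β = 3 are used by
the input-sensitivity sweep.  Because polarization is non-renewable, the
model has no steady state: everything decays with T₁ and is consumed by
RF sampling.

RF sampling is instantaneous: an excitation at flip θ with n transients
reads out a transverse signal proportional to
M_z·sinθ·(1−cosⁿθ)/(1−cosθ) and leaves cosⁿθ of M_z.  With the in-vivo
protocol (TR 1 s, three interleaved windows per frame, 9 transients,
flips 15°/90°/90°) the two 90° windows are nulled every frame, so their
signal reflects one TR of inflow; the substrate window at 15° retains
cos⁹(15°) ≈ 0.73 of its magnetization per frame.

The shipped 14-pool network (DHAc, DHAc-hydrate, DHAP, G3P, glycerol,
Ga3P, 3PG, PEP, pyruvate, lactate, alanine, FBP, G6P, glucose) is a
documented placeholder: the topology follows hepatic DHAc metabolism,
but the rate constants are order-of-magnitude stand-ins chosen once so
that 20 s metabolite-to-substrate ratios land in the few-percent range
observed in vivo (G3P ≈ 0.09, PEP ≈ 0.02, alanine/lactate ≈ 2).  They
are not fitted to any data, and every simulation is fully
configuration-driven so a user with a calibrated rate set can supply it.
T₁ defaults follow the chemistry: slow for carbonyl/quaternary C2
positions (DHAc 40 s, DHAP/pyruvate 30 s, PEP 25 s), faster for
protonated C2 carbons (12–15 s).

Ratios are evaluated at t = 20 s (the acquisition start) from the
continuous solution, before any RF event at that instant.

## Monte-Carlo uncertainty propagation

Each replicate draws the flagged rate constants independently from
normal distributions, rejecting and redrawing negative values (up to 10⁶
redraws; clipping would bias the mean upward differently).  The default
flags the 11 largest-mean rates (ties broken alphabetically) with a
relative SD of 0.30 — a placeholder spread, since no published mean/SD
rate table is reproduced here.  Replicate seeds derive from
`SeedSequence((master, replicate))`, making ensembles reproducible and
order-independent.  The default ensemble is 1000 replicates (a few
seconds of CPU); the convergence test compares 1000 against 4000.

## SPSP pulse design

A flyback pulse is a train of identical slab-selective sub-pulses on
positive trapezoidal gradient lobes with slew-limited rewinders.  Design
order:

1. **Gradient period.**  Plateau amplitude G = BW_spatial/(γ₁₃C·Δz) with
   γ₁₃C = 10.7084 MHz/T and Δz = 8 mm; plateau duration = TBW/BW_spatial
   with kernel time-bandwidth TBW = 2; ramps and flyback at the 2×10⁵
   G/cm/s slew limit on the 4 µs raster (gradient cap 40 G/cm).  The
   sub-pulse period T sets the spectral replica spacing 1/T.
2. **Dual band by replica locking.**  Pulse #3 must excite bands at 72
   and 50 ppm.  Rather than a true dual-band FIR, the flyback lobe is
   stretched so the 22 ppm band separation (1650 Hz at 75 MHz) is exactly
   one replica spacing; the replica then covers the second band.  This is
   why the quoted 1634 Hz "stop-band" of pulse #3 is ≈ the 22 ppm gap.
3. **Spectral envelope.**  Sub-pulse weights come from a weighted
   least-squares FIR fit (passband ≥ 0.95, stopband ≤ 0.05 of nominal;
   both configurable).  The transition width scales with 1/n_subpulses;
   if the ripple targets fail, the design retries with more sub-pulses —
   which is why pulse #3 runs ~4.2 ms rather than the nominal 2.98 ms.
   Durations are therefore reported, never asserted.
4. **Sub-pulse kernel.**  A Hamming-windowed sinc whose firwin cutoff is
   calibrated by bisection so the measured half-amplitude width of its
   Fourier response equals the spec's spatial bandwidth; the slab FWHM
   is then BW/(γG) = 8 mm by construction.  "Spatial bandwidth" is
   interpreted as the sub-pulse RF bandwidth.
5. **Refocusing.**  The final flyback is dropped and replaced by a lobe
   of −½ the excitation-lobe area, which zeroes the linear phase of
   spins excited at any sub-pulse centre (small-tip result); a Bloch-
   measured trim of the lobe area then removes the residual large-tip
   phase slope.  All three pulses hold the Mxy phase within 10° over the
   central 80 % of the slab.
6. **Flip calibration.**  The RF is globally scaled by Brent root-finding
   on the Bloch-simulated flip at the calibration offset and z = 0.
   Pulse #1's nominal 15° is defined at the substrate resonance
   (212.9 ppm, −82.5 Hz from the 214 ppm design centre), matching the
   acquisition protocol.  Peak B1 is capped at 2 G (0.2 mT) by default.

The Bloch simulator is a hard-pulse integrator: one rotation per 4 µs
raster sample about the effective field (γB1x, γB1y, f + γG(t)z), with
relaxation neglected over the ≤ 10.5 ms pulse (T₁, T₂ ≫ duration).
Consecutive RF-free samples merge into single z-rotations.  A quaternion
(spin-domain) propagation serves as an independent cross-check in the
tests (agreement to 1e−9).

At 90° nominal flip the measured slab FWHM narrows to 7.76 mm (−3 %): a
genuine large-tip effect (flip is no longer proportional to the local B1
integral off the profile shoulders), within the 5 % verification
tolerance.

## Synthetic spectra

Each resonance is a damped complex exponential with Lorentzian FWHM
15 Hz by default (in-vivo linewidths are < 20 Hz).  Scalar ¹JCH
couplings (145 Hz for protonated C2 carbons; none for the carbonyl DHAc
C2) split lines into ±J/2 doublets of half amplitude unless the series
is ¹H-decoupled; integrals are conserved either way.  Windows follow the
acquisition block: 10 kHz receiver bandwidth, 2048 complex points,
centres at 214, 150.5 and 61 ppm; frames start 20 s after injection at
TR 1 s.  Complex white Gaussian noise is seeded per series.  The FT
convention (forward FFT, first FID point halved, ppm increasing
right-to-left) is shared with the processing module and recorded in the
container metadata.

Two shift tables ship:

- **`invivo_resonances`** — literature-informed C2 shifts (G3P 71.9,
  glycerol 72.7, hexoses 74.9–76.8 ppm, …).  Realistically *unresolvable*
  by integration: it drives pulse-design checks and displays.
- **`roundtrip_resonances`** — the quantitative round-trip table, with
  the same pools spread several hundred Hz apart (hexose members
  contiguous, pooled into one region).  Both generator and quantifier
  share it, so round-trip recovery tests the processing chain, not the
  shift values, which are synthetic stand-ins.  Placement was set by an
  error budget over Lorentzian tail spill and baseline-node bias (the
  smallest peak, glycerol at ratio 9e−4, sits next to a 67× larger G3P
  peak in reality — no integration-only pipeline resolves that).

The generator emulates amplitudes, lineshapes, coupling, noise and
timing.  It does **not** emulate: B0 inhomogeneity or frequency drift,
chemical-shift displacement of the excitation slab, baseline roll from
hardware filters, imperfect decoupling sidebands, or spatial
compartmentalization.  Passing round-trip tests therefore demonstrate
the correctness of the processing arithmetic under the stated lineshape
model, not robustness to every in-vivo artefact.

Noise in the packaged noisy fixture is 1e−3 per complex point (substrate
amplitude 1 per frame): every metabolite keeps a summed-spectrum peak
SNR well above 5 (weakest ≈ 23), while the mean over 20 replicate seeds
stays resolvable against the tightest reported between-animal spread
(lactate, ±0.0001).

## Processing chain

Per frame: Gaussian apodization exp(−(π·lb·t)²/(4 ln 2)) with lb = 23 Hz
(a zero-width line acquires FWHM = lb; integrals are unchanged); FFT;
phase correction from generator metadata or, in `auto` mode, spectral-
entropy minimization over zero- and first-order terms (coarse φ₀ scan +
Nelder–Mead, estimated once on the frame sum and applied to all frames);
baseline subtraction; then the first six frames are summed and regions
integrated.

The default baseline interpolates (monotone PCHIP) the median level of
each signal-free gap, excluding a 150 Hz guard band around every
integration region so peaks' own tails do not inflate the estimate.  A
single low-order polynomial (the retained `poly` mode) cannot track the
1/Δf² Lorentzian tails that dominate the error budget under the
smallest peaks, which is why the gap-median mode is the default.

Integration regions default to the group's line positions ±150 Hz
(≈ ±4.7 apodized linewidths); identical margins for every region make
the captured fraction of an isolated line cancel in ratios.  The four
hexose lines (Glc-C2, G6P-C2, G6P-C5, 3PG-C2) are deliberately merged
into one region, mirroring their pooled reporting; interior lines of a
merged block capture slightly more of their tails, a ≈ +1.5 % bias on
the pooled value that stays inside the 2 % round-trip budget.

Ratios are raw signal-intensity ratios to the DHAc integral by default —
the published definition, with no flip-angle rescaling across windows.
An optional corrected mode divides each window's integral by its
per-frame signal gain sinθ·(1−cosⁿθ)/(1−cosθ) (n = 9 transients), which
reconciles ratios across windows excited at different flips; the bare
sinθ form would not, because the transient train consumes magnetization
within a frame.  Derived quantities: pooled hexoses, three-carbon-to-
hexose ratio, alanine/lactate.

## Numerical choices

- ODE integration: LSODA, rtol 1e−8, atol 1e−10; RF events by
  stop-and-restart at event times (discontinuities break smoothness).
  Correctness is pinned by a matrix-exponential oracle: gamma inputs
  with integer α are outputs of an Erlang chain, so the driven system
  augments to a homogeneous linear one solved exactly with `expm`
  (agreement < 1e−6 relative on random ≤ 6-pool networks).
- ppm ↔ Hz via a fixed 75.0 MHz ¹³C reference (nominal 7 T);
  configurable.
- All randomness flows through `numpy.random.SeedSequence`; fixed seeds
  give byte-identical pipeline outputs.
- Degenerate inputs: all-zero FIR taps produce a valid zero-RF pulse;
  an all-pass spectral spec degenerates to a single sub-pulse; zero or
  negative substrate integrals raise instead of returning ratios.

## Problem sizes

Defaults are sized for interactive use on one CPU: 1000 Monte-Carlo
replicates (~6 s), 20 replicate seeds for noisy round trips (< 1 s),
Bloch verification grids of 200 × 200 (frequency × position, ~10 s per
pulse) with 1 Hz spectral scans where band edges are measured.

## Known limitations

- Rate constants, their sampling SDs and several chemical shifts are
  placeholders; absolute simulated ratios are illustrative, not
  predictive.  No fitting of rates to dynamic data is provided (the
  in-vivo SNR that motivated this pipeline does not support it).
- Pulse design is small-tip with Bloch verification, not SLR; at 90°
  the passband measured at the 95 %-flip criterion is narrower than the
  design passband (flip compression), and achieved durations differ
  from the nominal ones.
- The quantifier integrates fixed regions; it does not fit lineshapes,
  so congested spectra (the realistic shift table) cannot be resolved —
  by design, matching the published integration-based analysis.
- No spatial encoding, B0/B1 maps, SAR, or vendor file export.
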