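# Methods

## Signal model

The chest is modelled as a point reflector whose displacement is the sum
of two tones, `x(t) = m_r sin(2πf_r t + φ_r) + m_h sin(2πf_h t + φ_h)`,
with amplitudes in mm and rates in Hz internally (bpm only at the CLI
boundary, 1 bpm = 1/60 Hz). The quadrature baseband pair is
`B_I = cos(4πx/λ + ψ)`, `B_Q = sin(4πx/λ + ψ)` with the receiver
amplitude normalized to 1, so every noiseless sample has unit modulus.
The wavelength default is λ = 5 mm (60 GHz carrier); acquisition defaults
are Fs = 100 Hz and T = 10 s, giving the spectral resolution
Δf = 1/T = 0.1 Hz that frames all of the detection arguments.

Only the combined residual phase ψ = θ + 4πd₀/λ is identifiable from
baseband data, so the nominal range d₀ and system phase θ are absorbed
into a single constant; ψ is assumed constant over an observation window
(still subject).

The complex baseband `B = e^{j(4πx/λ + ψ)}` expands into a double Bessel
series: a line of complex amplitude
`J_n(4πm_h/λ) J_k(4πm_r/λ) e^{j(nφ_h + kφ_r + ψ)}` at every frequency
`n f_h + k f_r`. `bessel_line_spectrum` evaluates this closed form
(grouping coincident frequencies by complex summation before magnitude
pruning) and serves as the analytic oracle against which the FFT of the
simulated signal is tested to ≤ 2%. Under the exact ambiguity
`n′f_h = k′f_r` the two leading coincident lines superpose coherently;
`ambiguity_amplitude` evaluates that two-term closed form, whose value
depends on `n′φ_h − k′φ_r` but not on ψ. Defaults `max_order=12`,
`floor=1e-6` cover m_r ≤ 2 mm at λ = 5 mm to below the floor; larger
amplitudes need a larger `max_order` (the reconstruction used by the
estimators evaluates the exponential directly and has no truncation).

**Receiver noise.** `add_awgn` adds independent zero-mean Gaussian noise
to each channel. SNR is defined per channel: each channel's noise
variance is its own clean power divided by `10^(SNR/10)`
(`per_channel=False` switches to a complex-signal definition; for a
unit-modulus signal the two differ only in how a slight I/Q power
imbalance is split). Empirical calibration is within 5% at 10⁴ samples.

**Body-motion artifact.** Random body motion is modelled as half a sine
cycle — amplitude 20 mm, period 0.5 s — recurring every 5 s, added to the
*displacement* before phase modulation (body motion physically modulates
path length). The first onset defaults to 2.5 s so a 10 s window holds
two complete, untruncated events. A 20 mm sweep in 125 ms is a ~630 rad/s
phase rate, far beyond what 100 Hz sampling can unwrap — one of the two
mechanisms (with spectral flooding) by which body motion destroys the
arctangent path.

## Demodulation and the direct baseline

`arctangent_demod` returns the unwrapped four-quadrant angle of (I, Q),
which for clean data is exactly the Doppler phase and hence *linear* in
x(t): a two-tone displacement yields exactly two spectral lines.
`complex_demod` returns B = I + jQ (mean removed by default — the DC
Bessel line carries no rate information). Spectra use a rectangular
window (the Δf = 1/T resolution argument assumes it; tapers would widen
the lines), one-sided, DC bin zeroed.

`peak_detect_rates` reads f_r as the largest bin in [0.1, 0.9] Hz and
f_h as the largest bin in [0.8, 3.0] Hz (band defaults chosen from the
physiological ranges; ties break toward lower frequency; a bin must
exceed 10⁻⁹ of the spectral maximum to count as a peak, else the result
is a flagged failure, never an exception). On complex-path spectra, bins
within Δf of the first four respiration harmonics are excluded from the
heart-band search first — without this the reading routinely locks onto
a harmonic. This guard is deliberately *disabled by default on
arctangent-path spectra*: that path is linear, so a heart-band peak at a
harmonic of f_r there can only be the heartbeat itself (under the 72 =
4×18 bpm ambiguity the rule would delete the true peak). Both behaviors
are switchable (`exclude_harmonics=True/False`) so the fully naive
baseline can be reproduced.

## Cost function and optimizers

`F(X) = ‖B_mes − B_est(X)‖²/‖B_mes‖²`, with `B_est` the unit-modulus
reconstruction from the candidate 7-vector. The frequency-domain variant
applies the same ratio to one-sided DC-zeroed *magnitude* spectra — a
complex-spectrum cost would equal the time-domain cost by Parseval;
discarding phase is what makes the frequency domain a genuinely
different (ψ- and shift-insensitive) objective. At an SNR of 10 dB the
time-domain cost at the true parameters is ≈ 0.09 (the noise floor), so
cost thresholds must be read against that floor.

Population evaluation is vectorized in float32 (the trig calls dominate
runtime; the resulting cost error is ~10⁻⁶, three orders below the
convergence tolerance). The scalar `cost()` is full float64.

* **LSM** — scipy trust-region-reflective least squares on the stacked
  real/imag residual (or the magnitude-spectrum residual), started from
  a uniform random point inside the bounds. Degenerate point bounds are
  returned as-is. Its poor success rate from random starts is a finding,
  not a defect: the ambiguity landscape is multimodal and local descent
  commits to whichever basin the start falls in.
* **GA** — real-coded: tournament selection (size 3), BLX-0.5 blend
  crossover at rate 0.8, per-gene Gaussian mutation (σ = 10% of the
  component range, rate 0.1), elitism 2, children clipped to bounds.
  Default population 200 (500 on the full-scale box).
* **PSO** — global-best swarm, inertia 0.9 → 0.4 linearly over the first
  min(budget, 200) iterations then held (the ramp must not stretch with
  a large evaluation budget, or the swarm never leaves exploration),
  cognitive = social = 1.49, velocities clamped to the component range,
  positions reflected at the bounds. Default swarm 200 (50 per subrange
  box).

**Stopping.** A run halts when the best cost falls below the tolerance
(10⁻³), when the evaluation budget is exhausted, or when the *relative*
improvement of the best cost over the stall window (GA 50 generations,
PSO 20 iterations — the customary toolbox defaults) drops below the same
tolerance. The relative-stall reading matters: under receiver noise the
cost can never approach 10⁻³, so stalling is the operative criterion
there, and it is also what produces the characteristic ~5% failure rate
of the noiseless PSO benchmark (a swarm that stalls in a local basin is
cut off rather than given unbounded time to escape). The `converged`
flag compares the final cost against the acceptance threshold (0.2
nominally — roughly a 20% model mismatch — raised to 0.3 under body
motion). `stop_at_threshold=True` additionally halts a run at the
threshold; this is the real-time operating mode used on the wide bounds
and inside the subrange scheme.

**Budgets.** Budgets are counted in cost-function evaluations for
hardware independence. The calibration used throughout: one candidate
evaluation on a 1000-sample trace costs ~25–50 µs vectorized, so a 5 s
real-time allowance corresponds to ≈ 2×10⁵ evaluations (10 s ≈ 4×10⁵).
Phases are optimized on [0, 2π] and never scored — they are nuisance
parameters; the error metric `|actual − est|/|actual|·100%` applies to
amplitudes and rates, falling back to the absolute error (flagged) when
the true value is below 10⁻⁶ in component units, which is how the
no-breath case (m_r = 0) is scored.

## Subrange parallel PSO

The full physiological box (f_r 12–60, f_h 48–180 bpm, m_r up to 6 mm)
is split into the 2×2 cross product of at-rest and after-sport rate
ranges, amplitudes unchanged (f_r: 12–30 / 30–60; f_h: 48–90 / 90–180
bpm). One swarm of 50 runs per box; per-box seeds derive from the master
seed (`seed + box_index`; restart r of a box reseeds deterministically),
and each box owns an equal share of the evaluation budget, which makes
the outcome exactly independent of box execution order. All boxes stop
at the first generation barrier at which any box's best cost has reached
the threshold; otherwise a box whose swarm stalls above the threshold is
reinitialized with a fresh independent population while its budget
lasts. The minimum-cost box is returned whether or not it converged, so
budget exhaustion still yields the best-so-far answer. The restarts are
load-bearing: the large-amplitude landscape (modulation index up to
~15 rad) traps a 50-particle swarm in most single runs, but a successful
run essentially always lands within a few percent on f_h, because at
m_h ≥ 0.05 mm the heartbeat carries enough signal energy that a wrong
f_h cannot reach cost 0.2.

When the estimated m_r falls below ~0.2 mm the subject is effectively
not breathing — the apnea flag used in the no-breath scenario.

## Scenario generator

The generator *is* the dataset; presets (shipped as YAML) encode the
benchmark conditions:

| preset | m_r (mm) | m_h (mm) | f_r (bpm) | f_h (bpm) | SNR | artifact |
|---|---|---|---|---|---|---|
| narrow_ambiguity | 1.0 | 0.08 | 18 | 72 (= 4f_r) | none | none |
| normal_wide | 2.0 | 0.3 | U[12,25] | U[60,100] | 10 dB | none |
| rapid | 2.0 | 0.3 | U[25,60] | U[100,180] | 10 dB | none |
| no_breath | 0 | 0.3 | U[12,25] | U[60,100] | 10 dB | none |
| body_motion | TG[0,6] | TG[0.05,1] | TG[12,60] | TG[48,180] | 10 dB | yes |

Phases are always uniform on [0, 2π). TG is a range-truncated Gaussian
with mean at the range midpoint and sd = range/4 (≈95% of mass inside
before truncation; parameters chosen once on that coverage argument).
Replicate k draws from seed `master_seed + k` in a fixed consumption
order, so any replicate is reproducible in isolation and replicate-level
parallelism cannot change results. Rates are *not* snapped to the Δf
grid (real physiology is off-grid); `on_grid=True` enables snapped draws
for spectral unit tests. The rapid preset caps f_r at 60 bpm so that
every drawn truth lies inside the subrange-search boxes — recovery is
always feasible by construction.

What the generator does **not** emulate: respiratory sinus arrhythmia or
any within-window rate variability, non-sinusoidal chest waveforms,
range-dependent amplitude, I/Q imbalance or DC offsets from real
hardware, multiple reflectors. Passing benchmarks therefore demonstrate
correct model inversion under the model's own assumptions plus white
noise and the half-sine artifact — not performance on real radar
captures.

## Benchmark harness

`run_benchmark` maps a (scenario, method, domain) cell over seeded
replicates and returns per-replicate errors with their empirical CDF.
Optimizer seeds are `master_seed + replicate + 2²⁰` — offset so the
scenario draw and the optimizer initialization never consume identical
underlying streams. Failed estimations (e.g. a peak search finding no
peak) score +∞ error rather than being dropped, keeping the CDF an
honest fraction of all replicates. Replicate counts: the full benchmark
script uses 200 per cell (500 for the fast LSM cell; 100/12 for the
expensive wide-bound PSO/GA cells, whose single-replicate cost is
dominated by restart-until-threshold); the test suite uses 30–120 per
cell, with assertion bands widened by two binomial standard errors at
the reduced n. At 200 replicates a probability near 0.9 carries a 95%
half-width of about ±0.03.

## Numerical notes and limitations

* Unwrapping assumes the per-sample phase step stays in (−π, π]; the
  20 mm artifact violates this at Fs = 100 Hz by design.
* The float32 population evaluator leaves a ~10⁻⁶ cost floor at the
  optimum; tests asserting "cost ≈ 0" through the optimizers use 10⁻⁴.
* GA/PSO hyperparameters beyond the stated ones are deliberately
  canonical, not tuned; the GA proves somewhat more noise-robust than
  the textbook expectation (its measured success at 6–10 dB is ~1.0).
* Tie-breaks in peak detection go to the lower frequency; the harmonic
  exclusion radius is one resolution bin.
* Wall-clock "estimation time" is not modelled; all real-time statements
  are expressed through the evaluation-budget calibration above.
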