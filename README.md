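# radarvitals

Noncontact estimation of breathing rate, heart rate, and chest-motion
amplitudes from a 60 GHz continuous-wave Doppler radar, by
bound-constrained optimization of a physiological phase-modulation model.

## The problem

A CW radar pointed at a person's chest receives a reflection whose phase
is modulated by chest displacement. With an IQ (quadrature) receiver the
baseband channels are

```
B_I(t) = cos(4πx(t)/λ + ψ),   B_Q(t) = sin(4πx(t)/λ + ψ),
```

with λ = 5 mm at 60 GHz, ψ a constant residual phase, and a two-tone
displacement model

```
x(t) = m_r sin(2πf_r t + φ_r) + m_h sin(2πf_h t + φ_h)
```

(respiration: m_r ~ 0.8–6 mm, f_r ~ 12–60 bpm; heartbeat: m_h ~
0.05–1 mm, f_h ~ 48–180 bpm). Because the modulation is nonlinear, the
complex baseband B = B_I + jB_Q carries Bessel-weighted lines at every
intermodulation frequency n·f_h + k·f_r. Whenever a respiration harmonic
lands on the heartbeat fundamental (n′f_h ≈ k′f_r — at 72 bpm the heart
sits exactly on the 4th harmonic of 18 bpm breathing), the observed peak
is a *coherent superposition* whose amplitude depends on the mutual
phases φ_r, φ_h. Direct spectral peak reading then becomes unreliable,
and it collapses outright under receiver noise or random body motion.

The remedy implemented here is model inversion: find the 7-vector
X = (m_r, m_h, f_r, f_h, φ_r, φ_h, ψ) minimizing the normalized cost

```
F(X) = ‖B_mes − B_est(X)‖² / ‖B_mes‖²
```

under physiological box bounds lb ≤ X ≤ ub, in either the time domain
(complex samples) or the frequency domain (one-sided, DC-zeroed magnitude
spectra). Three minimizers are provided — local trust-region least
squares (LSM), a real-coded genetic algorithm (GA), and particle swarm
optimization (PSO) — plus a parallel subrange-PSO scheme that splits the
full physiological range into four rest/sport (f_r, f_h) boxes, runs an
independent swarm per box with restart-on-stall, stops all boxes as soon
as one reaches the acceptance threshold (cost ≤ 0.2), and keeps the
minimum-cost box. Estimation error is scored per component as
|X_actual − X_est| / |X_actual| × 100%.

The package is aimed at researchers in noncontact physiological
monitoring who need a reproducible simulation-and-benchmark harness:
every claim is evaluated as an empirical CDF P(error ≤ threshold) over
seeded Monte-Carlo replicates.

## Worked example

```python
import radarvitals as rv

# the canonical hard case: heartbeat on the 4th respiration harmonic,
# receiver noise at 10 dB
scenario = rv.scenario_preset("narrow_ambiguity", master_seed=7, snr_db=10.0)
truth, signal = rv.draw_scenario(scenario, replicate=0)
print(f"truth:    fr={truth.fr_bpm:.2f} bpm  fh={truth.fh_bpm:.2f} bpm")

result = rv.estimate_pso(
    signal,
    scenario.radar_config,
    rv.ParameterBounds.rest_narrow(),
    rv.OptimizerSettings(population_size=200, seed=42),
)
p = result.params
print(f"estimate: fr={p.fr_bpm:.2f} bpm  fh={p.fh_bpm:.2f} bpm  "
      f"cost={result.final_cost:.3f}")
print(f"fh error: {rv.estimation_error(truth, p, 'fh').value:.2f}%")
```

Output:

```
truth:    fr=18.00 bpm  fh=72.00 bpm
estimate: fr=18.02 bpm  fh=72.15 bpm  cost=0.087
fh error: 0.20%
```

The final cost of 0.087 is the residual noise floor at 10 dB SNR (noise
power / signal power ≈ 0.1): the model fit has absorbed essentially all
of the physiological signal, and both rates are recovered to a fraction
of a percent despite the heartbeat sitting on a respiration harmonic.

The same pipeline is scriptable from a shell:

```bash
radarvitals simulate --scenario narrow_ambiguity --seed 7 --out trace.csv
radarvitals estimate --in trace.csv --method pso --bounds rest_narrow --out result.json
radarvitals benchmark --scenario no_breath --method pso_parallel --reps 200 --seed 1 --out cdf.json
```

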