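# All four physiological parameters drawn from range-truncated Gaussians over
# the full physiological ranges, plus a recurring 2 cm half-sine body-motion
# artifact (period 0.5 s, every 5 s) and receiver noise at 10 dB.
name: body_motion
mr: {kind: trunc_gauss, lo: 0.0, hi: 6.0}
mh: {kind: trunc_gauss, lo: 0.05, hi: 1.0}
fr_bpm: {kind: trunc_gauss, lo: 12.0, hi: 60.0}
fh_bpm: {kind: trunc_gauss, lo: 48.0, hi: 180.0}
duration: 10.0
sample_rate: 100.0
wavelength: 5.0
snr_db: 10.0
artifact: {amplitude: 20.0, period: 0.5, recurrence: 5.0, first_onset: 2.5}
n_replicates: 1000
master_seed: 0
on_grid: false
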