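# At-rest benchmark with an exact spectral ambiguity: the heartbeat (72 bpm)
# sits on the fourth harmonic of respiration (18 bpm). Noiseless by default;
# override snr_db for the noisy variants.
name: narrow_ambiguity
mr: 1.0
mh: 0.08
fr_bpm: 18.0
fh_bpm: 72.0
duration: 10.0
sample_rate: 100.0
wavelength: 5.0
snr_db: null
n_replicates: 1000
master_seed: 0
on_grid: false
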