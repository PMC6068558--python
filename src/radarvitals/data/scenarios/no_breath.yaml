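# Apnea: no respiration motion at all (mr = 0) with a normal heart rate.
# The estimated mr falling below ~0.2 mm is the apnea signature.
name: no_breath
mr: 0.0
mh: 0.3
fr_bpm: {kind: uniform, lo: 12.0, hi: 25.0}
fh_bpm: {kind: uniform, lo: 60.0, hi: 100.0}
duration: 10.0
sample_rate: 100.0
wavelength: 5.0
snr_db: 10.0
n_replicates: 1000
master_seed: 0
on_grid: false
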