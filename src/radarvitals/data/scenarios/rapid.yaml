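# After-sport condition: elevated breathing and heart rates. The fr range is
# capped at 60 bpm so every truth lies inside the subrange-search boxes.
name: rapid
mr: 2.0
mh: 0.3
fr_bpm: {kind: uniform, lo: 25.0, hi: 60.0}
fh_bpm: {kind: uniform, lo: 100.0, hi: 180.0}
duration: 10.0
sample_rate: 100.0
wavelength: 5.0
snr_db: 10.0
n_replicates: 1000
master_seed: 0
on_grid: false
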