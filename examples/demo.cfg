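# Demonstration run: small synthetic tumor section, both pipelines.
seed = 1
outdir = demo_out
pipeline = both

mri.grid_rows = 128
mri.grid_cols = 128
mri.tumor_radius = 45.0
mri.n_deposits = 30
mri.noise_sd = 0.01

histo.section_rows = 3000
histo.section_cols = 3000
histo.n_deposits = 12
histo.n_background_macrophages = 2000
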