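# Demo configuration for the three-progeny study-like analysis.
# Progeny sizes are fixed at 156 / 140 / 147; `scale` sets the marker count
# (0.25 of the full Table-style mix, ~240 markers) so the whole pipeline
# runs in a couple of minutes on one core.
seed: 1
scale: 0.25
error_rate: 0.002
missing_rate: 0.03
lod_threshold: 4.0
min_support: 2
alpha: 0.05
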