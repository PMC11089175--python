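shape:
- 240
- 320
background: translucent-yellowish
lesions:
- center:
  - 80.0
  - 90.0
  radii:
  - 30.0
  - 24.0
  angle: 15.0
  concentration: 50.0
  depth: 0.0
- center:
  - 160.0
  - 220.0
  radii:
  - 26.0
  - 26.0
  angle: 0.0
  concentration: 100.0
  depth: 0.5
k_sat: 0.5
mu: 0.6
noise_sd: 3.0
seed: 7
edge_softness: 0.05
n_highlights: 3
model_scale: '1:25'
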