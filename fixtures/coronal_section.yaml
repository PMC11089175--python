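shape:
- 256
- 256
background: opaque-pinkish
lesions:
- center:
  - 80.0
  - 128.0
  radii:
  - 30.0
  - 26.0
  angle: 0.0
  concentration: 5.0
  depth: 0.0
- center:
  - 180.0
  - 128.0
  radii:
  - 26.0
  - 24.0
  angle: 0.0
  concentration: 0.5
  depth: 0.0
k_sat: 0.5
mu: 0.6
noise_sd: 3.0
seed: 7
edge_softness: 0.05
n_highlights: 0
model_scale: '1:1'
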