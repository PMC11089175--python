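shape:
- 256
- 320
background: opaque-pinkish
lesions:
- center:
  - 75.0
  - 85.0
  radii:
  - 26.0
  - 22.0
  angle: 0.0
  concentration: 5.0
  depth: 0.3
- center:
  - 170.0
  - 160.0
  radii:
  - 24.0
  - 24.0
  angle: 0.0
  concentration: 2.5
  depth: 0.1
- center:
  - 90.0
  - 245.0
  radii:
  - 22.0
  - 18.0
  angle: 30.0
  concentration: 1.25
  depth: 0.0
k_sat: 0.5
mu: 0.6
noise_sd: 3.0
seed: 7
edge_softness: 0.05
n_highlights: 0
model_scale: '1:1'
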