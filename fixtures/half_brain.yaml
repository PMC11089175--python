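shape:
- 256
- 320
background: translucent-yellowish
lesions:
- center:
  - 60.0
  - 230.0
  radii:
  - 24.0
  - 20.0
  angle: 0.0
  concentration: 5.0
  depth: 0.0
- center:
  - 120.0
  - 260.0
  radii:
  - 20.0
  - 20.0
  angle: 0.0
  concentration: 5.0
  depth: 0.0
- center:
  - 90.0
  - 70.0
  radii:
  - 26.0
  - 22.0
  angle: -20.0
  concentration: 5.0
  depth: 0.6
- center:
  - 185.0
  - 110.0
  radii:
  - 22.0
  - 22.0
  angle: 0.0
  concentration: 5.0
  depth: 0.6
k_sat: 0.5
mu: 0.6
noise_sd: 3.0
seed: 7
edge_softness: 0.05
n_highlights: 2
model_scale: '1:1'
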