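name: case03
grid_size: 100
mask:
  shape: x_shape
  params: {}
assignments:
  TGFB: 1.0
  AngII: 1.0
  IL6: 1.0
  IL1: 1.0
  TNFa: 1.0
  NE: 1.0
default_input: 0.0
duration_iterations: 500
snapshot_iterations:
- 0
- 100
- 300
- 500
probe_cells:
- - 50
  - 50
- - 50
  - 75
fixed_dt: 0.1
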