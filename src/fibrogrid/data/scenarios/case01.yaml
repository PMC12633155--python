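name: case01
grid_size: 100
mask:
  shape: cells
  params:
    cells: []
assignments: {}
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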