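# CLI config schema

A `spindyn run` config is one YAML mapping. Frequencies are entered in
Hz, angles in radians or strings like `"pi/2"` / `"90deg"`, durations in
seconds; the boundary converts to the library's angular units exactly
once. Unknown or malformed fields abort with exit code 2 and a message
naming the field.

```yaml
spin_system: 2                      # n spins-1/2, or a list:
# spin_system:
#   - {label: I, spin: 0.5, isotope: "1H"}   # spin may be inferred from isotope
#   - {label: S, spin: 1.0}

interactions:                       # optional; all values in Hz
  offsets: {1: 200.0, 2: 300.0}     # per-spin z offsets
  j_couplings:
    - {spins: [1, 2], J: 50.0}      # full I·I coupling
    - {spins: [1, 2], J: 15.0, secular: true}   # 2πJ·I1z·I2z form
  quadrupolar:
    - {spin: 1, wQ: 1000.0}         # (2π·wQ/6)(3Iz² − I(I+1))

relaxation:                         # optional
  phenomenological: {T1: 1.0, T2: 0.5}          # uniform; or {T: 1.0};
  # or per-spin: {1: {T1: 1.0, T2: 0.5}, 2: {...}}
  thermalize: {B0: 11.4, isotope: "1H", temperature: 300.0}

sequence:                           # optional list of events
  - {type: pulse, flip: "pi/2", phase: x}       # ideal (instantaneous)
  - {type: pulse, flip: pi, phase: y, duration: 1.0e-5, spins: [1]}
  - {type: pulse, flip: pi, phase: x, nutation: 10000.0}   # Hz
  - {type: delay, duration: 0.5}
  - {type: filter, orders: [0], spins: [1, 2]}  # coherence-order filter
  - {type: shaped_pulse, duration: 0.2, origin_fraction: 0.5,
     amplitude: {shape: gaussian, max: 100.0, sigma: 0.05},
     frequency: {shape: tanh_sweep, extent: 500.0, tau: 0.05},
     phase: 0.0}
  # amplitude/frequency shapes: constant {value}, gaussian {max, sigma},
  # cosine {max, modulation}, tanh_sweep {extent, tau}; all Hz / s

task:                               # required
  kind: transformation              # transformation | trajectory | signal1d
  initial: {operator: z, spins: [1]}            # or initial_thermal: true
  observables:                      # transformation / trajectory targets
    - {operator: x}
    - {product: [{spin: 1, operator: z}, {spin: 2, operator: y}], scale: 2.0}
  npoints: 400                      # trajectory sampling density
  # --- signal1d only ---
  timing: {sw: 1000.0, npoints: "2k"}           # or {tmin, tmax, dt}
  line_broadening: automatic        # or a width in Hz, or none
  observe: [1]                      # restrict detection to these spins

ensemble:                           # optional (signal1d)
  parameter: interactions.quadrupolar.0.wQ      # config path to vary
  distribution: {type: normal, mean: 1000.0, sd: 30.0}
  # or {type: uniform, low: .., high: ..} or {type: values, values: [..]}
  n: 200

seed: 1                             # RNG seed for the ensemble sampling
output:
  prefix: result                    # output file prefix (default: config stem)
```

Outputs (written to `--out-dir`): `transformation` →
`<prefix>_amplitudes.json`; `trajectory` → `<prefix>_trajectory.csv`
(time plus re/im per observable); `signal1d` → `<prefix>_fid.csv`,
`<prefix>_fid.json` (timing, samples, mode table) and
`<prefix>_spectrum.csv`. Numbers are written with 17 significant digits
so re-reading reproduces the in-memory values exactly.
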