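# Expert-driven basic model of community care: 12 service variables with
# expected per-100k ranges used as uniform bounds by the area generator.
# T* = types of care available, P* = places (beds), U* = utilisation.
variables:
  - {name: TR2,    role: dea-input,  orientation: standard,     bounds: [1.0, 1.5]}
  - {name: PR2,    role: dea-input,  orientation: standard,     bounds: [9.0, 20.0]}
  - {name: UR2,    role: dea-output, orientation: standard,     bounds: [10.0, 19.0]}
  - {name: TR4R7,  role: dea-input,  orientation: standard,     bounds: [1.0, 3.1]}
  - {name: PR4R7,  role: dea-input,  orientation: standard,     bounds: [3.0, 13.0]}
  - {name: UR4R7,  role: dea-output, orientation: non-standard, bounds: [3.0, 12.0]}
  - {name: TR8R13, role: dea-input,  orientation: non-standard, bounds: [3.0, 20.0]}
  - {name: PR8R13, role: dea-input,  orientation: non-standard, bounds: [10.0, 20.0]}
  - {name: UR8R13, role: dea-output, orientation: standard,     bounds: [10.0, 40.0]}
  - {name: TD1D4,  role: dea-input,  orientation: standard,     bounds: [3.0, 20.0]}
  - {name: PD1D4,  role: dea-input,  orientation: standard,     bounds: [34.0, 100.0]}
  - {name: UD1D4,  role: dea-output, orientation: standard,     bounds: [33.0, 100.0]}
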