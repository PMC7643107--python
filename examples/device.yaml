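# Reference spiral device: rectangular cross-section, 10 loops, 5 outlets.
# Every numeric value carries an explicit unit tag and is converted to SI on load.
width: {value: 500, unit: um}
height: {value: 220, unit: um}
spiral_radius: {value: 5, unit: mm}
n_loops: 10
loop_spacing: {value: 300, unit: um}
n_outlets: 5
outlet_width: {value: 100, unit: um}
fluid:
  density: {value: 1000, unit: kg/m^3}
  viscosity: {value: 1.0e-3, unit: Pa.s}
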