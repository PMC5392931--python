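# Default cell model, sensitivity box and transport parameters.
# Units are embedded in key names; concentrations are mmol/L throughout.
acid_base:
  pka: 9.25
  temperature_K: 303.15
compartments:
  - name: cytosol
    volume_fraction: 0.70
    ph: 6.5          # midpoint of the 6-7 sensitivity range
  - name: vacuole
    volume_fraction: 0.14
    ph: 4.5
  - name: mitochondria
    volume_fraction: 0.01
    ph: 7.5          # contributes <0.01% of the retention factor
sensitivity_box:
  vacuole_fraction: [0.14, 0.25]
  cytosol_ph: [6.0, 7.0]
  vacuole_ph: [4.0, 5.5]
energetics:
  pmf_mV: -200.0     # model choice, reproduces the uniport ratio bounds
transport:
  a_m_m2_per_g: 3.22
  chi_n_mol_per_g: 5.60e-3
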