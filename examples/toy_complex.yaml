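# The standard three-bead host-guest complex and the full binding protocol.
# `geombind bind --seed 1 --config examples/toy_complex.yaml --out cycle.json`
system:
  builtin: toy_complex
  depths: [7.0, 5.0, 3.5]      # anchor-well depths, kcal/mol
  sigmas: [1.0, 0.9, 0.9]      # anchor-well widths, Å
  bond_k: 60.0                 # kcal/(mol·Å²)
  bond_r0: 1.5                 # Å
  angle_k: 30.0                # kcal/(mol·rad²)
  angle0_deg: 110.0

thermo:
  temperature: 300.0           # K
  v_standard: 1661.0           # Å³ (1 M standard state)

protocol:
  k_angular: 0.1               # kcal/(mol·deg²), all five angular restraints
  k_rmsd: 100.0                # kcal/(mol·Å²), conformational restraint
  r_star: 8.0                  # Å, reference separation (field < 1e-5 kcal/mol)
  r_min: 1.0
  separation_windows: 2
  rmsd_hi: 0.8
  euler_halfwidth: 60.0        # deg, PMF window half-width for Euler angles
  polar_halfwidth: 25.0        # deg, for the positional angles
  steps_angular: 2000000
  steps_rmsd: 1200000
  steps_separation: 2400000
  estimator: czar

oracle:
  site_box: [[-1.5, -4.0, -4.0], [6.5, 4.0, 4.0]]   # Å
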