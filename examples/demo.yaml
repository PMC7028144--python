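# Two-genotype demo: wild-type vs a low-production / long-cell cohort.
# Run:  rootkinetics run --config examples/demo.yaml --seed 1 --out out/
simulate:
  cohorts:
    wt:
      spec:
        meristem_length: 500.0        # um
        initial_cell_length: 10.0     # um
        meristem_strain_rate: 0.04    # 1/h
        elongation_zone_length: 400.0 # um
        elongation_strain_integral: 280.0  # um/h
    mut:
      spec:
        meristem_length: 375.0
        initial_cell_length: 10.0
        meristem_strain_rate: 0.04
        elongation_zone_length: 400.0
        elongation_strain_integral: 255.0
  roots: 10
  particles_per_root: 40
  dt: 1.0                 # h
  position_noise_sd: 5.0  # um
  length_cv: 0.05
  ploidy:
    proportions:
      wt:  {2C: 0.40, 4C: 0.33, 8C: 0.17, 16C: 0.05, 32C: 0.05}
      mut: {2C: 0.36, 4C: 0.30, 8C: 0.17, 16C: 0.12, 32C: 0.05}
    samples_per_genotype: 6
    n_nuclei: 10000
    anchor: 100.0
    cv: 0.05
static_profile:
  tol: 0.05
kinematics:
  bandwidth: 50.0   # um
  min_points: 16
ploidy: {}
compare:
  metrics: [P_cells_per_h, mature_len_um, Tc_h, V_um_per_h]
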