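# End-to-end demo: one contractile cell on a 1300 Pa gel, one tracer-bead
# rheology field of view, one two-channel co-localization scene, and one
# Alu-qPCR burden experiment. Runs in well under a minute on one CPU;
# rerunning with the same seed reproduces report.json bit-for-bit.
seed: 7
out_dir: demo_out
stages:
  traction:
    grid_shape: [48, 48]
    grid_spacing: 2.0          # µm
    youngs_modulus: 1300.0     # Pa
    poisson_ratio: 0.48
    mode: constrained
    effective_height_um: 5.0
    dipoles:
      - center: [47.0, 47.0]
        axis: [1.0, 0.0]
        force_magnitude: 100000.0  # pN
        separation: 20.0       # µm
        patch_sigma: 3.0       # µm
  rheology:
    alpha_true: 1.5
    dstar_true: 2.0            # nm²/s^alpha
    n_beads: 75
    frame_interval: 1.0        # s
    duration: 300.0            # s
    fit_window: [10.0, 300.0]  # s
  coloc:
    overlap_fraction: 0.5
    n_spots_a: 60
    n_extra_b: 30
    spot_sigma: 2.0            # px
    noise_sd: 0.1              # SNR 10 against unit-amplitude spots
  qpcr:
    efficiency: 1.0
    intercept_ct: 38.0
    noise_sd: 0.2              # cycles
    tissues: [liver, lung, spleen]
    n_per_group: 5
    control_equivalents: 50.0
    fold: 100.0
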