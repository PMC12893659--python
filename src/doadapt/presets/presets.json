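{
  "nominal": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.01, "L_f": 0.0001, "F_n": 1.0},
  "Savings with CP": {"K": 0.25, "F": 0.9, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.01, "L_f": 0.0, "F_n": 1.0},
  "Spontaneous Recovery": {"K": 0.25, "F": 0.9, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.01, "L_f": 0.0, "F_n": 1.0},
  "Evoked Recovery": {"K": 0.25, "F": 0.9, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 1.0},
  "Bansal, 2023": {"K": 0.25, "F": 0.7, "psi0": 0.9, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 1.0},
  "Bond & Taylor, 2015": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 1.0},
  "Morehead, 2017": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 1.0},
  "Kim, 2018": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 1.0},
  "Tsay, 2021": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.95, "A_fn": 0.95, "L0": 1.1, "b_f": 0.1, "L_f": 0.005, "F_n": 1.0},
  "Ignore-N (CW)": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.005, "F_n": 1.0},
  "Ignore-N (CCW)": {"K": 0.25, "F": 0.7, "psi0": 0.8, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.005, "F_n": 1.0},
  "Learn-N (CW)": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.005, "F_n": 1.0},
  "Learn-N (CCW)": {"K": 0.25, "F": 0.7, "psi0": 0.8, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.005, "F_n": 1.0},
  "Ignore-W": {"K": 0.25, "F": 0.7, "psi0": 0.9, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.01, "L_f": 0.002, "F_n": 1.0},
  "Learn-W": {"K": 0.25, "F": 0.7, "psi0": 0.9, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.95, "L0": 1.1, "b_f": 0.01, "L_f": 0.002, "F_n": 1.0},
  "Avraham, 2021": {"K": 0.25, "F": 0.9, "psi0": 0.9, "b_w": 0.001, "A_f": 0.9, "A_fn": 0.95, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 0.92},
  "Yin, 2020 (Fig 2A)": {"K": 0.25, "F": 0.85, "psi0": 0.9, "b_w": 0.001, "A_f": 0.6, "A_fn": 0.92, "L0": 1.1, "b_f": 0.02, "L_f": 0.0, "F_n": 0.95},
  "Yin, 2020 (Fig 2B)": {"K": 0.25, "F": 0.85, "psi0": 0.9, "b_w": 0.001, "A_f": 0.6, "A_fn": 0.92, "L0": 1.1, "b_f": 0.05, "L_f": 0.0, "F_n": 0.9},
  "Ruttle, 2021": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.8, "L0": 1.1, "b_f": 0.01, "L_f": 0.005, "F_n": 1.0},
  "Amario, 2024": {"K": 0.25, "F": 0.7, "psi0": 1.0, "b_w": 0.001, "A_f": 0.0, "A_fn": 0.9, "L0": 1.1, "b_f": 0.01, "L_f": 0.005, "F_n": 1.0},
  "saccadic": {"K": 0.22, "F": 0.9, "psi0": 0.95, "b_w": 0.0, "A_f": 0.0, "A_fn": 1.0, "L0": 1.1, "b_f": 0.0, "L_f": 0.0, "F_n": 1.0}
}
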