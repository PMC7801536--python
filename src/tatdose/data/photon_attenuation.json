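{
  "_schema": {
    "energy_mev": "photon energy grid, MeV",
    "mu_over_rho": "total mass attenuation coefficient (with coherent), cm^2/g",
    "mu_en_over_rho": "mass energy-absorption coefficient, cm^2/g",
    "z_over_a": "mean ratio of atomic number to mass number (electrons per amu)",
    "_note": "compiled from published NIST-style photon attenuation tabulations; interpolated log-log"
  },
  "water": {
    "energy_mev": [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0],
    "mu_over_rho": [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.137, 0.1186, 0.1061, 0.0969, 0.0896, 0.0786, 0.0707, 0.0632, 0.0575, 0.0494],
    "mu_en_over_rho": [4.944, 1.374, 0.5503, 0.1557, 0.0695, 0.0422, 0.0319, 0.0262, 0.0256, 0.0277, 0.0297, 0.0319, 0.0328, 0.033, 0.0329, 0.0321, 0.031, 0.0296, 0.0283, 0.026],
    "z_over_a": 0.5551
  },
  "air": {
    "energy_mev": [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0],
    "mu_over_rho": [5.12, 1.614, 0.7779, 0.3538, 0.2485, 0.208, 0.1875, 0.1662, 0.1541, 0.1356, 0.1233, 0.1067, 0.0954, 0.087, 0.0806, 0.0707, 0.0636, 0.0569, 0.0518, 0.0445],
    "mu_en_over_rho": [4.742, 1.334, 0.5389, 0.1537, 0.0683, 0.041, 0.0304, 0.0241, 0.0234, 0.025, 0.0268, 0.0288, 0.0296, 0.0297, 0.0296, 0.0289, 0.028, 0.0267, 0.0255, 0.0234],
    "z_over_a": 0.4992
  },
  "lung": {
    "energy_mev": [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0],
    "mu_over_rho": [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1505, 0.137, 0.1186, 0.1061, 0.0969, 0.0896, 0.0786, 0.0707, 0.0632, 0.0575, 0.0494],
    "mu_en_over_rho": [4.944, 1.374, 0.5503, 0.1557, 0.0695, 0.0422, 0.0319, 0.0262, 0.0256, 0.0277, 0.0297, 0.0319, 0.0328, 0.033, 0.0329, 0.0321, 0.031, 0.0296, 0.0283, 0.026],
    "z_over_a": 0.5551
  },
  "bone": {
    "energy_mev": [0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.25, 1.5, 2.0],
    "mu_over_rho": [28.51, 9.032, 4.001, 1.331, 0.666, 0.4242, 0.3148, 0.2229, 0.1855, 0.148, 0.1309, 0.1113, 0.0991, 0.0904, 0.0836, 0.0732, 0.0657, 0.0589, 0.0536, 0.0462],
    "mu_en_over_rho": [26.8, 8.388, 3.601, 1.07, 0.4507, 0.2336, 0.14, 0.0692, 0.0459, 0.0313, 0.0302, 0.0311, 0.0316, 0.0316, 0.0315, 0.0306, 0.0297, 0.0283, 0.027, 0.0248],
    "z_over_a": 0.5148
  }
}
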