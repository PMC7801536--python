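{
  "_schema": {
    "half_life_h": "physical half-life in hours; null for a stable nuclide",
    "emissions": "list of per-decay emission lines",
    "emissions[].kind": "one of alpha | beta_plus | beta_minus | discrete_electron | photon",
    "emissions[].energy_mev": "line energy in MeV; MEAN energy for continuous beta spectra",
    "emissions[].yield": "emissions per parent decay",
    "emissions[].endpoint_mev": "optional beta-spectrum endpoint energy (MeV), enables spectral sampling",
    "daughters": "list of {name, branching} decay branches to daughter nuclides"
  },
  "F-18": {
    "half_life_h": 1.8295,
    "emissions": [
      {"kind": "beta_plus", "energy_mev": 0.2498, "yield": 0.9686, "endpoint_mev": 0.6335},
      {"kind": "photon", "energy_mev": 0.511, "yield": 1.9372}
    ],
    "daughters": []
  },
  "At-211": {
    "half_life_h": 7.214,
    "emissions": [
      {"kind": "alpha", "energy_mev": 5.8674, "yield": 0.418},
      {"kind": "photon", "energy_mev": 0.079, "yield": 0.213},
      {"kind": "photon", "energy_mev": 0.0922, "yield": 0.051},
      {"kind": "discrete_electron", "energy_mev": 0.0056, "yield": 2.8}
    ],
    "daughters": [
      {"name": "Po-211", "branching": 0.582},
      {"name": "Bi-207", "branching": 0.418}
    ]
  },
  "Po-211": {
    "half_life_h": 0.00014333,
    "emissions": [
      {"kind": "alpha", "energy_mev": 7.4503, "yield": 0.9892},
      {"kind": "alpha", "energy_mev": 6.892, "yield": 0.00556},
      {"kind": "alpha", "energy_mev": 6.57, "yield": 0.00541},
      {"kind": "photon", "energy_mev": 0.8971, "yield": 0.00561},
      {"kind": "photon", "energy_mev": 0.569, "yield": 0.00545}
    ],
    "daughters": [
      {"name": "Pb-207", "branching": 1.0}
    ]
  },
  "Bi-207": {
    "half_life_h": 276567.0,
    "emissions": [
      {"kind": "photon", "energy_mev": 0.5697, "yield": 0.978},
      {"kind": "photon", "energy_mev": 1.0637, "yield": 0.745},
      {"kind": "photon", "energy_mev": 1.7702, "yield": 0.0687},
      {"kind": "discrete_electron", "energy_mev": 0.4817, "yield": 0.0155}
    ],
    "daughters": [
      {"name": "Pb-207", "branching": 1.0}
    ]
  },
  "Pb-207": {
    "half_life_h": null,
    "emissions": [],
    "daughters": []
  },
  "I-131": {
    "half_life_h": 192.61,
    "emissions": [
      {"kind": "beta_minus", "energy_mev": 0.1917, "yield": 1.0, "endpoint_mev": 0.6063},
      {"kind": "photon", "energy_mev": 0.3645, "yield": 0.815},
      {"kind": "photon", "energy_mev": 0.637, "yield": 0.0717},
      {"kind": "photon", "energy_mev": 0.2843, "yield": 0.0614},
      {"kind": "photon", "energy_mev": 0.0802, "yield": 0.0262},
      {"kind": "photon", "energy_mev": 0.7229, "yield": 0.0177},
      {"kind": "discrete_electron", "energy_mev": 0.3299, "yield": 0.0155}
    ],
    "daughters": [
      {"name": "Xe-131m", "branching": 0.0118}
    ]
  },
  "Xe-131m": {
    "half_life_h": 284.2,
    "emissions": [
      {"kind": "discrete_electron", "energy_mev": 0.129, "yield": 0.609},
      {"kind": "photon", "energy_mev": 0.1639, "yield": 0.0196}
    ],
    "daughters": []
  },
  "Lu-177": {
    "half_life_h": 159.53,
    "emissions": [
      {"kind": "beta_minus", "energy_mev": 0.1333, "yield": 1.0, "endpoint_mev": 0.4983},
      {"kind": "photon", "energy_mev": 0.2084, "yield": 0.1041},
      {"kind": "photon", "energy_mev": 0.113, "yield": 0.0617}
    ],
    "daughters": []
  }
}
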