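{
  "_schema": {
    "energy_mev": "kinetic energy grid, MeV",
    "let_kev_um": "electronic (collision) stopping power in unit-density liquid water, keV/um",
    "_note": "compiled from published ICRU-49/ICRU-37-style stopping-power tabulations; interpolated log-log"
  },
  "alpha": {
    "energy_mev": [0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 9.0, 10.0],
    "let_kev_um": [40.0, 58.0, 75.0, 105.0, 145.0, 170.0, 200.0, 213.0, 214.0, 207.0, 195.0, 183.0, 162.0, 145.0, 131.0, 120.0, 111.0, 103.0, 96.0, 89.5, 84.0, 79.0, 75.0, 71.0, 68.0, 62.0, 57.0]
  },
  "electron": {
    "energy_mev": [0.0001, 0.0003, 0.001, 0.003, 0.01, 0.03, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 2.0, 3.0, 5.0, 10.0],
    "let_kev_um": [25.0, 17.0, 12.6, 5.8, 2.256, 0.96, 0.668, 0.412, 0.284, 0.2355, 0.203, 0.192, 0.185, 0.182, 0.186, 0.192, 0.2]
  }
}
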