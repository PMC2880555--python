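{
  "cell_type": "basket",
  "comment": "Fast-spiking soma-targeting basket cell, 3 compartments, essentially non-adapting (no Ca/KCa machinery). Units: nF, nS, mV.",
  "compartments": {
    "soma": {
      "c_m": 0.016,
      "g_m": 3.2,
      "E_leak": -65.0
    },
    "basal": {
      "c_m": 0.012,
      "g_m": 2.4,
      "E_leak": -65.0
    },
    "initial_segment": {
      "c_m": 0.004,
      "g_m": 0.8,
      "E_leak": -65.0
    }
  },
  "core": {
    "soma-basal": 60.0,
    "soma-initial_segment": 40.0
  },
  "channels": {
    "g_na": {
      "soma": 2000.0,
      "initial_segment": 600.0
    },
    "g_k": {
      "soma": 1200.0,
      "initial_segment": 320.0
    },
    "g_ca": {},
    "g_kca": {},
    "ca_alpha": 0.0,
    "ca_tau": 100.0,
    "nmda_ca_scale": 0.15,
    "E_na": 50.0,
    "E_k": -90.0,
    "E_ca": 150.0
  },
  "g_ext": 0.0,
  "E_ex": 0.0
}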