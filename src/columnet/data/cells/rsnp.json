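{
  "cell_type": "RSNP",
  "comment": "Regular-spiking non-pyramidal (double-bouquet-like) dendrite-targeting interneuron, 3 compartments, intermediate adaptation. Units: nF, nS, mV.",
  "compartments": {
    "soma": {
      "c_m": 0.008,
      "g_m": 0.8,
      "E_leak": -66.0
    },
    "basal": {
      "c_m": 0.006,
      "g_m": 0.6,
      "E_leak": -66.0
    },
    "initial_segment": {
      "c_m": 0.002,
      "g_m": 0.2,
      "E_leak": -66.0
    }
  },
  "core": {
    "soma-basal": 30.0,
    "soma-initial_segment": 20.0
  },
  "channels": {
    "g_na": {
      "soma": 800.0,
      "initial_segment": 300.0
    },
    "g_k": {
      "soma": 400.0,
      "initial_segment": 120.0
    },
    "g_ca": {
      "soma": 3.0
    },
    "g_kca": {
      "soma": 16.0
    },
    "ca_alpha": 0.0001,
    "ca_tau": 200.0,
    "nmda_ca_scale": 0.15,
    "E_na": 50.0,
    "E_k": -90.0,
    "E_ca": 150.0
  },
  "g_ext": 0.0,
  "E_ex": 0.0
}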