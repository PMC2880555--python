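{
  "cell_type": "pyramidal",
  "comment": "Layer 2/3 pyramidal cell, 6 compartments. Strongly adapting. Calibrated so that the standard background noise source (300 /s Poisson, 0.08 nS AMPA on apical2+basal) alone drives ~8 spikes/s with <CV2> ~= 0.69. Units: nF, nS, mV.",
  "compartments": {
    "soma": {
      "c_m": 0.005,
      "g_m": 0.5,
      "E_leak": -65.25
    },
    "basal": {
      "c_m": 0.003,
      "g_m": 0.3,
      "E_leak": -65.25
    },
    "initial_segment": {
      "c_m": 0.001,
      "g_m": 0.1,
      "E_leak": -65.25
    },
    "apical1": {
      "c_m": 0.0025,
      "g_m": 0.25,
      "E_leak": -65.25
    },
    "apical2": {
      "c_m": 0.002,
      "g_m": 0.2,
      "E_leak": -65.25
    },
    "apical3": {
      "c_m": 0.0015,
      "g_m": 0.15,
      "E_leak": -65.25
    }
  },
  "core": {
    "soma-basal": 15.0,
    "soma-initial_segment": 10.0,
    "soma-apical1": 15.0,
    "apical1-apical2": 10.0,
    "apical2-apical3": 7.0
  },
  "channels": {
    "g_na": {
      "soma": 400.0,
      "initial_segment": 150.0
    },
    "g_k": {
      "soma": 160.0,
      "initial_segment": 60.0
    },
    "g_ca": {
      "soma": 2.0
    },
    "g_kca": {
      "soma": 30.0
    },
    "ca_alpha": 0.0001,
    "ca_tau": 300.0,
    "nmda_ca_scale": 0.15,
    "E_na": 50.0,
    "E_k": -90.0,
    "E_ca": 150.0
  },
  "g_ext": 0.0,
  "E_ex": 0.0
}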