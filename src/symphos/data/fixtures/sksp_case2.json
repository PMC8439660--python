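{
  "name": "sksp_case2",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "separate",
    "phosphatase_mode": "separate",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 1.0039609129305955,
        "k_off": 0.3136235910428823,
        "k_cat": 7.105622125918801
      },
      "d:A10>A00": {
        "k_on": 1.0039609129305955,
        "k_off": 0.3136235910428823,
        "k_cat": 7.105622125918801
      },
      "d:A11>A01": {
        "k_on": 0.7746133492364546,
        "k_off": 0.6705800945195862,
        "k_cat": 7.53313934731181
      },
      "d:A11>A10": {
        "k_on": 0.7746133492364546,
        "k_off": 0.6705800945195862,
        "k_cat": 7.53313934731181
      },
      "p:A00>A01": {
        "k_on": 12.032141007458415,
        "k_off": 2.025347754376392,
        "k_cat": 6.226533970657075
      },
      "p:A00>A10": {
        "k_on": 12.032141007458415,
        "k_off": 2.025347754376392,
        "k_cat": 6.226533970657075
      },
      "p:A01>A11": {
        "k_on": 31.953203636491544,
        "k_off": 0.7703409025009259,
        "k_cat": 1.2615356866098248
      },
      "p:A10>A11": {
        "k_on": 31.953203636491544,
        "k_off": 0.7703409025009259,
        "k_cat": 1.2615356866098248
      }
    },
    "totals": {
      "substrate_total": 6.073263733160981,
      "enzyme_totals": {
        "K1": 1.1388659409130901,
        "K2": 1.1388659409130901,
        "P1": 0.6362430001249484,
        "P2": 0.6362430001249484
      }
    }
  },
  "a_range": [
    0.022777318818261803,
    25.0
  ],
  "case": "case2",
  "notes": "seed 3 conditioned on k1/k4 > PT/KT > k2/k3; supercritical pitchfork near A=11.13; A00/A11 pinned on the asymmetric branches"
}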