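{
  "name": "mixed2_case2",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "separate",
    "phosphatase_mode": "common",
    "dephosphorylation": "processive"
  },
  "parameters": {
    "triplets": {
      "p:A00>A01": {
        "k_on": 29.626130418782047,
        "k_off": 3.1940209325751465,
        "k_cat": 18.957995062112794
      },
      "p:A00>A10": {
        "k_on": 29.626130418782047,
        "k_off": 3.1940209325751465,
        "k_cat": 18.957995062112794
      },
      "p:A01>A11": {
        "k_on": 8.840207804223306,
        "k_off": 12.728374183577378,
        "k_cat": 0.1372817787795644
      },
      "p:A10>A11": {
        "k_on": 8.840207804223306,
        "k_off": 12.728374183577378,
        "k_cat": 0.1372817787795644
      },
      "proc:A11>A00:via01": {
        "k_on": 1.5323354714925708,
        "k_off": 5.24007364185972,
        "k_cat": 34.11567145124491
      },
      "proc:A11>A00:via10": {
        "k_on": 1.5323354714925708,
        "k_off": 5.24007364185972,
        "k_cat": 34.11567145124491
      }
    },
    "totals": {
      "substrate_total": 0.39660861757979243,
      "enzyme_totals": {
        "K1": 1.0483244202821385,
        "K2": 1.0483244202821385,
        "P": 3.6743610665238338
      }
    }
  },
  "a_range": [
    0.07348722133047668,
    10.0
  ],
  "case": "case2",
  "notes": "seed 9; processive dephosphorylation with separate kinases breaks the leg-exchange symmetry: supercritical pitchfork near A=4.02"
}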