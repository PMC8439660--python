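{
  "name": "random_ckcp_case1",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 2.5410333603388624,
        "k_off": 1.0932283927712874,
        "k_cat": 24.962768695191482
      },
      "d:A10>A00": {
        "k_on": 0.16263588153864583,
        "k_off": 16.82061927175265,
        "k_cat": 1.860883477750745
      },
      "d:A11>A01": {
        "k_on": 15.70580056962994,
        "k_off": 1.395157391882497,
        "k_cat": 8.126820301688786
      },
      "d:A11>A10": {
        "k_on": 4.6354517679496725,
        "k_off": 33.00264248190588,
        "k_cat": 0.6550879043607041
      },
      "p:A00>A01": {
        "k_on": 15.70580056962994,
        "k_off": 1.395157391882497,
        "k_cat": 8.126820301688786
      },
      "p:A00>A10": {
        "k_on": 4.6354517679496725,
        "k_off": 33.00264248190588,
        "k_cat": 0.6550879043607041
      },
      "p:A01>A11": {
        "k_on": 2.5410333603388624,
        "k_off": 1.0932283927712874,
        "k_cat": 24.962768695191482
      },
      "p:A10>A11": {
        "k_on": 0.16263588153864583,
        "k_off": 16.82061927175265,
        "k_cat": 1.860883477750745
      }
    },
    "totals": {
      "substrate_total": 1.7012581665586322,
      "enzyme_totals": {
        "K": 2.40373999748515,
        "P": 2.40373999748515
      }
    }
  },
  "a_range": [
    0.048074799949703,
    31.0
  ],
  "case": "case1",
  "notes": "seed 0 conditioned on k2>k1, a2>a1; supercritical pitchfork near A=14.07"
}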