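{
  "name": "sksp_case1",
  "network": {
    "topology": "random_dsp",
    "kinase_mode": "separate",
    "phosphatase_mode": "separate",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:A01>A00": {
        "k_on": 0.9546747826312745,
        "k_off": 0.535322589015901,
        "k_cat": 3.3488258581349375
      },
      "d:A10>A00": {
        "k_on": 0.802551431187669,
        "k_off": 17.25698426849497,
        "k_cat": 5.447516321502561
      },
      "d:A11>A01": {
        "k_on": 0.8527030104570045,
        "k_off": 1.2208600675420849,
        "k_cat": 1.1133483293310835
      },
      "d:A11>A10": {
        "k_on": 8.628317571019208,
        "k_off": 19.70391035244848,
        "k_cat": 1.77701309599328
      },
      "p:A00>A01": {
        "k_on": 0.8527030104570045,
        "k_off": 1.2208600675420849,
        "k_cat": 1.1133483293310835
      },
      "p:A00>A10": {
        "k_on": 8.628317571019208,
        "k_off": 19.70391035244848,
        "k_cat": 1.77701309599328
      },
      "p:A01>A11": {
        "k_on": 0.9546747826312745,
        "k_off": 0.535322589015901,
        "k_cat": 3.3488258581349375
      },
      "p:A10>A11": {
        "k_on": 0.802551431187669,
        "k_off": 17.25698426849497,
        "k_cat": 5.447516321502561
      }
    },
    "totals": {
      "substrate_total": 0.43280592870085677,
      "enzyme_totals": {
        "K1": 1.0750389633516109,
        "K2": 1.4610622760532601,
        "P1": 1.4610622760532601,
        "P2": 1.0750389633516109
      }
    }
  },
  "a_range": [
    0.0292212455210652,
    52.0
  ],
  "case": "case1",
  "notes": "seed 2 conditioned on the two-inequality criterion; pitchfork near A=23.78"
}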