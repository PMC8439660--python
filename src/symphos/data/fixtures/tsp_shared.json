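{
  "name": "tsp_shared",
  "network": {
    "topology": "ordered_tsp",
    "kinase_mode": "common",
    "phosphatase_mode": "common",
    "dephosphorylation": "distributive"
  },
  "parameters": {
    "triplets": {
      "d:Ap>A": {
        "k_on": 9.314785261541516,
        "k_off": 16.610803212600324,
        "k_cat": 72.09499901123318
      },
      "d:App>Ap": {
        "k_on": 0.5847880003105468,
        "k_off": 12.429504740266891,
        "k_cat": 10.989030441663942
      },
      "d:Appp>App": {
        "k_on": 10.441524494648935,
        "k_off": 4.122060330154927,
        "k_cat": 10.54831758835225
      },
      "p:A>Ap": {
        "k_on": 10.441524494648935,
        "k_off": 4.122060330154927,
        "k_cat": 10.54831758835225
      },
      "p:Ap>App": {
        "k_on": 0.5847880003105468,
        "k_off": 12.429504740266891,
        "k_cat": 10.989030441663942
      },
      "p:App>Appp": {
        "k_on": 9.314785261541516,
        "k_off": 16.610803212600324,
        "k_cat": 72.09499901123318
      }
    },
    "totals": {
      "substrate_total": 0.22666536893758638,
      "enzyme_totals": {
        "K": 2.0592845558902506,
        "P": 2.0592845558902506
      }
    }
  },
  "a_range": [
    0.04118569111780501,
    12.0
  ],
  "case": "case1",
  "notes": "seed 4; triple-site chain, pitchfork near A=4.96; shared robustness of the sum Ap+App on the asymmetric branches"
}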