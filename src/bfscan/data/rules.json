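{
  "description": "Subunit complements, per-role E-value cut-offs and ORF flanking windows for the twelve biochemically confirmed flavin-based electron-bifurcating enzyme complexes. Windows count annotated ORFs on the same replicon; 'ALL' means anywhere in the genome; paired windows tie the two small Hdr2 subunits to each other. The metagenome block gives the relaxed contig-level complements.",
  "role_thresholds": {
    "HydA": 2e-20,
    "HydB": 2e-13,
    "HydC": 1e-07,
    "HydD": 2e-13,
    "MvhA": 1e-90,
    "MvhG": 5e-07,
    "MvhD": 4e-07,
    "HdrA": 3e-08,
    "HdrB": 1e-03,
    "HdrC": 2e-06,
    "FdhA": 6e-12,
    "FdhB": 8e-15,
    "HytA": 1e-04,
    "HytB": 2e-13,
    "HytC": 1e-07,
    "HytD": 3e-17,
    "HytE1": 1e-43,
    "HytE2": 1e-43,
    "NfnS": 9e-22,
    "NfnL": 2e-96,
    "FixA": 1e-43,
    "FixB": 6e-45,
    "FixC": 4e-35,
    "FixX": 3e-05,
    "Bcd": 3e-12,
    "EtfA": 6e-45,
    "EtfB": 1e-43,
    "CarC": 2e-12,
    "FdhF2": 6e-12,
    "HylA": 2e-39,
    "HylB": 3e-14,
    "HylC": 5e-38,
    "Ldh": 3e-29,
    "MetF": 9e-13,
    "MetV": 0.1
  },
  "shared_roles": ["EtfA", "EtfB", "MvhD"],
  "complexes": [
    {
      "name": "Hyd",
      "label": "NAD(H)-dependent [FeFe]-hydrogenase",
      "catalytic": "HydA",
      "companions": [
        {"role": "HydB", "window": "±5"},
        {"role": "HydC", "window": "±5"},
        {"role": "HydD", "window": "±5", "required": false}
      ]
    },
    {
      "name": "Mvh",
      "label": "[NiFe]-hydrogenase/heterodisulfide reductase",
      "catalytic": "MvhA",
      "companions": [
        {"role": "MvhG", "window": "±3"},
        {"role": "MvhD", "window": "±3"},
        {"role": "HdrA", "window": "ALL"},
        {"role": "HdrB", "window": "ALL"},
        {"role": "HdrC", "window": "ALL"}
      ],
      "metagenome": {
        "companions": [
          {"role": "MvhG", "window": "±3"},
          {"role": "MvhD", "window": "±3"}
        ]
      }
    },
    {
      "name": "Fdh",
      "label": "Formate dehydrogenase/heterodisulfide reductase",
      "catalytic": "FdhA",
      "companions": [
        {"role": "FdhB", "window": "±1"},
        {"role": "HdrA", "window": "ALL"},
        {"role": "HdrB", "window": "ALL"},
        {"role": "HdrC", "window": "ALL"}
      ],
      "metagenome": {
        "companions": [
          {"role": "FdhB", "window": "±1"}
        ]
      }
    },
    {
      "name": "Hyt",
      "label": "NADP(H)-dependent [FeFe]-hydrogenase",
      "catalytic": "HytA",
      "companions": [
        {"role": "FdhA", "window": "±10"},
        {"role": "HytE2", "window": "±10"},
        {"role": "HytE1", "window": "±10"},
        {"role": "HytD", "window": "±10"},
        {"role": "HytB", "window": "±10"},
        {"role": "HytC", "window": "±10"}
      ]
    },
    {
      "name": "Nfn",
      "label": "NAD(H)-dependent reduced ferredoxin:NADP(H) oxidoreductase",
      "catalytic": "NfnL",
      "companions": [
        {"role": "NfnS", "window": "±1"}
      ]
    },
    {
      "name": "Fix",
      "label": "Electron transfer flavoprotein involved in nitrogen fixation",
      "catalytic": "FixA",
      "companions": [
        {"role": "FixB", "window": "±4"},
        {"role": "FixC", "window": "±4"},
        {"role": "FixX", "window": "±4"}
      ]
    },
    {
      "name": "Bcd",
      "label": "Butyryl-CoA dehydrogenase/electron transfer flavoprotein",
      "catalytic": "Bcd",
      "companions": [
        {"role": "EtfA", "window": "±2"},
        {"role": "EtfB", "window": "±2"}
      ]
    },
    {
      "name": "Car",
      "label": "Caffeyl-CoA reductase/electron transfer flavoprotein",
      "catalytic": "CarC",
      "companions": [
        {"role": "EtfB", "window": "±2"},
        {"role": "EtfA", "window": "±2"}
      ]
    },
    {
      "name": "Hyl",
      "label": "NAD(H)-dependent formate dehydrogenase",
      "catalytic": "HylA",
      "companions": [
        {"role": "FdhF2", "window": "±4"},
        {"role": "HylB", "window": "±4"},
        {"role": "HylC", "window": "±4"}
      ]
    },
    {
      "name": "Ldh",
      "label": "Lactate dehydrogenase/electron transfer flavoprotein",
      "catalytic": "Ldh",
      "companions": [
        {"role": "EtfA", "window": "±2"},
        {"role": "EtfB", "window": "±2"}
      ]
    },
    {
      "name": "Hdr2",
      "label": "F420H2-dependent heterodisulfide reductase",
      "catalytic": "HdrA",
      "special": "hdr2",
      "companions": [
        {"role": "HdrB", "window": {"type": "paired", "sibling": "HdrC", "k": 2}},
        {"role": "HdrC", "window": {"type": "paired", "sibling": "HdrB", "k": 2}}
      ],
      "metagenome": {"disabled": true}
    },
    {
      "name": "Met",
      "label": "Methylene-tetrahydrofolate reductase/heterodisulfide reductase",
      "catalytic": "MetF",
      "companions": [
        {"role": "MetV", "window": "±3"},
        {"role": "MvhD", "window": "±3"},
        {"role": "HdrA", "window": "ALL"},
        {"role": "HdrB", "window": "ALL"},
        {"role": "HdrC", "window": "ALL"}
      ],
      "metagenome": {
        "companions": [
          {"role": "MetV", "window": "±3"},
          {"role": "MvhD", "window": "±3"}
        ]
      }
    }
  ]
}
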