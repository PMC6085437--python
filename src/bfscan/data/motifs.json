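{
  "description": "Active-site motif screens per catalytic-subunit class. Grammar: uppercase residue = required; x = any residue; xN = N-fold any-residue run; lowercase residue = weakly conserved position (required under the strict policy, wildcard under the relaxed policy). mode 'require' keeps only sequences containing the motif; 'require_absence' keeps only sequences lacking it. Classes with no published motif (NfnS, NfnL, MetF) carry empty lists and pass by default.",
  "roles": {
    "HydA": [
      {"name": "L1", "pattern": "TSCCPxW", "mode": "require"},
      {"name": "L2", "pattern": "MPCxxKxxE", "mode": "require"},
      {"name": "L3", "pattern": "ExMACxxGCxxGGGxP", "mode": "require"}
    ],
    "HytA": [
      {"name": "L1", "pattern": "TSCCPxW", "mode": "require"},
      {"name": "L2", "pattern": "MPCxxKxxE", "mode": "require"},
      {"name": "L3", "pattern": "ExMACxxGCxxGGGxP", "mode": "require"}
    ],
    "HylA": [
      {"name": "L1", "pattern": "TSCCPxW", "mode": "require_absence"},
      {"name": "L2", "pattern": "MPCxxKxxE", "mode": "require_absence"},
      {"name": "L3", "pattern": "ExMACxxGCxxGGGxP", "mode": "require_absence"}
    ],
    "MvhA": [
      {"name": "L1", "pattern": "ICGxCxxxH", "mode": "require"},
      {"name": "L2", "pattern": "AYDPCccCATH", "mode": "require"}
    ],
    "FdhA": [
      {"name": "CysSig", "pattern": "CxxCxxCx26C", "mode": "require"}
    ],
    "FdhF2": [
      {"name": "CysSig", "pattern": "CxxCxxCx26C", "mode": "require_absence"}
    ],
    "NfnS": [],
    "NfnL": [],
    "MetF": []
  }
}
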