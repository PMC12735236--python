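{
  "SC_ACID": {
    "description": "Unsaturated side chain terminating in a free carboxyl group: CO2 loss followed by CO2+CH4.",
    "rules": [
      {"kind": "loss", "label": "[M-H-CO2]-", "chain": ["CO2"], "required": true, "weight": 0.5},
      {"kind": "loss", "label": "[M-H-CO2-CH4]-", "chain": ["CO2", "CH4"], "required": true, "weight": 0.5}
    ]
  },
  "SC_ACID_HYDROXY": {
    "description": "Carboxylated side chain plus hydroxyl: CO2, H2O and CO2+H2O losses, no CH4 chain.",
    "rules": [
      {"kind": "loss", "label": "[M-H-CO2]-", "chain": ["CO2"], "required": true, "weight": 0.4},
      {"kind": "loss", "label": "[M-H-H2O]-", "chain": ["H2O"], "required": true, "weight": 0.3},
      {"kind": "loss", "label": "[M-H-CO2-H2O]-", "chain": ["CO2", "H2O"], "required": true, "weight": 0.3},
      {"kind": "loss", "label": "[M-H-CO2-CH4]-", "chain": ["CO2", "CH4"], "forbidden": true}
    ]
  },
  "CORE_3OH_4COOH": {
    "description": "3-hydroxy-4-carboxy core: spectrum dominated by the CO2+H2O loss, CH4 chain absent.",
    "rules": [
      {"kind": "loss", "label": "[M-H-CO2-H2O]-", "chain": ["CO2", "H2O"], "required": true, "base_peak": true, "weight": 0.7},
      {"kind": "loss", "label": "[M-H-CO2-CH4]-", "chain": ["CO2", "CH4"], "forbidden": true},
      {"kind": "loss", "label": "[M-H-H2O]-", "chain": ["H2O"], "weight": 0.15},
      {"kind": "loss", "label": "[M-H-CO2]-", "chain": ["CO2"], "weight": 0.15}
    ]
  },
  "CARBONYL_CO": {
    "description": "Carbonyl group: distinctive CO-loss series CO, CO2, CO+CO2.",
    "rules": [
      {"kind": "loss", "label": "[M-H-CO]-", "chain": ["CO"], "required": true, "weight": 0.34},
      {"kind": "loss", "label": "[M-H-CO2]-", "chain": ["CO2"], "required": true, "weight": 0.33},
      {"kind": "loss", "label": "[M-H-CO-CO2]-", "chain": ["CO", "CO2"], "required": true, "weight": 0.33}
    ]
  },
  "ACETOXY_MOD": {
    "description": "Acetoxy substituent: acetic-acid loss and/or parallel fragment series 44 Da apart.",
    "rules": [
      {"kind": "loss", "label": "[M-H-C2H4O2]-", "chain": ["C2H4O2"], "weight": 0.5},
      {"kind": "parallel_series", "label": "parallel series (44 Da)", "offset": "C2H4O", "min_pairs": 3, "weight": 0.5}
    ]
  },
  "GLYCOSIDE": {
    "description": "Glycoside: sequential sugar-unit Y-ion losses (HexNAc/Hex first, then a second sugar) with sugar fragments at m/z 202 / 262.",
    "rules": [
      {"kind": "loss", "label": "Y1 (first sugar loss)", "chains": [["C8H13NO5"], ["C6H10O5"]], "required": true, "weight": 0.4},
      {"kind": "loss", "label": "Y2 (second sugar loss)", "chains": [["C8H13NO5", "C6H10O5"], ["C6H10O5", "C6H10O5"]], "weight": 0.3},
      {"kind": "series", "label": "sugar fragments 202/262", "nominal_mzs": [202, 262], "min_hits": 1, "weight": 0.3}
    ]
  },
  "NITROGENOUS": {
    "description": "Nitrogen-containing side chain: even nominal precursor with combined CO2 + C2H3NO (57.02 Da) losses.",
    "rules": [
      {"kind": "parity", "label": "even nominal precursor", "parity": "even", "required": true, "weight": 0.3},
      {"kind": "loss", "label": "[M-H-CO2-C2H3NO]-", "chain": ["CO2", "C2H3NO"], "weight": 0.35},
      {"kind": "loss", "label": "[M-H-CO2-CH4-C2H3NO]-", "chain": ["CO2", "CH4", "C2H3NO"], "weight": 0.35}
    ]
  },
  "LYSO_PI": {
    "description": "Lysophosphatidylinositol-type lipid: inositol-phosphate headgroup ions 259/241/223 plus hexose losses.",
    "rules": [
      {"kind": "series", "label": "headgroup 259/241/223", "nominal_mzs": [259, 241, 223], "min_hits": 2, "required": true, "weight": 0.6},
      {"kind": "loss", "label": "[M-H-C6H10O5]-", "chain": ["C6H10O5"], "weight": 0.2},
      {"kind": "loss", "label": "[M-H-C6H12O6]-", "chain": ["C6H12O6"], "weight": 0.2}
    ]
  },
  "CORE_RAA": {
    "description": "RAA-type core: side-chain cleavage series at m/z 301/285/261/245/229.",
    "rules": [
      {"kind": "series", "label": "RAA series 301/285/261/245/229", "nominal_mzs": [301, 285, 261, 245, 229], "min_hits": 3, "required": true, "weight": 1.0}
    ]
  },
  "CORE_JASPIFERAL": {
    "description": "Jaspiferal-type core: fragment series at m/z 269/257/215/183.",
    "rules": [
      {"kind": "series", "label": "jaspiferal series 269/257/215/183", "nominal_mzs": [269, 257, 215, 183], "min_hits": 3, "required": true, "weight": 1.0}
    ]
  },
  "CORE_OXY": {
    "description": "Extra core oxygenation: fragment ions at m/z 247 and 231.",
    "rules": [
      {"kind": "series", "label": "oxygenated core 247/231", "nominal_mzs": [247, 231], "min_hits": 2, "required": true, "weight": 1.0}
    ]
  }
}
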