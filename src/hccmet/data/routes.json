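{
  "comment": "Canonical single-pass label-propagation routes. Each step names a reaction from network.json; 'inputs' maps each substrate to 'carry' (the running distribution), 'pool' (unlabeled), or 'saved:<name>' (an intermediate stored with save_as). Single-substrate steps default to carry; the first product is carried unless 'product' says otherwise.",
  "routes": [
    {"name": "glucose_to_lactate", "tracer": "U-13C6-glucose", "label": "glycolysis -> LDH",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate"}, {"reaction": "LDH"}]},
    {"name": "glucose_to_alanine", "tracer": "U-13C6-glucose", "label": "glycolysis -> ALT",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate"}, {"reaction": "GPT1"}]},
    {"name": "glucose_pdh_citrate", "tracer": "U-13C6-glucose", "label": "PDH entry, unlabeled OAA",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate"},
               {"reaction": "PDH", "product": "AcCoA"},
               {"reaction": "CS", "inputs": {"AcCoA": "carry", "OAA": "pool"}}]},
    {"name": "glucose_pc_oaa", "tracer": "U-13C6-glucose", "label": "PC entry, unlabeled CO2",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate"},
               {"reaction": "PC", "inputs": {"pyruvate": "carry", "CO2": "pool"}}]},
    {"name": "glucose_pdh_pc_citrate", "tracer": "U-13C6-glucose", "label": "PDH + PC condensation",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate", "save_as": "pyr"},
               {"reaction": "PDH", "inputs": {"pyruvate": "saved:pyr"}, "product": "AcCoA", "save_as": "ac"},
               {"reaction": "PC", "inputs": {"pyruvate": "saved:pyr", "CO2": "pool"}, "product": "OAA"},
               {"reaction": "CS", "inputs": {"AcCoA": "saved:ac", "OAA": "carry"}}]},
    {"name": "glucose_oxidative_tca_succinate", "tracer": "U-13C6-glucose", "label": "PDH -> first-turn oxidative TCA",
     "steps": [{"reaction": "HK"}, {"reaction": "glycolysis", "product": "pyruvate"},
               {"reaction": "PDH", "product": "AcCoA"},
               {"reaction": "CS", "inputs": {"AcCoA": "carry", "OAA": "pool"}},
               {"reaction": "IDH_ox", "product": "aKG"},
               {"reaction": "OGDH", "product": "succinate"}]},
    {"name": "glucose_oxppp_6pg", "tracer": "U-13C6-glucose", "label": "oxidative PPP entry",
     "steps": [{"reaction": "HK"}, {"reaction": "G6PDH"}]},
    {"name": "glucose_oxppp_r5p", "tracer": "U-13C6-glucose", "label": "oxidative PPP",
     "steps": [{"reaction": "HK"}, {"reaction": "G6PDH"},
               {"reaction": "6PGD", "product": "Ru5P"}, {"reaction": "RPI"}]},
    {"name": "g3p_nonoxppp_r5p",
     "tracer": {"metabolite": "G3P", "pattern": [1, 1, 1]},
     "label": "non-oxidative PPP from glucose-derived m+3 G3P, unlabeled F6P",
     "steps": [{"reaction": "TKT2_rev", "inputs": {"F6P": "pool", "G3P": "carry"}, "product": "X5P"},
               {"reaction": "RPE_rev"}, {"reaction": "RPI"}]},
    {"name": "gln_to_glutamate", "tracer": "U-13C5-glutamine", "label": "glutaminolysis",
     "steps": [{"reaction": "GLS"}]},
    {"name": "gln_oxidative_succinate", "tracer": "U-13C5-glutamine", "label": "oxidative glutamine metabolism",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"}, {"reaction": "OGDH", "product": "succinate"}]},
    {"name": "gln_oxidative_malate", "tracer": "U-13C5-glutamine", "label": "oxidative glutamine metabolism",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"}, {"reaction": "OGDH", "product": "succinate"},
               {"reaction": "SDH"}, {"reaction": "FH"}]},
    {"name": "gln_oxidative_aspartate", "tracer": "U-13C5-glutamine", "label": "oxidative glutamine metabolism",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"}, {"reaction": "OGDH", "product": "succinate"},
               {"reaction": "SDH"}, {"reaction": "FH"}, {"reaction": "MDH"}, {"reaction": "GOT2"}]},
    {"name": "gln_oxidative_citrate", "tracer": "U-13C5-glutamine", "label": "oxidative glutamine metabolism, unlabeled AcCoA",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"}, {"reaction": "OGDH", "product": "succinate"},
               {"reaction": "SDH"}, {"reaction": "FH"}, {"reaction": "MDH"},
               {"reaction": "CS", "inputs": {"AcCoA": "pool", "OAA": "carry"}}]},
    {"name": "gln_reductive_citrate", "tracer": "U-13C5-glutamine", "label": "reductive carboxylation, unlabeled CO2",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"},
               {"reaction": "IDH_red", "inputs": {"aKG": "carry", "CO2": "pool"}}]},
    {"name": "gln_reductive_aspartate", "tracer": "U-13C5-glutamine", "label": "reductive carboxylation -> ACL -> GOT2",
     "steps": [{"reaction": "GLS"}, {"reaction": "GLUD1"},
               {"reaction": "IDH_red", "inputs": {"aKG": "carry", "CO2": "pool"}},
               {"reaction": "ACL", "product": "OAA"}, {"reaction": "GOT2"}]}
  ]
}
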