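{
  "comment": "Atom-mapped reaction library for central carbon metabolism. Carbon slots are 1-based and flattened across the substrate (resp. product) list in declared order; 'map' lists [substrate_slot, product_slot] pairs forming a bijection. TCA orientation convention: acetyl-CoA carbons occupy citrate C5/C6 and alpha-ketoglutarate C4/C5, so the CO2 released by both oxidative decarboxylations of the first turn is oxaloacetate-derived.",
  "metabolites": {
    "glucose": 6, "G6P": 6, "F6P": 6, "G3P": 3,
    "pyruvate": 3, "lactate": 3, "alanine": 3,
    "AcCoA": 2, "CO2": 1,
    "OAA": 4, "citrate": 6, "aKG": 5,
    "succinate": 4, "fumarate": 4, "malate": 4, "aspartate": 4,
    "glutamine": 5, "glutamate": 5,
    "6PG": 6, "Ru5P": 5, "R5P": 5, "X5P": 5, "S7P": 7, "E4P": 4
  },
  "symmetric_metabolites": ["succinate", "fumarate"],
  "reactions": [
    {"id": "HK", "substrates": [["glucose", 6]], "products": [["G6P", 6]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5],[6,6]]},
    {"id": "glycolysis", "substrates": [["G6P", 6]], "products": [["pyruvate", 3], ["pyruvate", 3]],
     "map": [[1,6],[2,5],[3,4],[4,1],[5,2],[6,3]],
     "comment": "Lumped PFK/aldolase/TPI/lower glycolysis: C4-C6 give the first pyruvate directly, C1-C3 give the second via DHAP with carbon order inverted."},
    {"id": "LDH", "substrates": [["pyruvate", 3]], "products": [["lactate", 3]],
     "map": [[1,1],[2,2],[3,3]]},
    {"id": "GPT1", "substrates": [["pyruvate", 3]], "products": [["alanine", 3]],
     "map": [[1,1],[2,2],[3,3]],
     "comment": "Alanine transaminase; only the carbon skeleton is tracked."},
    {"id": "PDH", "substrates": [["pyruvate", 3]], "products": [["AcCoA", 2], ["CO2", 1]],
     "map": [[1,3],[2,1],[3,2]],
     "comment": "Pyruvate C1 (carboxyl) is released as CO2."},
    {"id": "PC", "substrates": [["pyruvate", 3], ["CO2", 1]], "products": [["OAA", 4]],
     "map": [[1,1],[2,2],[3,3],[4,4]]},
    {"id": "CS", "substrates": [["AcCoA", 2], ["OAA", 4]], "products": [["citrate", 6]],
     "map": [[1,5],[2,6],[3,1],[4,2],[5,3],[6,4]]},
    {"id": "IDH_ox", "substrates": [["citrate", 6]], "products": [["aKG", 5], ["CO2", 1]],
     "map": [[1,6],[2,1],[3,2],[4,3],[5,4],[6,5]],
     "comment": "Lumped aconitase + oxidative IDH; releases an OAA-derived carboxyl (citrate C1)."},
    {"id": "IDH_red", "substrates": [["aKG", 5], ["CO2", 1]], "products": [["citrate", 6]],
     "map": [[1,2],[2,3],[3,4],[4,5],[5,6],[6,1]],
     "comment": "Reductive carboxylation; exact inverse of IDH_ox."},
    {"id": "OGDH", "substrates": [["aKG", 5]], "products": [["succinate", 4], ["CO2", 1]],
     "map": [[1,5],[2,1],[3,2],[4,3],[5,4]],
     "comment": "Lumped aKG dehydrogenase + succinyl-CoA synthetase; releases aKG C1."},
    {"id": "SDH", "substrates": [["succinate", 4]], "products": [["fumarate", 4]],
     "map": [[1,1],[2,2],[3,3],[4,4]]},
    {"id": "FH", "substrates": [["fumarate", 4]], "products": [["malate", 4]],
     "map": [[1,1],[2,2],[3,3],[4,4]]},
    {"id": "MDH", "substrates": [["malate", 4]], "products": [["OAA", 4]],
     "map": [[1,1],[2,2],[3,3],[4,4]]},
    {"id": "GOT2", "substrates": [["OAA", 4]], "products": [["aspartate", 4]],
     "map": [[1,1],[2,2],[3,3],[4,4]]},
    {"id": "ACL", "substrates": [["citrate", 6]], "products": [["OAA", 4], ["AcCoA", 2]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5],[6,6]],
     "comment": "ATP-citrate lyase; reverses the CS carbon assignment."},
    {"id": "GLS", "substrates": [["glutamine", 5]], "products": [["glutamate", 5]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5]]},
    {"id": "GLUD1", "substrates": [["glutamate", 5]], "products": [["aKG", 5]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5]],
     "comment": "Also stands for the GPT2/GOT2 transaminase entries; carbon skeleton is identical."},
    {"id": "G6PDH", "substrates": [["G6P", 6]], "products": [["6PG", 6]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5],[6,6]]},
    {"id": "6PGD", "substrates": [["6PG", 6]], "products": [["Ru5P", 5], ["CO2", 1]],
     "map": [[1,6],[2,1],[3,2],[4,3],[5,4],[6,5]],
     "comment": "Oxidative decarboxylation releasing glucose C1."},
    {"id": "RPI", "substrates": [["Ru5P", 5]], "products": [["R5P", 5]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5]]},
    {"id": "RPE", "substrates": [["Ru5P", 5]], "products": [["X5P", 5]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5]]},
    {"id": "RPE_rev", "substrates": [["X5P", 5]], "products": [["Ru5P", 5]],
     "map": [[1,1],[2,2],[3,3],[4,4],[5,5]]},
    {"id": "TKT1", "substrates": [["X5P", 5], ["R5P", 5]], "products": [["S7P", 7], ["G3P", 3]],
     "map": [[1,1],[2,2],[3,8],[4,9],[5,10],[6,3],[7,4],[8,5],[9,6],[10,7]],
     "comment": "Transketolase: moves the C1-C2 unit of X5P onto R5P."},
    {"id": "TKT1_rev", "substrates": [["S7P", 7], ["G3P", 3]], "products": [["X5P", 5], ["R5P", 5]],
     "map": [[1,1],[2,2],[3,6],[4,7],[5,8],[6,9],[7,10],[8,3],[9,4],[10,5]]},
    {"id": "TAL", "substrates": [["S7P", 7], ["G3P", 3]], "products": [["E4P", 4], ["F6P", 6]],
     "map": [[1,5],[2,6],[3,7],[4,1],[5,2],[6,3],[7,4],[8,8],[9,9],[10,10]],
     "comment": "Transaldolase: moves the C1-C3 unit of S7P onto G3P."},
    {"id": "TAL_rev", "substrates": [["E4P", 4], ["F6P", 6]], "products": [["S7P", 7], ["G3P", 3]],
     "map": [[1,4],[2,5],[3,6],[4,7],[5,1],[6,2],[7,3],[8,8],[9,9],[10,10]]},
    {"id": "TKT2", "substrates": [["X5P", 5], ["E4P", 4]], "products": [["F6P", 6], ["G3P", 3]],
     "map": [[1,1],[2,2],[3,7],[4,8],[5,9],[6,3],[7,4],[8,5],[9,6]],
     "comment": "Transketolase: moves the C1-C2 unit of X5P onto E4P."},
    {"id": "TKT2_rev", "substrates": [["F6P", 6], ["G3P", 3]], "products": [["X5P", 5], ["E4P", 4]],
     "map": [[1,1],[2,2],[3,6],[4,7],[5,8],[6,9],[7,3],[8,4],[9,5]]}
  ]
}
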