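# Default membrane fatty-acid cluster: ten FAs in GC elution order.
# ui_weight: double-bond count used by the unsaturation index.
# pi_weight: oxidizability weight used by the peroxidation index.
cluster:
  - {code: "C16:0",     common_name: "palmitic acid",                 acronym: null,   carbons: 16, double_bonds: 0, family: SFA,     ui_weight: 0, pi_weight: 0.0}
  - {code: "C16:1",     common_name: "palmitoleic acid",              acronym: null,   carbons: 16, double_bonds: 1, family: MUFA,    ui_weight: 1, pi_weight: 0.025}
  - {code: "C18:0",     common_name: "stearic acid",                  acronym: null,   carbons: 18, double_bonds: 0, family: SFA,     ui_weight: 0, pi_weight: 0.0}
  - {code: "9c-C18:1",  common_name: "oleic acid",                    acronym: null,   carbons: 18, double_bonds: 1, family: MUFA,    ui_weight: 1, pi_weight: 0.025}
  - {code: "11c-C18:1", common_name: "cis-vaccenic acid",             acronym: null,   carbons: 18, double_bonds: 1, family: MUFA,    ui_weight: 1, pi_weight: 0.025}
  - {code: "C18:2",     common_name: "linoleic acid",                 acronym: LA,     carbons: 18, double_bonds: 2, family: PUFA_n6, ui_weight: 2, pi_weight: 1.0}
  - {code: "C20:3",     common_name: "dihomo-gamma-linolenic acid",   acronym: DGLA,   carbons: 20, double_bonds: 3, family: PUFA_n6, ui_weight: 3, pi_weight: 2.0}
  - {code: "C20:4",     common_name: "arachidonic acid",              acronym: ARA,    carbons: 20, double_bonds: 4, family: PUFA_n6, ui_weight: 4, pi_weight: 4.0}
  - {code: "C20:5",     common_name: "eicosapentaenoic acid",         acronym: EPA,    carbons: 20, double_bonds: 5, family: PUFA_n3, ui_weight: 5, pi_weight: 6.0}
  - {code: "C22:6",     common_name: "docosahexaenoic acid",          acronym: DHA,    carbons: 22, double_bonds: 6, family: PUFA_n3, ui_weight: 6, pi_weight: 8.0}
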