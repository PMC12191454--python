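{
 "n_reports": 1611,
 "consequent_label": "bradycardia",
 "consequent_count": 209,
 "pair_specs": [
  {"label": "syncope", "kind": "ade", "antecedent_count": 18, "joint_count": 11},
  {"label": "loss of consciousness", "kind": "ade", "antecedent_count": 27, "joint_count": 14},
  {"label": "cardiac arrest", "kind": "ade", "antecedent_count": 119, "joint_count": 44},
  {"label": "hypotension", "kind": "ade", "antecedent_count": 128, "joint_count": 46},
  {"label": "overdose", "kind": "ade", "antecedent_count": 33, "joint_count": 10},
  {"label": "drug interaction", "kind": "ade", "antecedent_count": 61, "joint_count": 17},
  {"label": "product administered to patient of inappropriate age", "kind": "ade", "antecedent_count": 47, "joint_count": 11},
  {"label": "cardio-respiratory arrest", "kind": "ade", "antecedent_count": 43, "joint_count": 10},
  {"label": "respiratory arrest", "kind": "ade", "antecedent_count": 74, "joint_count": 15},
  {"label": "lactated ringer's solution", "kind": "drug", "antecedent_count": 17, "joint_count": 12},
  {"label": "bupivacaine", "kind": "drug", "antecedent_count": 31, "joint_count": 12},
  {"label": "risperidone", "kind": "drug", "antecedent_count": 38, "joint_count": 12},
  {"label": "albuterol", "kind": "drug", "antecedent_count": 52, "joint_count": 13},
  {"label": "potassium chloride", "kind": "drug", "antecedent_count": 68, "joint_count": 14},
  {"label": "haloperidol", "kind": "drug", "antecedent_count": 83, "joint_count": 17},
  {"label": "sevoflurane", "kind": "drug", "antecedent_count": 107, "joint_count": 21}
 ],
 "item_specs": [],
 "background_items": [
  {"label": "ade_001", "kind": "ade", "probability": 0.08},
  {"label": "ade_002", "kind": "ade", "probability": 0.05},
  {"label": "drug_001", "kind": "drug", "probability": 0.06},
  {"label": "drug_002", "kind": "drug", "probability": 0.04}
 ],
 "literature_extra": 1050,
 "cohort_drug": "dexmedetomidine",
 "seed": 7
}
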