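{
  "_comment": "Yes/No contingency tables from a published comparison of model-selection programs (jModelTest2, ModelTest-NG, IQ-TREE) and information criteria (AIC, AICc, BIC). 'truth' tables count exact recovery of the generating model over 88 simulated datasets; 'agreement' tables count datasets where one program's best model was consistent across the three criteria (34 real / 88 simulated datasets).",
  "programs_vs_truth": {
    "rows": ["jModelTest2", "ModelTest-NG", "IQ_TREE"],
    "counts": [[189, 75], [198, 66], [188, 76]]
  },
  "criteria_vs_truth": {
    "rows": ["AIC", "AICc", "BIC"],
    "counts": [[156, 108], [157, 107], [262, 2]]
  },
  "criteria_vs_truth_jmodeltest2": {
    "rows": ["AIC", "AICc", "BIC"],
    "counts": [[50, 38], [51, 37], [88, 0]]
  },
  "criteria_vs_truth_modeltestng": {
    "rows": ["AIC", "AICc", "BIC"],
    "counts": [[55, 33], [55, 33], [88, 0]]
  },
  "criteria_vs_truth_iqtree": {
    "rows": ["AIC", "AICc", "BIC"],
    "counts": [[51, 37], [51, 37], [86, 2]]
  },
  "criteria_agreement_real": {
    "rows": ["jModelTest2", "ModelTest-NG", "IQ_TREE"],
    "counts": [[19, 15], [24, 10], [26, 8]]
  },
  "criteria_agreement_simulated": {
    "rows": ["jModelTest2", "ModelTest-NG", "IQ_TREE"],
    "counts": [[67, 21], [71, 17], [64, 24]]
  }
}
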