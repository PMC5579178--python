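{
  "provenance": "PanCan/Brock full logistic model with spiculation (model 2b), McWilliams et al., N Engl J Med 2013;369:910-919, supplementary appendix. Nodule count enters the published model as the total nodule count per scan centred at 4; this file stores the count of ADDITIONAL nodules, hence count_center = 3.",
  "intercept": -6.7892,
  "beta_age": 0.0287,
  "age_center": 62.0,
  "beta_sex_female": 0.6011,
  "beta_family_history": 0.2961,
  "beta_emphysema": 0.2953,
  "beta_size": -5.3854,
  "size_transform": {
    "name": "power_centered",
    "power": -0.5,
    "center": 1.58113883,
    "scale_mm": 10.0
  },
  "beta_nonsolid": -0.1276,
  "beta_partsolid": 0.377,
  "beta_upper_lobe": 0.6581,
  "beta_count": -0.0824,
  "count_center": 3.0,
  "beta_spiculation": 0.7729
}
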