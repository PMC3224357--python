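# Tissue-weighting scheme used for the anthropomorphic-phantom effective-dose
# assembly: the subset of ICRP-103 factors for the organs actually dosimetered,
# with a four-organ remainder at w = 0.12 on the mean remainder dose.  The
# factors sum to 0.53, not 1.0 (skin, breast, gonads-as-gonads, marrow etc.
# were not measured); see docs/methods.md.
weights:
  brain: 0.01
  colon: 0.12
  esophagus: 0.04
  liver: 0.04
  lung: 0.12
  thymus: 0.04
  thyroid: 0.04
  remainder: 0.12
remainder_members: [pancreas, uterus_testes, kidney, adrenals_gall_bladder]
cc_mSv_per_mGy_cm: 0.015
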