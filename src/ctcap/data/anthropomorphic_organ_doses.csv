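organ,female_measured_mGy,female_measured_sigma_mGy,female_calculated_mGy,female_calculated_sigma_mGy,male_measured_mGy,male_measured_sigma_mGy,male_calculated_mGy,male_calculated_sigma_mGy
adrenals_gall_bladder,26.90,0.03,25,1,27.9,0.4,23,1
brain,0.29,0.02,0.4,0.1,0.7,0.3,0.4,0.1
colon,22.3,0.7,21.1,0.8,28,5,20,0.8
esophagus,25,1,23,1,22.1,0.4,21,1
eye,0.495,0.008,,,0.74,0.08,,
kidney,24.2,0.5,31.5,0.9,24.2,0.8,30.3,0.9
liver,26.0,0.2,29.5,0.3,26.3,0.9,28.1,0.3
lung,27,1,33.9,0.7,24,1,32.4,0.6
pancreas,25.9,0.4,25.1,0.7,28.5,0.2,23.2,0.7
thymus,23.5,0.3,25,5,27.0,0.5,24,5
thyroid,12.3,0.4,24,9,30.2,0.8,24,9
uterus_testes,25.6,0.1,21,4,8,4,0.8,0.4
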