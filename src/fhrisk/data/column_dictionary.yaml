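# Default cohort column dictionary: file column -> patient-record field.
# Edit the left-hand side to match your CSV's headers. Booleans are {0,1},
# categories lowercase tokens, missing values empty cells.
id: id
age: age
sex: sex
bmi: bmi
smoking: smoking
drinking: drinking
ldl_c: ldl_c
hdl_c: hdl_c
tc: tc
tg: tg
lp_a: lp_a
tendon_xanthomata: tendon_xanthomata
arcus_cornealis: arcus_cornealis
chd_onset_age: chd_onset_age
stroke_onset_age: stroke_onset_age
pvd_onset_age: pvd_onset_age
hyperlipemia: hyperlipemia
diabetes: diabetes
hypertension: hypertension
therapy_level: therapy_level
therapy_duration_years: therapy_duration_years
fh_chd_onset_age: fh_chd_onset_age
fh_chd_relative_sex: fh_chd_relative_sex
fh_stroke_onset_age: fh_stroke_onset_age
fh_stroke_relative_sex: fh_stroke_relative_sex
fh_hyperlipemia: fh_hyperlipemia
fh_xanthomata: fh_xanthomata
genetic_test: genetic_test
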