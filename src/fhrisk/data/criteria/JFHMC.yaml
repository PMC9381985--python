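# Japanese FH Management Criteria, adapted. The shipped form requires a
# positive genetic test alongside a clinical finding, so in a cohort where
# genetic testing was not done it cannot flag anyone — the observed
# behaviour that gets it excluded from candidate selection. Two levels.
name: JFHMC
mode: rules
levels: [unlikely, definite]
items:
  - id: dna_mutation
    when: {field: genetic_test, eq: positive}
  - id: high_ldl
    when: {field: ldl_untreated, ge: 4.7}
  - id: xanthomata
    when: {field: tendon_xanthomata, eq: true}
  - id: fh_premature_chd
    when: {field: pCHD_fh, eq: true}
rules:
  definite:
    all_of:
      - dna_mutation
      - any_of: [high_ldl, xanthomata, fh_premature_chd]
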