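# Simon Broome Register criteria, adapted to this record schema.
# Definite: marked hypercholesterolemia (TC > 7.5 or untreated LDL > 4.9)
# with tendon xanthomata in the patient or a relative, or DNA evidence.
# Possible: the same lipid finding with a family history of premature
# myocardial infarction or of raised cholesterol. Three levels.
name: SBR
mode: rules
levels: [unlikely, possible, definite]
items:
  - id: high_cholesterol
    when:
      any:
        - {field: tc, gt: 7.5}
        - {field: ldl_untreated, gt: 4.9}
  - id: xanthomata_self_or_relative
    when:
      any:
        - {field: tendon_xanthomata, eq: true}
        - {field: fh_xanthomata, eq: true}
  - id: dna_mutation
    when: {field: genetic_test, eq: positive}
  - id: fh_premature_mi
    when: {field: pCHD_fh, eq: true}
  - id: fh_raised_cholesterol
    when: {field: fh_hyperlipemia, eq: true}
rules:
  definite:
    any_of:
      - all_of: [high_cholesterol, xanthomata_self_or_relative]
      - dna_mutation
  possible:
    all_of:
      - high_cholesterol
      - any_of: [fh_premature_mi, fh_raised_cholesterol]
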