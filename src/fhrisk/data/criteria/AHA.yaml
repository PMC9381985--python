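# American Heart Association definitions, adapted. Definite (homozygous
# range): untreated LDL >= 10 mmol/L, or >= 4.9 with a confirmed mutation.
# Probable (heterozygous): untreated LDL >= 4.9 with a first-degree family
# history of premature CHD or hypercholesterolemia. Three levels.
name: AHA
mode: rules
levels: [unlikely, probable, definite]
items:
  - id: ldl_very_high
    when: {field: ldl_untreated, ge: 10.0}
  - id: ldl_high
    when: {field: ldl_untreated, ge: 4.9}
  - id: dna_mutation
    when: {field: genetic_test, eq: positive}
  - id: family_history
    when:
      any:
        - {field: pCHD_fh, eq: true}
        - {field: fh_hyperlipemia, eq: true}
rules:
  definite:
    any_of:
      - ldl_very_high
      - all_of: [ldl_high, dna_mutation]
  probable:
    all_of: [ldl_high, family_history]
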