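# Simplified Chinese Criteria for FH, adapted. Probable: untreated
# LDL >= 4.7 mmol/L alone. Definite: any 2 of {the LDL finding, xanthomata
# or premature arcus, family history of premature CHD / hypercholesterolemia},
# or a confirmed mutation. Three levels.
name: SCCFH
mode: rules
levels: [unlikely, probable, definite]
items:
  - id: high_ldl
    when: {field: ldl_untreated, ge: 4.7}
  - id: physical_signs
    when:
      any:
        - {field: tendon_xanthomata, eq: true}
        - all:
            - {field: arcus_cornealis, eq: true}
            - {field: age, lt: 45}
  - id: family_history
    when:
      any:
        - {field: pCHD_fh, eq: true}
        - {field: fh_hyperlipemia, eq: true}
  - id: dna_mutation
    when: {field: genetic_test, eq: positive}
rules:
  definite:
    any_of:
      - any_k:
          k: 2
          of: [high_ldl, physical_signs, family_history]
      - dna_mutation
  probable:
    any_of: [high_ldl]
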