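# 2018 Chinese expert-consensus criteria, adapted. FH requires untreated
# LDL >= 4.7 mmol/L together with a supporting finding (xanthomata, arcus
# before 45, or a first-degree family history of premature CHD or
# hypercholesterolemia), or a confirmed pathogenic mutation. Two levels.
name: CHC
mode: rules
levels: [unlikely, definite]
items:
  - id: high_ldl
    when: {field: ldl_untreated, ge: 4.7}
  - id: supporting_finding
    when:
      any:
        - {field: tendon_xanthomata, eq: true}
        - all:
            - {field: arcus_cornealis, eq: true}
            - {field: age, lt: 45}
        - {field: pCHD_fh, eq: true}
        - {field: fh_hyperlipemia, eq: true}
  - id: dna_mutation
    when: {field: genetic_test, eq: positive}
rules:
  definite:
    any_of:
      - all_of: [high_ldl, supporting_finding]
      - dna_mutation
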