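# Taiwan FH diagnostic criteria: DLCN point structure and LDL bands
# (possible from LDL 5.0 mmol/L) with the stricter premature-age cutoffs
# (men < 45 y, women < 55 y) for personal and family-history CHD items.
name: TW
mode: points
levels: [unlikely, possible, probable, definite]
level_thresholds:
  unlikely: [null, 2]
  possible: [3, 5]
  probable: [6, 8]
  definite: [9, null]
items:
  - id: fh_premature_chd_tw
    group: family
    points: 1
    when: {field: pCHD_fhTW, eq: true}
  - id: fh_xanthomata
    group: family
    points: 2
    when: {field: fh_xanthomata, eq: true}
  - id: premature_chd_tw
    points: 2
    when: {field: pCHDTW, eq: true}
  - id: premature_cerebral_peripheral
    points: 1
    when:
      any:
        - {field: pStroke, eq: true}
        - {field: pPVD, eq: true}
  - id: tendon_xanthomata
    points: 6
    when: {field: tendon_xanthomata, eq: true}
  - id: arcus_under_45
    points: 4
    when:
      all:
        - {field: arcus_cornealis, eq: true}
        - {field: age, lt: 45}
  - id: ldl_ge_8_5
    group: ldl
    points: 8
    when: {field: ldl_untreated, ge: 8.5}
  - id: ldl_6_5_to_8_4
    group: ldl
    points: 5
    when: {field: ldl_untreated, ge: 6.5, lt: 8.5}
  - id: ldl_5_0_to_6_4
    group: ldl
    points: 3
    when: {field: ldl_untreated, ge: 5.0, lt: 6.5}
  - id: ldl_4_0_to_4_9
    group: ldl
    points: 1
    when: {field: ldl_untreated, ge: 4.0, lt: 5.0}
  - id: dna_mutation
    points: 8
    when: {field: genetic_test, eq: positive}
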