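# DLCN modified for mainland China: identical structure to DLCN, with the
# untreated-LDL bands shifted down — the 8-point band starts at 6.0 mmol/L
# (vs 8.5 in DLCN) and 3 points (-> possible) start at 3.5 mmol/L.
name: MDLCN
mode: points
levels: [unlikely, possible, probable, definite]
level_thresholds:
  unlikely: [null, 2]
  possible: [3, 5]
  probable: [6, 8]
  definite: [9, null]
items:
  - id: fh_premature_chd
    group: family
    points: 1
    when: {field: pCHD_fh, eq: true}
  - id: fh_xanthomata
    group: family
    points: 2
    when: {field: fh_xanthomata, eq: true}
  - id: premature_chd
    points: 2
    when: {field: pCHD, eq: true}
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
  - id: ldl_ge_6_0
    group: ldl
    points: 8
    when: {field: ldl_untreated, ge: 6.0}
  - id: ldl_4_5_to_5_9
    group: ldl
    points: 5
    when: {field: ldl_untreated, ge: 4.5, lt: 6.0}
  - id: ldl_3_5_to_4_4
    group: ldl
    points: 3
    when: {field: ldl_untreated, ge: 3.5, lt: 4.5}
  - id: ldl_2_5_to_3_4
    group: ldl
    points: 1
    when: {field: ldl_untreated, ge: 2.5, lt: 3.5}
  - id: dna_mutation
    points: 8
    when: {field: genetic_test, eq: positive}
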