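# Make Early Diagnosis to Prevent Early Deaths: age-banded total-cholesterol
# cutoffs, lower when a first-degree relative has known hypercholesterolemia
# (fh_hyperlipemia / fh_xanthomata stand in for a diagnosed relative).
# Two levels.
name: MEDPED
mode: rules
levels: [unlikely, definite]
items:
  - id: general_tc_under_30
    when:
      all:
        - {field: age, lt: 30}
        - {field: tc, ge: 7.5}
  - id: general_tc_30_39
    when:
      all:
        - {field: age, ge: 30, lt: 40}
        - {field: tc, ge: 8.8}
  - id: general_tc_40_plus
    when:
      all:
        - {field: age, ge: 40}
        - {field: tc, ge: 9.3}
  - id: relative_tc_under_30
    when:
      all:
        - {field: age, lt: 30}
        - {field: tc, ge: 5.9}
        - any:
            - {field: fh_hyperlipemia, eq: true}
            - {field: fh_xanthomata, eq: true}
  - id: relative_tc_30_39
    when:
      all:
        - {field: age, ge: 30, lt: 40}
        - {field: tc, ge: 6.2}
        - any:
            - {field: fh_hyperlipemia, eq: true}
            - {field: fh_xanthomata, eq: true}
  - id: relative_tc_40_plus
    when:
      all:
        - {field: age, ge: 40}
        - {field: tc, ge: 6.7}
        - any:
            - {field: fh_hyperlipemia, eq: true}
            - {field: fh_xanthomata, eq: true}
rules:
  definite:
    any_of:
      - general_tc_under_30
      - general_tc_30_39
      - general_tc_40_plus
      - relative_tc_under_30
      - relative_tc_30_39
      - relative_tc_40_plus
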