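# Laboratory-only screen: risky on untreated LDL-C or total cholesterol
# alone, no physical findings or histories. Two levels.
name: LDLC_TC
mode: rules
levels: [unlikely, risky]
items:
  - id: high_ldl
    when: {field: ldl_untreated, ge: 4.0}
  - id: high_tc
    when: {field: tc, ge: 6.0}
rules:
  risky:
    any_of: [high_ldl, high_tc]
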