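# Parent selection: high / high-intermediate / intermediate amylose,
# yield >= 3.5 mt/ha, maturity <= 125 days, complete or moderate blast resistance.
missing_policy: exclude
criteria:
  - trait: amylose
    op: in
    values: [high, high_intermediate, intermediate]
  - trait: yield
    op: ge
    value: 3.5
  - trait: maturity_yala
    op: le
    value: 125
  - trait: blast
    op: in
    values: [R, MR]
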