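# Parent selection: white pericarp, yield >= 3.5 mt/ha, complete or moderate
# BPH resistance, maturity <= 125 days. Grain shape is displayed, not filtered.
# Criteria are listed in breeder priority order (reporting order only).
missing_policy: exclude
criteria:
  - trait: pericarp_color
    op: in
    values: [white]
  - trait: yield
    op: ge
    value: 3.5
  - trait: bph
    op: in
    values: [R, MR]
  - trait: maturity_yala
    op: le
    value: 125
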