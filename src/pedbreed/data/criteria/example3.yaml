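# Parent selection by availability of phosphorus-deficiency-tolerance (PDT)
# ranks: the subpopulation is every cultivar with a recorded PDT class; the
# other traits are displayed over the same set, not filtered on.
missing_policy: exclude
criteria:
  - trait: pdt
    op: in
    values: [high, moderate, sensitive]
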