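# Human PDI domain table, translation-product numbering (signal peptide
# included; mature numbering = these values - 17).  Ranges follow the
# abb'xa' architecture; the c-tail is absent from the crystallised fragment.
convention: translation-product
offset: 17
domains:
  a: [18, 134]
  b: [135, 239]
  bp: [240, 345]
  x: [346, 365]
  ap: [366, 479]
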