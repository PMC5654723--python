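# Yeast (S. cerevisiae) PDI domain table in the residue numbering of the
# 2B5E crystal structure.  Boundaries are approximate trx-fold limits;
# the acidic c-tail follows the a' domain.
convention: mature
offset: 0
domains:
  a: [25, 135]
  b: [136, 235]
  bp: [236, 347]
  x: [348, 357]
  ap: [358, 475]
  c: [476, 522]
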