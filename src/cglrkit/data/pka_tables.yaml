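# Named pKa tables for Henderson-Hasselbalch net-charge / pI calculation.
# Side-chain signs: D, E, C, Y deprotonate to negative; H, K, R protonate to
# positive; the N-terminus is positive and the C-terminus negative.
#
# "emboss" is the default shipped table (values of the EMBOSS iep program,
# Rice et al. 2000). pI depends on the table chosen; alternative tables may
# be added here and selected by name.
default: emboss
tables:
  emboss:
    version: "EMBOSS-6.x"
    n_terminus: 8.6
    c_terminus: 3.6
    side_chains:
      D: {pka: 3.9, sign: "-"}
      E: {pka: 4.1, sign: "-"}
      C: {pka: 8.5, sign: "-"}
      Y: {pka: 10.1, sign: "-"}
      H: {pka: 6.5, sign: "+"}
      K: {pka: 10.8, sign: "+"}
      R: {pka: 12.5, sign: "+"}
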