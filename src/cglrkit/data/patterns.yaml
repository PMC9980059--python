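# Default motif grammar for cGLR curation.
#
# classes: named residue classes usable as single lowercase letters inside
#   pattern strings. "h" is the hydrophobic class (Kyte-Doolittle-positive
#   set commonly used in motif curation); it is configurable here.
# patterns: the three curation motifs. Spacer tokens [Xm-n] bound the number
#   of residues strictly between the flanking anchors (inclusive).
classes:
  h: "ACFILMVWY"
patterns:
  active_site: "h[QT]GS[X8-20][DE]h[DE]h[X50-90]h[DE]h"
  activation_loop: "G[SG]"
  catalytic_triad: "[ED]h[ED][X50-90][ED]"
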