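# Pinned atomic constants for molecular-mass arithmetic.
# average: IUPAC 2021 standard atomic weights (conventional values).
# monoisotopic: AME2020 principal-isotope masses.
# Pinning these here makes 2-decimal agreement with printed molecular
# weights reproducible across environments.
version: "IUPAC-2021/AME2020"
average:
  H: 1.008
  C: 12.011
  N: 14.007
  O: 15.999
  P: 30.973761998
  Na: 22.98976928
monoisotopic:
  H: 1.00782503207
  C: 12.0
  N: 14.0030740048
  O: 15.9949146196
  P: 30.97376163
  Na: 22.9897692809
particles:
  proton: 1.007276466621
  electron: 0.000548579909
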