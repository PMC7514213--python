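# Three-state nutrient environment with two specialist phenotypes.
#
# s1y / s2y are nutrient-A- and nutrient-B-rich environments; s3y is a
# nutrient-poor environment visited occasionally.  Phenotypes s1x / s2x are
# specialists for s1y / s2y.  Tables are row-stochastic: the row key is the
# conditioning state and the columns give the outgoing distribution (the
# transpose of the column-stochastic orientation often used in print).
spaces:
  phenotypes: [s1x, s2x]
  environments: [s1y, s2y, s3y]
  signals: [s1z, s2z]

environment:
  transition:
    s1y: {s1y: 0.70, s2y: 0.25, s3y: 0.05}
    s2y: {s1y: 0.25, s2y: 0.70, s3y: 0.05}
    s3y: {s1y: 0.25, s2y: 0.25, s3y: 0.50}
  initial: stationary            # (5/11, 5/11, 1/11)

sensing:
  memoryless: true
  kernel:                        # TS(z'|y'); rows keyed by the new environment
    s1y: {s1z: 0.8, s2z: 0.2}
    s2y: {s1z: 0.2, s2z: 0.8}
    s3y: {s1z: 0.5, s2z: 0.5}
  initial: from_kernel

switching:
  memoryless: true
  kernel:                        # TF(x'|z'); rows keyed by the new signal
    s1z: {s1x: 0.95, s2x: 0.05}
    s2z: {s1x: 0.05, s2x: 0.95}
  initial: from_kernel

replication:
  rates_are_exponentiated: true  # table entries are e^{k(x,y)}
  table:
    s1x: {s1y: 2.24, s2y: 0.32, s3y: 0.08}
    s2x: {s1y: 0.32, s2y: 2.24, s3y: 0.08}

decomposition:
  # e^{kmax} is pinned in the nutrient-poor state; the remaining entries are
  # then forced to e^{kmax(s1y)} = e^{kmax(s2y)} = 5.12 and TK(s3y|.) = 0.5.
  pin: {s3y: 0.16}
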