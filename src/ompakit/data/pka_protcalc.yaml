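# Side-chain and terminal pKa values, Protein Calculator-style set.
# The tool the study used is named but its constants are not printed, so the
# set is data and swappable.
name: protcalc-style
acidic:   # deprotonated form carries -1
  D: 4.05
  E: 4.45
  C: 9.0
  Y: 10.0
basic:    # protonated form carries +1
  H: 5.98
  K: 10.0
  R: 12.0
n_terminus: 8.0
c_terminus: 3.1
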