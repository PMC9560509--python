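# OmpA allele classification scheme.
#
# N-terminal domain patterns I-VII are defined by the residues at one variant
# site in each of the four surface loops; loop 3 is a residue run whose length
# itself varies (7 residues in I/IV/VI/VII, 8 in II/III/V). C-terminal domain
# patterns alpha-delta are defined by single residues at mature positions
# 175, 203 and 251. alpha is the K-12 reference; delta differs from alpha at
# exactly 203 and 251.
#
# Residue identities at sites the running text does not anchor were fixed once
# for this package (see docs/methods.md) and are versioned here as data.
name: ompa-allele-scheme
version: "1.0"
provenance: >
  Transcription of the published OmpA allele naming convention for E. coli
  (N-terminal patterns I-VII over loops 1-4; C-terminal patterns
  alpha/beta/gamma/delta over mature positions 175/203/251), completed with
  package-chosen residues where the text anchors only the pattern structure.

nterm_sites:
  loop1: {start: 25,  end: 25}
  loop2: {start: 66,  end: 68}
  loop3: {start: 105, end: 111, variable_length: true}
  loop4: {start: 147, end: 147}

cterm_sites: [175, 203, 251]

nterm_patterns:
  I:   {loop1: N, loop2: SVE, loop3: DTKSNVY,  loop4: I}
  II:  {loop1: G, loop2: DNI, loop3: DTKSGNVY, loop4: V}
  III: {loop1: S, loop2: DNI, loop3: DTKSGNVY, loop4: V}
  IV:  {loop1: N, loop2: SVE, loop3: DTKSNVY,  loop4: L}
  V:   {loop1: D, loop2: SVE, loop3: DTKSGNVY, loop4: I}
  VI:  {loop1: D, loop2: DNI, loop3: DTKSNVY,  loop4: V}
  VII: {loop1: D, loop2: SVE, loop3: DTKSNVY,  loop4: L}

cterm_patterns:
  alpha: {"175": A, "203": N, "251": G}
  beta:  {"175": A, "203": T, "251": G}
  gamma: {"175": T, "203": T, "251": G}
  delta: {"175": A, "203": T, "251": D}
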