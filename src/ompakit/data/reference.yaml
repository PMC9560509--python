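# K-12 MG1655 OmpA reference geometry, mature 1-based coordinates.
# The mature chain is 325 residues after removal of the 21-residue signal
# peptide. Loop boundaries are approximate (the source literature does not fix
# them to the residue); they are data, so recalibration never touches code.
signal_peptide_length: 21
mature_length: 325

# Positions where allelic variation is catalogued. 175/203/251 define the
# C-terminal domain patterns; 93/129/161 fall in transmembrane strands and are
# recorded but excluded from the classification.
classification_positions:
  - {position: 175, classifying: true}
  - {position: 203, classifying: true}
  - {position: 251, classifying: true}
  - {position: 93,  classifying: false}
  - {position: 129, classifying: false}
  - {position: 161, classifying: false}

segments:
  # N-terminal beta-barrel: four surface loops (8-strand model) and strands.
  - {name: tm1,   start: 1,   end: 15,  surface_exposed: false}
  - {name: loop1, start: 16,  end: 32,  surface_exposed: true}
  - {name: tm2,   start: 33,  end: 45,  surface_exposed: false}
  - {name: tm3,   start: 46,  end: 56,  surface_exposed: false}
  - {name: loop2, start: 57,  end: 74,  surface_exposed: true}
  - {name: tm4,   start: 75,  end: 87,  surface_exposed: false}
  - {name: tm5,   start: 88,  end: 99,  surface_exposed: false}
  - {name: loop3, start: 100, end: 118, surface_exposed: true}
  - {name: tm6,   start: 119, end: 130, surface_exposed: false}
  - {name: tm7,   start: 131, end: 139, surface_exposed: false}
  - {name: loop4, start: 140, end: 155, surface_exposed: true}
  - {name: tm8,   start: 156, end: 171, surface_exposed: false}
  # C-terminal domain in the minority 16-strand "large pore" model: four more
  # exposed loops (5-8) and eight strands.
  - {name: tm9,   start: 178, end: 189, surface_exposed: false}
  - {name: loop5, start: 190, end: 200, surface_exposed: true}
  - {name: tm10,  start: 201, end: 210, surface_exposed: false}
  - {name: tm11,  start: 214, end: 224, surface_exposed: false}
  - {name: loop6, start: 225, end: 235, surface_exposed: true}
  - {name: tm12,  start: 236, end: 246, surface_exposed: false}
  - {name: tm13,  start: 247, end: 257, surface_exposed: false}
  - {name: loop7, start: 258, end: 268, surface_exposed: true}
  - {name: tm14,  start: 269, end: 280, surface_exposed: false}
  - {name: tm15,  start: 281, end: 294, surface_exposed: false}
  - {name: loop8, start: 295, end: 305, surface_exposed: true}
  - {name: tm16,  start: 306, end: 318, surface_exposed: false}
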