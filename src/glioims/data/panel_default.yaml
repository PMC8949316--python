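# Default brain lipid panel: 124 sum-composition species over 11 classes.
# Reconstructed from the species reported for human cortex / glioblastoma
# MALDI imaging in the 550-1000 (negative) and 480-1000 (positive) Da ranges.
# Adduct policy: [M-H]- for acidic phospholipids and sulfatides, [M+H]+ for
# choline lipids, glycerolipids and neutral sphingolipids.
classes:
  PE:
    adduct: "[M-H]-"
    species: ["32:0", "34:0", "34:1", "34:2", "36:1", "36:2", "36:3", "36:4",
              "38:1", "38:2", "38:4", "38:5", "38:6", "40:4", "40:5", "40:6"]
  PE P-:
    adduct: "[M-H]-"
    species: ["32:1", "34:1", "34:2", "36:1", "36:2", "36:4", "38:1", "38:4",
              "38:5", "38:6", "40:4", "40:5", "40:6", "40:7"]
  PI:
    adduct: "[M-H]-"
    species: ["34:1", "34:2", "36:1", "36:2", "36:4", "38:3", "38:4", "38:5",
              "38:6", "40:4", "40:5", "40:6"]
  PS:
    adduct: "[M-H]-"
    species: ["34:1", "36:1", "36:2", "36:4", "38:1", "38:4", "40:4", "40:5",
              "40:6", "42:6"]
  PG:
    adduct: "[M-H]-"
    species: ["34:0", "34:1", "36:1", "36:2", "36:4", "38:4", "38:5", "40:6"]
  Sulf:
    adduct: "[M-H]-"
    species: ["d34:1", "d36:2", "d36:3", "d36:4", "d38:1", "d38:2", "d40:1",
              "d42:1", "d42:2", "d42:3", "d44:2", "t40:1", "t42:1", "t42:2"]
  PC:
    adduct: "[M+H]+"
    species: ["30:0", "32:0", "32:1", "34:0", "34:1", "34:2", "36:1", "36:2",
              "36:3", "36:4", "36:5", "38:2", "38:3", "38:4", "38:5", "38:6",
              "40:4", "40:5", "40:6", "40:7"]
  SM:
    adduct: "[M+H]+"
    species: ["d34:1", "d34:2", "d36:1", "d36:2", "d38:1", "d38:2", "d40:1",
              "d42:1", "d42:2", "d42:3", "d44:1", "d44:2"]
  HexCer:
    adduct: "[M+H]+"
    species: ["d34:1", "d36:1", "d38:1", "d40:1", "d42:1", "d42:2", "d44:2",
              "t42:1"]
  DG:
    adduct: "[M+H]+"
    species: ["34:1", "36:1", "36:2", "38:4"]
  TG:
    adduct: "[M+H]+"
    species: ["50:1", "52:2", "52:3", "54:3", "54:4", "56:6"]
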