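{
  "bondi": {
    "comment": "Bondi (1964) van der Waals radii in nm, keyed by element symbol.",
    "default": 0.15,
    "radii": {
      "H": 0.12,
      "C": 0.17,
      "N": 0.155,
      "O": 0.152,
      "S": 0.18,
      "P": 0.18,
      "F": 0.147
    }
  },
  "martini-cg": {
    "comment": "Coarse-grained bead radius: half the Martini LJ sigma of 0.47 nm, applied to every bead regardless of element.",
    "default": 0.235,
    "radii": {}
  }
}
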