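# Family scaffold template registry (synthetic exemplar registry bundled alongside).
EGF-like:
  connectivity: []
  notes: EGF-fold toxins (Gigantoxin-I-like)
  pattern: C-C-C-CXC-C
ICK:
  connectivity: []
  notes: inhibitor cystine-knot; 8 Cys
  pattern: C-C-CC-C-C-C-C
Kunitz-type:
  connectivity:
  - - 1
    - 6
  - - 3
    - 5
  - - 2
    - 4
  notes: protease-inhibitor fold, Kv/TRPV blockers
  pattern: C-C-C-C-CX3C
ShKT:
  connectivity:
  - - 1
    - 6
  - - 2
    - 4
  - - 3
    - 5
  notes: ShK-like Kv-channel blockers; 6 Cys, 3 disulfides
  pattern: C-C-C-CX3CX2C
beta-defensin:
  connectivity:
  - - 1
    - 5
  - - 2
    - 4
  - - 3
    - 6
  notes: defensin-fold Nav/Kv/ASIC toxins
  pattern: CXC-C-C-CC
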