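# Tandem cAMP-binding domain boundaries and conserved sub-regions of PKA
# RIalpha, author numbering of the 91-379 construct.  The two domains overlap
# at 244-268: the N3A motif of CBD-B also caps CBD-A (it carries W260).
CBD-A:
  range: [119, 268]
  subregions:
    N3A: [119, 150]
    beta2-3: [163, 171]
    BBR: [180, 193]
    PBC: [199, 211]
    hinge: [226, 251]
CBD-B:
  range: [244, 379]
  subregions:
    N3A: [244, 268]
    beta2-3: [281, 289]
    BBR: [298, 316]
    PBC: [323, 335]
    hinge: [350, 370]
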