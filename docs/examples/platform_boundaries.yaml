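# Structural feature boundaries for an MHC/MHC-like platform-domain alignment.
# Intervals are 0-based half-open [start, end) in alignment coordinates, in
# N- to C-terminal order; names must begin with "strand" or "helix".  Obtain
# the coordinates from a structure or a secondary-structure prediction of one
# representative sequence per class, mapped into the alignment.
features:
  - {name: strand_1, start: 0, end: 25}
  - {name: strand_2, start: 30, end: 55}
  - {name: helix_1, start: 60, end: 100}
  - {name: helix_2, start: 110, end: 150}
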