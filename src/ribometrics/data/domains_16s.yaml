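# 16S rRNA rigid-domain boundaries, by numbering scheme.
#
# Ecoli-16S: head = 3'-major domain, residues 930-1390 (E. coli numbering);
# body = the remainder of 16S.
#
# Sac-16S: the same boundaries ported to Sulfolobus acidocaldarius numbering
# with piecewise constant offsets anchored on conserved landmarks:
#   Sac G1307 <-> E. coli G1338  (offset -31, applies 3' of the head junction)
#   Sac G496  <-> E. coli G530   (offset -34, applies to the 5'/central body)
# These boundaries are versioned data, not code constants; edit here to use
# different domain definitions.
schemes:
  Ecoli-16S:
    head:
      residue_ranges: [[930, 1390]]
    body:
      residue_ranges: [[1, 929], [1391, 1542]]
  Sac-16S:
    head:
      residue_ranges: [[899, 1359]]
    body:
      residue_ranges: [[1, 898], [1360, 1494]]
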