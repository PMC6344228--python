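# Default kinase element maps, author numbering, inclusive ranges.
#
# Lobe split: N-lobe = chain start to the residue before the hinge; hinge =
# 81-84 (anchored on the E81/L83 hinge hydrogen-bonding residues); C-lobe =
# after the hinge to the chain end.  P loop and activation segment follow
# the CDK1 definitions (11-17 and 146-173); CDK2 equivalents are shifted by
# the one-residue offset that appears between the hinge and the catalytic
# loop (CDK2 DFG = D145, activation-loop glutamate E162).
#
# Spine assignments follow the standard protein-kinase hydrophobic-spine
# scheme: R-spine = beta4 leucine, C-helix leucine (L55), DFG phenylalanine,
# catalytic-loop HRD histidine; C-spine = the beta2/beta3 adenine-sandwich
# pair (V18/A31), the beta7 triplet around the C-lobe adenine cap
# (CDK2 L133-I135; CDK1 L134-I136), and the alpha-F anchor methionine.
#
# beta_sheet_base approximates the part of the beta1-5 sheet that faces the
# C-lobe across the catalytic cleft (beta1 base plus beta4-beta5 including
# the gatekeeper).  The exact spans of the "extended hinge" and the sheet
# base are calibration choices and may be overridden per analysis.
CDK1:
  n_lobe: [[1, 80]]
  hinge: [[81, 84]]
  c_lobe: [[85, 297]]
  p_loop: [[11, 17]]
  c_helix: [[46, 56]]
  activation_segment: [[146, 173]]
  beta_sheet_base: [[4, 12], [66, 80]]
  r_spine_residues: [66, 55, 147, 126]
  c_spine_residues: [18, 31, 134, 135, 136, 197]
  gatekeeper: 80
  ploop_tyrosine: 15
  activation_glutamate: 163
CDK2:
  n_lobe: [[1, 80]]
  hinge: [[81, 84]]
  c_lobe: [[85, 298]]
  p_loop: [[11, 17]]
  c_helix: [[46, 56]]
  activation_segment: [[145, 172]]
  beta_sheet_base: [[4, 12], [66, 80]]
  r_spine_residues: [66, 55, 146, 125]
  c_spine_residues: [18, 31, 133, 134, 135, 196]
  gatekeeper: 80
  ploop_tyrosine: 15
  activation_glutamate: 162
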