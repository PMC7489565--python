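{
 "name": "tetromadurin retrobiosynthetic decomposition",
 "provenance": "from_target",
 "notes": "Linear free-acid intermediate read back from the final metabolite: starter propionate plus 14 extensions, positions numbered in assembly order (position 1 extends the starter; position 14 carries the carboxy/tetronate end). Carbon numbering runs from the tetronate-proximal end, so position i has carbonyl carbon C(29-2i). Reduction states: full saturation at C27/C23/C15/C9 (positions 2, 4, 8, 11), hydroxyls at C21/C17/C7 (positions 5, 7, 12, all D), alpha-beta double bonds from positions 1, 3, 6, 9, 10, 13, and the C3 ketone from position 14. Double-bond positions are recorded at the alpha-beta locus of the forming module; migrated placements in the mature rings are a tailoring-level feature outside this positional model. The glycerate-derived tetronate carbons (C39-C41) and the position-13 methoxy carbon (C42) enter via the tailoring pathway and the extender side group, respectively.",
 "starter": {"position": "LM", "extender": "propionate"},
 "extensions": [
  {"position": "1", "extender": "propionate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "methyl", "alpha_stereo": "none"},
  {"position": "2", "extender": "acetate", "beta_state": "methylene", "beta_stereo": "none", "alpha_substituent": "none", "alpha_stereo": "none"},
  {"position": "3", "extender": "acetate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "none", "alpha_stereo": "none"},
  {"position": "4", "extender": "propionate", "beta_state": "methylene", "beta_stereo": "none", "alpha_substituent": "methyl", "alpha_stereo": "D"},
  {"position": "5", "extender": "acetate", "beta_state": "hydroxyl", "beta_stereo": "D", "alpha_substituent": "none", "alpha_stereo": "none"},
  {"position": "6", "extender": "propionate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "methyl", "alpha_stereo": "none"},
  {"position": "7", "extender": "propionate", "beta_state": "hydroxyl", "beta_stereo": "D", "alpha_substituent": "methyl", "alpha_stereo": "D"},
  {"position": "8", "extender": "acetate", "beta_state": "methylene", "beta_stereo": "none", "alpha_substituent": "none", "alpha_stereo": "none"},
  {"position": "9", "extender": "acetate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "none", "alpha_stereo": "none"},
  {"position": "10", "extender": "propionate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "methyl", "alpha_stereo": "none"},
  {"position": "11", "extender": "propionate", "beta_state": "methylene", "beta_stereo": "none", "alpha_substituent": "methyl", "alpha_stereo": "D"},
  {"position": "12", "extender": "propionate", "beta_state": "hydroxyl", "beta_stereo": "D", "alpha_substituent": "methyl", "alpha_stereo": "D"},
  {"position": "13", "extender": "methoxymalonate", "beta_state": "enoyl_double_bond", "beta_stereo": "none", "alpha_substituent": "methoxy", "alpha_stereo": "none"},
  {"position": "14", "extender": "acetate", "beta_state": "ketone", "beta_stereo": "none", "alpha_substituent": "none", "alpha_stereo": "none"}
 ]
}
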