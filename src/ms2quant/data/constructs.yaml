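# Consensus binding-site patterns and mutant-construct substitution tables for
# the sog_Distal enhancer reporter series.
#
# Substitution notation: `original` is the wild-type substring (lowercase, as it
# appears in the enhancer); in `replacement`, CAPITALIZED letters are changed
# bases, lowercase letters are unchanged, and "-" deletes the base at that
# position. Replacements are the same length as originals with "-" counted.

patterns:
  SuH: RTGRGAR      # Su(H) consensus
  Run: ACCGCA       # Run core consensus (Runx-derived)
  Run_ext: AACCRCA  # extended Run consensus

constructs:
  sogD_dSuH:
    - original: ttcccacc
      replacement: ttcccGA-
    - original: gtgggaa
      replacement: ACAAgaa
    - original: gtgagag
      replacement: ACAagag
  sogD_drun:
    - original: tgcggtt
      replacement: tAcgAtt
  sogD_dSuH_run:
    - original: ttcccacc
      replacement: ttcccGA-
    - original: gtgggaa
      replacement: ACAAgaa
    - original: gtgcggtt
      replacement: gtAcgAtt
    - original: gtgagag
      replacement: ACAagag
  sogD_add_run:
    - original: cgcggtt
      replacement: Tgcggtt
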