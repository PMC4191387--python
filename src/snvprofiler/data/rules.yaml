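# Tolerated-substitution rules per functional-site category.
#
# Default policy: every replacement of a modified residue disrupts the
# site.  The only built-in tolerance is the N-glycosylation sequon logic
# (handled by the motif evaluator, not listed here): the T<->S exchange at
# the third sequon position preserves the motif, and a non-proline change
# at the X position leaves it intact.  Phospho S<->T is deliberately NOT
# tolerated: phosphoserine and phosphothreonine losses are tallied as
# separate events.
#
# Format (uncomment and extend to relax categories):
# tolerated:
#   Phosphorylation:
#     S: [T]
#     T: [S]
tolerated: {}
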