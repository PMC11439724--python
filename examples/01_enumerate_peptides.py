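"""Enumerate candidate neoantigen peptides for the two MPN driver mutations.

The recurrent CALR exon 9 frameshifts all produce one shared novel C-terminal
tail, so every 8-11-mer window of that tail is a candidate class I neoantigen;
JAK2 V617F is a point substitution, so only windows covering residue 617
qualify.
"""

from immunoedit import (
    calr_context,
    enumerate_class_ii,
    enumerate_neo_terminus,
    enumerate_point_mutation,
    jak2_context,
)

calr = enumerate_neo_terminus(calr_context())          # 8-11-mers of the neo-tail
jak2 = enumerate_point_mutation(jak2_context())        # 8-11-mers covering F617
calr_ii = enumerate_class_ii(calr_context())           # 15-mers for class II input

print(f"CALR neo-terminus ({len(calr_context().sequence)} aa): "
      f"{len(calr)} windows, {len(calr.peptide_strings())} unique peptides")
print(f"JAK2 V617F (full flanks): {len(jak2)} windows")
print(f"CALR 15-mers for class II prediction: {len(calr_ii)} windows")
print(f"example peptides: {calr.peptide_strings()[8]}, {jak2.peptide_strings()[4]}")

# The window counts are the sizes of the candidate neoantigen search space
# submitted to a binding predictor: 142 class I candidates for CALRmut and 38
# for JAK2 V617F.
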