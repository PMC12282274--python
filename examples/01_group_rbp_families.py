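"""Classify synthetic RBP head domains into groups and subgroups.

Generates three head-domain families (one split into two subgroups) plus
one orphan sequence, builds the all-vs-all identity matrix, applies the
50/90 group rule and the 65% subgroup rule, and prints the assignment next
to the generating truth labels.
"""

import rbprofiler as rp

spec = rp.FamilySpec(
    n_groups=3, members_per_group=5, subgroup_plan={0: [3, 3]}, n_ungrouped=1, seed=11
)
seqs, truth = rp.simulate_rbp_families(spec)
heads = rp.heads_from_sequences(seqs, head_length=110)
matrix = rp.build_identity_matrix(heads)
assignment = rp.assign_groups(matrix, rp.GroupingThresholds())

print(truth.assign(assigned=[assignment.label(i) for i in truth.sequence_id]).to_string(index=False))
print()
print(rp.summarize_groups(assignment, matrix).round(2).to_string())
print()
print(
    "Each row maps a sequence to its inferred group (roman numeral, with a"
    " subgroup letter where a group splits at the 65% floor); the summary"
    " shows group sizes and the within-group identity band, which for"
    " undivided groups sits in the simulated 85-95% range."
)
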