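"""Single-linkage versus greedy-centroid homology clustering on deep
families.

Thirty ortholog families are evolved along the deep_chain12 caterpillar:
adjacent tips stay alignable (~84% identity) while the most distant tips
diverge to ~48% identity over a 0.9-substitutions/site path. Transitive
single-linkage clustering can walk the chain of intermediate relatives;
the greedy centroid method must compare every sequence to a single
centroid and is order dependent, so deep families fragment or absorb
wrong members. Efficiency counts a family as recovered only if all its
members are gathered in one cluster with nothing else.
"""

from radphy import deep_family_comparison

table = deep_family_comparison(n_families=30, tag_len=85, seed=1)
print(table.to_string(index=False))
print(
    "\nAt the permissive 35% threshold single-linkage recovers most"
    "\nfamilies while the greedy baseline recovers almost none; at a 90%"
    "\nthreshold both collapse -- permissive thresholds are essential for"
    "\ndeep-divergence clustering."
)
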