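"""Restriction-site conservation versus divergence.

Evolves one 4-Mb genome into pairs of lineages at increasing per-site
substitution probability p and counts how many Sbf1 sites survive in both,
against the independent-sites prediction (1-p)^16: the usable locus set
shrinks rapidly with divergence.
"""

import math

import dendropy

from radphy import (
    conservation_curve,
    evolve_along_tree,
    expected_site_conservation,
    generate_ancestor,
)

anc = generate_ancestor(4_000_000, 0.5, seed=7)
print("p/lineage\tobserved\texpected (1-p)^16\tn_sites")
for p in (0.01, 0.02, 0.05, 0.1, 0.2):
    d = -0.75 * math.log(1 - 4 * p / 3)  # JC branch length realizing p
    tree = dendropy.Tree.get(data=f"(x:{d},y:{d});", schema="newick")
    leaves = evolve_along_tree(anc, tree, seed=7)
    row = conservation_curve(leaves).iloc[0]
    print(
        f"{p:.2f}\t\t{row['fraction']:.3f}\t\t{expected_site_conservation(p):.3f}"
        f"\t\t\t{row['n_sites_ref']}"
    )
print(
    "\nAt p=0.05 per lineage roughly 44% of sites remain shared; at p=0.2\n"
    "only ~3% do -- the deep-divergence regime where homology detection,\n"
    "not site loss, becomes the limiting factor."
)
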