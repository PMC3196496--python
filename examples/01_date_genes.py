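"""Assign gene origination branches from ortholog presence/absence.

Builds the demo vertebrate tree (13 tips, branches 0..12 with human the
focal species), simulates 500 genes with known origination branches and no
losses, and dates them back from the presence matrix alone.
"""

from genebirth.dating import classify_age, date_catalog
from genebirth.simulate import (DEMO_YOUNG_BRANCHES, SimConfig, demo_tree,
                                gen_presence)

tree = demo_tree()
print(f"focal tip: {tree.focal}; terminal branch index: {tree.n_branches}")
print(f"oldest outgroup clade O_0: {sorted(tree.outgroups[0])}")

config = SimConfig(seed=42, n_genes=500, loss_prob=0.0)
presence, truth = gen_presence(tree, config)
assigned = date_catalog(tree, presence)

exact = (assigned.loc[truth["gene_id"]].to_numpy()
         == truth["true_branch"].to_numpy()).mean()
print(f"\nloss-free recovery: {100 * exact:.1f}% of 500 genes dated exactly")

ages = assigned.map(lambda b: classify_age(b, DEMO_YOUNG_BRANCHES))
print(f"young (primate-specific, branches 8-12): {(ages == 'young').sum()} genes")
print(f"old (predating the primate split):       {(ages == 'old').sum()} genes")
print("\nWith no losses the oldest-outgroup-presence rule inverts the "
      "simulation exactly; losses could only make genes look younger.")
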