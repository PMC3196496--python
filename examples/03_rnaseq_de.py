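"""Mappability-corrected quantification and two-group differential expression.

Simulates transcripts (with paralogs sharing a 40-bp duplicated block),
draws 32-nt error-free reads for a fetal and an adult group, maps them by
exact match discarding multi-gene hits, computes unique-32-mer effective
lengths and RPMK, and calls DE with the binomial likelihood-ratio test at
FDR 0.05.
"""

import pandas as pd

from genebirth.quant import (assign_reads, de_table, effective_length,
                             filter_short_mappable, rpmk)
from genebirth.simulate import (SimConfig, demo_tree, gen_catalog, gen_rnaseq,
                                gen_transcripts)

config = SimConfig(seed=3, n_genes=800, reads_per_group=100_000,
                   prop_de=0.1, de_effect_logfc=2.0)
tree = demo_tree()
catalog, _ = gen_catalog(tree, config)
transcripts, _ = gen_transcripts(catalog, config)
reads, _, truth = gen_rnaseq(catalog, transcripts, config)

lengths = effective_length(transcripts, k=32)
retained, excluded = filter_short_mappable(catalog, lengths, min_bp=30)
print(f"{len(excluded)} duplicated genes excluded for unique mappable "
      f"region < 30 bp ({100 * len(excluded) / len(catalog):.1f}% of genes)")

asg = {g: assign_reads((s for _, s in reads[g]), transcripts, k=32)
       for g in ("fetal", "adult")}
for g, a in asg.items():
    print(f"{g}: {a.total_assigned} reads assigned, {a.n_multi_gene} "
          f"multi-gene reads discarded")

gene = retained[0]
value = rpmk(asg["fetal"].counts[gene], lengths[gene],
             asg["fetal"].total_assigned)
print(f"\nexample RPMK for {gene}: {value:.1f} "
      f"(count {asg['fetal'].counts[gene]}, mappable length {lengths[gene]} bp)")

calls = de_table(asg["fetal"].counts.loc[retained],
                 asg["fetal"].total_assigned,
                 asg["adult"].counts.loc[retained],
                 asg["adult"].total_assigned, labels=("fetal", "adult"))
merged = calls.merge(truth, on="gene_id")
de_true = merged[merged["de_status"]]
recall = (de_true["direction"] != "unbiased").mean()
called = merged[merged["direction"] != "unbiased"]
fdr = (~called["de_status"]).mean() if len(called) else 0.0
print(f"\nDE at q < 0.05: {len(called)} genes called; recall of planted DE "
      f"genes {100 * recall:.0f}%, observed false-discovery {100 * fdr:.1f}%")
print("(the binomial LRT on pooled group counts recovers the planted "
      "e^2-fold expression changes)")
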