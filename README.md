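# genebirth

Tools for asking when genes arose and where in development they act: a
reusable implementation of the analysis that crosses **gene origination age**
(phylostratigraphy from ortholog presence/absence on a species tree) with
**developmental expression bias** (EST presence calls, read-count
differential expression), plus the sequence-evolution layer (Ka/Ks,
McDonald–Kreitman, Poisson-random-field selection intensity) used to ask
whether the young, early-expressed genes evolve under positive selection.
It is aimed at comparative genomicists and evo-devo researchers who want
these bespoke statistics as tested library functions rather than one-off
scripts, with a synthetic-data module that generates every input with known
truth.

## The statistics at the core

**Dollo dating.** On a rooted species tree with focal tip (say, human), the
root-to-focal path defines outgroup clades `O_0 … O_{B-1}` and branches
`0 … B` (0 oldest, `B` the focal terminal branch). A gene present in some
tip of `O_i` must predate that divergence, so its origination branch is
`min{ i : presence in O_i }` (or `B` with no outgroup presence). Losses
can only make genes look younger — the assignment is conservative.

**EST enrichment.** A gene is "expressed" in a tissue when ≥ 2 ESTs from
normal libraries support it. Per tissue, the young-gene share of the
expressed transcriptome is compared between species by a two-sided Fisher's
exact test with Bonferroni correction, with two resampling guards:
bootstrap of the tissue's EST pool (mean ± 2 sd across 100 replicates) and
depth-matched subsampling without replacement (empirical p over 1,000
replicates, ties counted conservatively).

**Mappability-corrected RPMK and the count LRT.** Expression is
`count / (total/10^6) / (L_u/10^3)` where `L_u` is the number of 32-mers
unique to the gene's transcripts; 32-nt reads matching more than one gene
are discarded, and duplication-born genes with `L_u < 30` bp are dropped.
Two pooled groups are contrasted per gene with the binomial generalized
likelihood-ratio test

```
Λ = 2[ ℓ(x₁; N₁, x₁/N₁) + ℓ(x₂; N₂, x₂/N₂) − ℓ(x₁; N₁, p̂₀) − ℓ(x₂; N₂, p̂₀) ],
p̂₀ = (x₁+x₂)/(N₁+N₂),   p = P(χ²₁ > Λ),
```

with Benjamini–Hochberg FDR at 0.05.

**Age × bias inference.** 2×2 Fisher tables of age class × bias direction;
per-branch exact binomial tests of up vs down against 1/2 (Bonferroni over
branches); pooling of neighboring same-age same-bias genes into clusters at
100 kb / 1 Mb cutoffs so a duplication block counts once; feature-proximity
fractions; fold-enrichment arithmetic for annotation terms.

**Selection.** NG86 Ka/Ks with Jukes–Cantor correction and the standard
filters (> 100 codons, ≥ 1 estimated synonymous substitution, ratios
trimmed to 1 for plotting); the MK 2×2 exact test with
`NI = (pn/ps)/(dn/ds)` and `α = 1 − NI`; and a per-gene estimate of the
scaled selection intensity `γ = 2Ns` obtained by inverting the PRF
neutrality-index curve `R(γ) = [L(γ,n)/L(0,n)]/G(γ)` (strictly decreasing,
`G(γ) = 2γ/(1−e^{−2γ})`, `L(0,n)` the Watterson harmonic sum), with a
χ²₁ likelihood-ratio test against neutrality and a positive-selection call
at p < 0.1.

## Worked example

`examples/` has one narrative script per capability. The full pipeline
(`python examples/06_full_pipeline.py`, equivalent to
`genebirth run --seed 1 --out <dir>`) simulates 5,000 genes with a planted
3× young-gene fetal-brain boost, 10% DE genes and MK tables at
γ ∈ {−2, 0, 2, 5}, then prints:

```
                                         analysis                              statistic                  value        p  threshold significant  family_size
 EST young-gene brain enrichment (species a vs b) two-sided FET, Bonferroni over tissues         0.212 vs 0.151 0.017553       0.05        True            6
              age x fetal/adult bias (gene level)                          two-sided FET [[20, 62], [232, 216]] 0.000004       0.05        True            1
  age x bias at cluster level (cutoff 100,000 bp)                          two-sided FET [[20, 62], [219, 212]] 0.000011       0.05        True            1
age x bias at cluster level (cutoff 1,000,000 bp)                          two-sided FET [[20, 61], [194, 186]] 0.000014       0.05        True            1
        positively selected genes (PRF gamma > 0)                      chi-square(1) LRT                     10      NaN       0.10         NaN           20
```

Reading it: 21.2% of genes expressed in the focal species' brain are young
versus 15.1% in the null species — the planted enrichment, significant
after Bonferroni over the six tissues and in no other tissue; among biased
genes, young ones lean fetal (62 fetal vs 20 adult) while old ones split
evenly, at gene and at cluster level for both distance cutoffs; and 10 of
the 20 simulated MK tables — exactly the γ > 0 ones — are flagged as
positively selected. Result TSVs, separate truth files and a sha256
manifest land in the output directory; a rerun with the same seed is
byte-identical.

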