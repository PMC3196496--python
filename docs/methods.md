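# Methods

## Scope and model

The package operationalizes one analysis idea: classify genes by
origination age on a species phylogeny, classify the same genes by
developmental expression bias, and test whether the two classifications are
associated — then ask whether the young, early-biased genes carry
signatures of positive selection. Each layer is a self-contained module
(`dating`, `est`, `quant`, `enrichment`, `selection`) with a generator in
`simulate` that produces its inputs with known truth, and `pipeline` wires
them end to end.

## Gene dating

Dating assumes Dollo parsimony: one origination on the focal lineage,
losses allowed, regain forbidden. Given a rooted tree and focal tip, each
internal node on the root-to-focal path contributes an outgroup clade
`O_i`; the assigned branch is the smallest `i` with presence in `O_i`,
or the terminal branch with no outgroup presence. Consequences worth
keeping in mind:

* The rule is deliberately conservative — a single presence in an old
  clade forces an old age. Under simulated loss the assigned branch is
  always ≥ the true branch (asserted in tests); with loss probability 0 the
  assignment inverts the generator exactly.
* "Absent" and "undetected" are indistinguishable in a presence/absence
  matrix. Upstream detection (syntenic alignment, homology search) is out
  of scope here; the matrix is taken at face value.
* Multifurcations on the focal path make branch indices ambiguous and are
  rejected rather than resolved silently. Multifurcations elsewhere are
  tolerated (they simply enlarge an `O_i`).

Age classes are defined by a configurable young-branch set; the demo tree
has 13 tips and branches 0–12 with {8…12} young, mirroring the standard
human configuration where the terminal branch is species-specific. The
stringent "ancestral subset" extraction (one-to-one orthologs in every
ingroup species, no homolog in any outgroup) is a plain boolean filter on
two flag tables.

## EST profiling

Presence = ≥ `min_ests` (default 2) ESTs from normal-sample libraries in a
(species, tissue) or (species, tissue, stage) cell. Presence is monotone
in the threshold (property-tested). Proportion comparisons use the
two-sided Fisher exact test on the gene-level 2×2 — rows species, columns
(young expressed, old expressed) — because the quantities being compared
are gene counts; Bonferroni m = number of tissue categories in the run.

Resampling choices that the data format does not dictate:

* **Bootstrap unit**: individual ESTs within a (species, tissue) cell,
  resampled with replacement to the original depth (multinomially over
  genes). Resampling libraries or genes instead would be defensible; the
  EST is the elementary sampling event here, so it is the unit.
* **Subsampling control**: equal-size draws without replacement
  (multivariate hypergeometric over the gene-count vector) from each
  species; the empirical p counts replicates where the first species fails
  to exceed the second, with ties counted as failures (the conservative
  direction). A zero count is reported as `p < 1/n_reps`, never as 0.

## Quantification and differential expression

The effective gene length is the number of distinct 32-mers occurring in
the gene's transcripts and in no other gene's (forward strand; duplicates
within a gene count once). The toy mapper assigns an error-free 32-nt read
to a gene iff the read or its reverse complement occurs in exactly one
gene's transcripts; multi-gene and unmatched reads are discarded, and
assigned + discarded = input always. Exact matching is adequate because the
simulated reads are error-free; it stands in for a probabilistic aligner
whose score-difference filtering plays the same role of discarding
ambiguous placements. Duplication-born genes (DNA duplicates, retrogenes)
with < 30 bp of unique sequence are excluded; de novo genes are exempt from
that filter since they have no paralog to confound mapping.

DE uses the binomial two-group generalized LRT on pooled group counts
(x, N per group), `p` from χ²₁, BH FDR at 0.05. The binomial likelihood
was chosen over Poisson because totals are fixed by conditioning and the
two are numerically indistinguishable at realistic depths; the statistic
equals the G-test of the 2×2 table, which the tests assert to 1e-8, and its
type-I error at 0.05 is calibrated within the exact binomial 99% interval
over 10,000 null simulations. Direction is assigned only at q < threshold;
exact rate ties are unbiased. Sample grouping, when needed, is average-
linkage hierarchical clustering on 1 − Pearson distance cut at two
clusters, refusing all-identical profiles.

## Age × bias inference

The 2×2 bias table excludes unbiased genes — the contrast is among genes
that moved, and including the unmoved majority would only dilute both
rows. Branch profiles use the exact two-sided binomial test (sum of
outcome probabilities ≤ observed) with the one-sided p reported alongside;
the Bonferroni family is the branches with a defined test, kept
configurable. Cluster pooling chains coordinate-sorted biased genes on a
chromosome when they share branch and bias and the end-to-start gap (half-
open coordinates, strand ignored) is within the cutoff; overlapping genes
merge; an interleaved gene of different label breaks the chain. The
cluster count is non-increasing in the cutoff and the chaining matches a
union-find oracle on random catalogs. Feature proximity uses nearest-end
distance (0 for overlap) with a strict ≤ cutoff. Term enrichment is plain
fold + one-sided FET + BH; no EASE-style deflation is attempted.

## Selection layer

Ka/Ks is Nei–Gojobori (1986) with Jukes–Cantor correction — a deliberately
desk-scale, oracle-verifiable counting estimator rather than an ML codon
model; externally computed ML values can be imported as TSV for comparison.
Site counting treats mutations to stop codons as nonsynonymous so that
S + N = 3 × codons exactly; pathway averaging over multi-step codon
differences excludes paths through stops unless every path hits one.
Filters: > 100 codons alignable, ≥ 1 estimated synonymous substitution
(Ks·S ≥ 1), correction undefined at p ≥ 3/4; ratios above 1 are
additionally reported trimmed to 1 for plotting.

The PRF model gives expected counts `E[ps] = θ_s L(0,n)`, `E[ds] = θ_s τ`,
`E[pn] = θ_r L(γ,n)`, `E[dn] = θ_r τ G(γ)`. Numerics:

* `L(γ,n)` by adaptive quadrature (tolerance 1e-12); the integrand is
  bounded at both endpoints after cancellation. At γ = 0 the analytic
  limit integrand `(1−q^n−(1−q)^n)/q` is integrated instead, and equals the
  Watterson harmonic sum to 1e-10 (tested, not assumed).
* `G(γ)` via `expm1` with the asymptotic form beyond floating range.
* γ̂ solves `R(γ) = NI_obs` on the strictly decreasing curve
  `R(γ) = [L(γ,n)/L(0,n)]/G(γ)` by Brent root finding, bracket [−30, 30]
  doubled up to [−200, 200] before flagging a boundary. `pn = 0` pins
  γ̂ = +∞ (boundary); zero `ps`, `ds` or `dn` declines estimation with a
  reason rather than pseudocounting.
* The full model is saturated (four Poisson means, four free parameters)
  and the γ = 0 ML fit is the 2×2 independence fit, so the LRT statistic
  equals the G-test of the MK table whenever γ̂ is finite — asserted
  numerically to 1e-6.
* `n_sample` defaults to 40 chromosomes and is configurable; polymorphism
  tables rarely state it.

The per-gene MLE here is an analog of, not a substitute for, hierarchical
Bayesian fits across genes: the shipped 16-gene MK table is therefore
reclassified on its printed score column (five genes at p < 0.1) while the
package's own χ²₁ p accompanies each row as a separate column.

## Synthetic data: what it emulates and what it does not

One global integer seed; each generator draws from a substream derived
from seed + stage name (CRC-folded), so stages rerun independently and a
fixed seed is byte-reproducible. Truth is returned separately and written
under `truth/`; pipeline stages never read it (the manifest is tested for
this).

Default study conditions, chosen once: 13-branch tree with an old-skewed
origination prior (55% branch 0, 30% spread over branches 1–7, 15% young —
the age spectrum real genomes show); 6 tissues × {fetal, adult} × 3
libraries of ~1,000 ESTs with lognormal(σ = 2) expression propensities, so
a sizeable fraction of genes sits near the 2-EST presence threshold as in
real EST collections; young-gene fetal-brain odds multiplier 3 (effect
sizes are not published for this contrast; 3× gives clear signal at the
5,000-gene demo scale without being trivial); 300-nt transcripts with
40 bp shared blocks copied into duplication-born genes from non-duplicated
parents; 32-nt error-free reads, 200,000 per group at demo scale (the
package's standard demo depth; deeper runs only sharpen the same
contrasts); 10% DE genes at e² ≈ 7.4-fold with young genes' fetal-bias
odds tripled; MK tables as independent Poissons under the PRF means at
θ = 100 (demo) or 1,000 (recovery study), τ = 1, n = 40.

Not emulated: sequencing error and quality trimming, intron/isoform
structure, library-composition biases, coalescent sampling of allele
frequencies (Poisson means suffice for MK counts), and between-gene
correlation other than paralog sequence sharing. Passing tests therefore
demonstrate the statistics' correctness and calibration under their own
assumptions, not robustness to real-data artifacts like mapping error or
batch effects.

## Degenerate inputs and tie-breaks

Zero-EST tissues, zero totals, empty table margins, all-zero MK tables and
all-identical sample profiles raise typed errors naming the offense;
undefined NI/α are NaN-flagged, never pseudocounted. Proportion ties in
the subsampling control count against the enriched hypothesis. Cluster
chaining breaks ties in coordinates by gene id for deterministic output
order.

## Known limitations

* Presence/absence dating cannot rescue fast-evolving genes the way
  synteny-aware detection can; the package consumes the matrix it is given.
* The exact-match mapper understands neither mismatches nor gaps; it is a
  stand-in adequate for error-free simulation only.
* The EST Fisher test treats genes as independent; the cluster-pooling
  analysis is the package's own guard against the worst violation
  (tandem duplication blocks), not a full dependence model.
* Per-gene γ̂ is noisy at small counts (the recovery study uses θ = 1,000);
  at realistic per-gene counts only the sign and magnitude class are
  trustworthy, which is why classification, not estimation, is the
  headline output.
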