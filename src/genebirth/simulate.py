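"""Synthetic-data generators with known ground truth for every pipeline stage.

Every generator derives its own deterministic random substream from one
global integer seed plus a stage name, so any stage can be rerun in
isolation and a fixed seed yields byte-identical outputs.  Truth (true
origination branch, true DE status/direction, true selection intensity,
true mappable length) is returned alongside the data and written to
separate files; pipeline code never reads it.

The generators emulate the structure of the real inputs: an ortholog
presence/absence matrix over a vertebrate-style species tree (Dollo: one
origin, optional per-tip loss), per-library EST count tables over
tissue x stage cells with an odds multiplier boosting young genes in the
(brain, fetal) cell, 32-nt error-free RNA-seq reads from transcripts that
may share recently duplicated sequence blocks, Poisson MK count tables
under the PRF means, and codon alignment pairs with exactly placed
synonymous/nonsynonymous differences.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dating import FocalPath
from .selection import fixation_factor, harmonic, sojourn_l

DEMO_NEWICK = (
    "(zebrafish,(frog,(chicken,(platypus,(opossum,(dog,(mouse,(treeshrew,"
    "(marmoset,(rhesus,(gibbon,(chimp,human))))))))))));"
)
#: Origination branches counted as "young" on the demo tree (primate-specific
#: branches 8..12, branch 12 being the focal-species terminal branch).
DEMO_YOUNG_BRANCHES = tuple(range(8, 13))

#: Default per-branch origination probabilities on the demo tree: most genes
#: predate the vertebrate radiation (branch 0), a middle mass spreads over
#: branches 1..7, and ~15% of genes are lineage-specific (branches 8..12) --
#: the old-skewed age spectrum real genomes show.
DEMO_BRANCH_PROBS = (0.55,) + (0.30 / 7,) * 7 + (0.15 / 5,) * 5

TISSUE_POOL = ("brain", "heart", "liver", "kidney", "lung", "muscle",
               "testis", "skin", "gut", "spleen")
MECHANISMS = ("dna_duplicate", "retrogene", "de_novo", "unknown")


class SimulationError(ValueError):
    pass


def demo_tree(focal: str = "human") -> FocalPath:
    """A 13-tip vertebrate-style tree with 13 branches (0 oldest, 12 focal)."""
    return FocalPath.from_newick(DEMO_NEWICK, focal)


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG: global seed + CRC of the stage name."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode()) % 2**31])


@dataclass
class SimConfig:
    """Knobs for the synthetic study; defaults define the demo conditions."""
    seed: int = 0
    n_genes: int = 1000
    branch_origination_probs: tuple[float, ...] | None = None  # None = uniform
    loss_prob: float = 0.0
    young_fetal_enrichment: float = 3.0   # odds multiplier, >= 1
    n_tissues: int = 6
    libraries_per_tissue_stage: int = 3
    mean_library_size: int = 1000
    propensity_sigma: float = 2.0         # lognormal spread of expression propensity
    de_effect_logfc: float = 2.0          # natural-log fold change of true DE genes
    prop_de: float = 0.1
    gamma_values: tuple[float, ...] = (-2.0, 0.0, 2.0, 5.0)
    paralog_shared_bp: int = 40
    transcript_length: int = 300
    read_length: int = 32
    reads_per_group: int = 200_000
    n_sample: int = 40                    # chromosomes behind MK polymorphism counts
    theta_s: float = 100.0
    theta_r: float = 100.0
    tau: float = 1.0

    def __post_init__(self):
        for name in ("n_genes", "n_tissues", "libraries_per_tissue_stage",
                     "mean_library_size", "reads_per_group", "transcript_length"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.young_fetal_enrichment < 1.0:
            raise SimulationError("young_fetal_enrichment must be >= 1")
        if not 0.0 <= self.prop_de <= 1.0:
            raise SimulationError("prop_de must be in [0, 1]")
        if not 0.0 <= self.loss_prob < 1.0:
            raise SimulationError("loss_prob must be in [0, 1)")
        if self.branch_origination_probs is not None:
            probs = np.asarray(self.branch_origination_probs, dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise SimulationError("branch origination probabilities must sum to 1")
            if (probs < 0).any():
                raise SimulationError("branch origination probabilities must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# presence / dating
# ---------------------------------------------------------------------------

def gen_presence(tree: FocalPath, config: SimConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample true origination branches and the implied presence matrix.

    A gene arising on branch b is present in the focal tip and in every
    outgroup clade O_i with i >= b (those lineages diverged after the
    origination); each non-focal presence is independently deleted with
    ``loss_prob`` (Dollo: losses only, no regain).
    Returns (presence matrix genes x species, truth with true_branch).
    """
    rng = substream(config.seed, "presence")
    n_branches = tree.n_branches
    probs = config.branch_origination_probs
    if probs is None:
        if n_branches + 1 == len(DEMO_BRANCH_PROBS):
            probs = np.asarray(DEMO_BRANCH_PROBS)
        else:
            probs = np.full(n_branches + 1, 1.0 / (n_branches + 1))
    else:
        probs = np.asarray(probs, dtype=float)
        if len(probs) != n_branches + 1:
            raise SimulationError(
                f"need {n_branches + 1} branch probabilities, got {len(probs)}"
            )
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    true_branch = rng.choice(n_branches + 1, size=config.n_genes, p=probs)
    species = sorted(tree.tips)
    presence = pd.DataFrame(False, index=pd.Index(gene_ids, name="gene_id"),
                            columns=species)
    presence[tree.focal] = True
    for i, clade in enumerate(tree.outgroups):
        carried = true_branch <= i
        for sp in clade:
            keep = carried & (rng.random(config.n_genes) >= config.loss_prob)
            presence[sp] = keep
    truth = pd.DataFrame({"gene_id": gene_ids, "true_branch": true_branch})
    return presence, truth


def gen_catalog(tree: FocalPath, config: SimConfig,
                young_branches: Sequence[int] = DEMO_YOUNG_BRANCHES,
                n_chromosomes: int = 5, gene_spacing: int = 50_000,
                gene_span: int = 2_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene catalog with coordinates, branch, age class and mechanism.

    Branches come from ``gen_presence`` truth; genes are laid out evenly
    spaced along synthetic chromosomes.  Returns (catalog, presence truth).
    """
    presence, truth = gen_presence(tree, config)
    rng = substream(config.seed, "catalog")
    n = config.n_genes
    chrom = np.array([f"chr{(i % n_chromosomes) + 1}" for i in range(n)])
    pos_index = np.arange(n) // n_chromosomes
    start = pos_index * gene_spacing
    mech = rng.choice(MECHANISMS, size=n, p=[0.45, 0.2, 0.1, 0.25])
    young = set(young_branches)
    catalog = pd.DataFrame({
        "gene_id": truth["gene_id"],
        "chromosome": chrom,
        "start": start,
        "end": start + gene_span,
        "strand": rng.choice(["+", "-"], size=n),
        "branch": truth["true_branch"],
        "age_class": ["young" if b in young else "old" for b in truth["true_branch"]],
        "mechanism": mech,
    })
    return catalog, truth


# ---------------------------------------------------------------------------
# EST tables
# ---------------------------------------------------------------------------

def gen_est_table(catalog: pd.DataFrame, config: SimConfig,
                  species: str = "human") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library multinomial EST draws over genes.

    Each (tissue, stage fetal/adult) cell gets ``libraries_per_tissue_stage``
    libraries with sizes 1 + Poisson(mean - 1) (never zero).  Gene sampling
    weights are a shared heavy-tailed lognormal expression propensity
    (sigma = ``propensity_sigma``), so at the default depth a sizeable
    fraction of genes sits below the presence threshold in any one tissue,
    as in real EST collections; in the (brain, fetal) cell young genes'
    weight is multiplied by ``young_fetal_enrichment``.  Truth records each
    gene's propensity and whether it was boosted.
    """
    rng = substream(config.seed, f"est:{species}")
    if config.n_tissues > len(TISSUE_POOL):
        raise SimulationError(f"at most {len(TISSUE_POOL)} tissues supported")
    tissues = TISSUE_POOL[: config.n_tissues]
    genes = catalog["gene_id"].to_numpy()
    young = (catalog["age_class"] == "young").to_numpy()
    propensity = rng.lognormal(mean=0.0, sigma=config.propensity_sigma, size=len(genes))
    records = []
    for tissue in tissues:
        for stage in ("fetal", "adult"):
            weights = propensity.copy()
            if tissue == "brain" and stage == "fetal" and config.young_fetal_enrichment != 1.0:
                weights[young] *= config.young_fetal_enrichment
            probs = weights / weights.sum()
            for lib in range(config.libraries_per_tissue_stage):
                size = 1 + rng.poisson(max(config.mean_library_size - 1, 0))
                counts = rng.multinomial(size, probs)
                nz = counts.nonzero()[0]
                records.append(pd.DataFrame({
                    "library_id": f"{species}_{tissue}_{stage}_{lib}",
                    "species": species, "tissue": tissue, "stage": stage,
                    "normal_flag": 1, "gene_id": genes[nz],
                    "est_count": counts[nz],
                }))
    est = pd.concat(records, ignore_index=True)
    truth = pd.DataFrame({
        "gene_id": genes, "propensity": propensity,
        "fetal_brain_boosted": young & (config.young_fetal_enrichment != 1.0),
    })
    return est, truth


# ---------------------------------------------------------------------------
# transcripts and RNA-seq reads
# ---------------------------------------------------------------------------

def gen_transcripts(catalog: pd.DataFrame, config: SimConfig
                    ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Random transcript per gene; duplication-born genes copy a parent block.

    Genes with mechanism dna_duplicate or retrogene share an identical
    ``paralog_shared_bp`` block with a randomly chosen partner gene, which
    makes reads from that block multi-map and erodes both genes' unique
    k-mer length.  Truth records each gene's true mappable length at the
    configured read length.
    """
    rng = substream(config.seed, "transcripts")
    bases = np.array(list("ACGT"))
    genes = catalog["gene_id"].tolist()
    seqs = {
        g: "".join(rng.choice(bases, size=config.transcript_length))
        for g in genes
    }
    dup_mask = catalog["mechanism"].isin(["dna_duplicate", "retrogene"]).to_numpy()
    dup_genes = [g for g, d in zip(genes, dup_mask) if d]
    # parents come from the non-duplicated genes so the copied block is never
    # itself overwritten afterwards and the pair really shares sequence
    stable = [g for g, d in zip(genes, dup_mask) if not d]
    shared = config.paralog_shared_bp
    parent_of: dict[str, str] = {}
    if shared > 0 and shared <= config.transcript_length and stable:
        for g in dup_genes:
            parent = stable[rng.integers(len(stable))]
            block = seqs[parent][:shared]
            seqs[g] = block + seqs[g][shared:]
            parent_of[g] = parent
    transcripts = {g: [s] for g, s in seqs.items()}
    from .quant import effective_length  # local import to avoid a cycle
    lengths = effective_length(transcripts, k=config.read_length)
    truth = pd.DataFrame({
        "gene_id": genes,
        "parent_gene": [parent_of.get(g, "") for g in genes],
        "true_mappable_length": [lengths[g] for g in genes],
    })
    return transcripts, truth


def gen_rnaseq(catalog: pd.DataFrame, transcripts: Mapping[str, list[str]],
               config: SimConfig
               ) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame, pd.DataFrame]:
    """Fixed-length error-free reads from transcripts, two sample groups.

    A fraction ``prop_de`` of genes is truly differentially expressed, by a
    factor of exp(de_effect_logfc) on the sampling weight in its biased
    group.  Among DE genes the direction depends on age: an old gene is
    fetal- or adult-biased with equal odds, while a young gene's odds of
    being fetal-biased are multiplied by ``young_fetal_enrichment`` — the
    planted young-early signal the downstream age x bias tests look for.
    Read start positions are uniform along the chosen transcript; genes
    whose transcripts are all shorter than the read length are emitted with
    zero reads (warning).

    Returns (reads per group as (id, seq) lists, drawn CountMatrix with a
    per-group total row, truth with de_status/direction).
    """
    rng = substream(config.seed, "rnaseq")
    k = config.read_length
    genes = catalog["gene_id"].tolist()
    n = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    de_flags = rng.random(n) < config.prop_de
    young = (catalog["age_class"] == "young").to_numpy()
    e = config.young_fetal_enrichment
    p_fetal = np.where(young, e / (e + 1.0), 0.5)
    up_fetal = rng.random(n) < p_fetal
    direction = np.where(de_flags, np.where(up_fetal, "fetal", "adult"), "none")
    # genes with no usable transcript produce no reads
    usable = np.array([
        any(len(s) >= k for s in transcripts.get(g, [])) for g in genes
    ])
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} genes have no transcript >= {k} nt; emitted with zero reads"
        )
    factor = float(np.exp(config.de_effect_logfc))
    reads: dict[str, list[tuple[str, str]]] = {}
    counts = {}
    for group in ("fetal", "adult"):
        w = base.copy()
        w[(direction == group)] *= factor
        w[~usable] = 0.0
        probs = w / w.sum()
        gene_counts = rng.multinomial(config.reads_per_group, probs)
        out = []
        for gi in gene_counts.nonzero()[0]:
            cands = [s for s in transcripts[genes[gi]] if len(s) >= k]
            m = int(gene_counts[gi])
            which = rng.integers(len(cands), size=m) if len(cands) > 1 else np.zeros(m, dtype=int)
            for wi in which:
                seq = cands[wi]
                start = int(rng.integers(len(seq) - k + 1))
                out.append((f"{group}:r{len(out)}", seq[start:start + k]))
        reads[group] = out
        counts[group] = gene_counts
    count_matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame({
        "gene_id": genes, "de_status": de_flags, "de_direction": direction,
        "base_rate": base,
    })
    return reads, count_matrix, truth


# ---------------------------------------------------------------------------
# MK counts
# ---------------------------------------------------------------------------

def gen_mk_counts(gamma_values: Sequence[float], theta_s: float, theta_r: float,
                  tau: float, n_sample: int, seed: int,
                  genes_per_gamma: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent Poisson MK tables under the PRF expected counts.

    Per gene with intensity gamma: ps ~ Poi(theta_s L(0,n)),
    ds ~ Poi(theta_s tau), pn ~ Poi(theta_r L(gamma,n)),
    dn ~ Poi(theta_r tau G(gamma)).
    """
    if theta_s <= 0 or theta_r <= 0 or tau <= 0:
        raise SimulationError("rates must be positive")
    rng = substream(seed, "mk")
    a_n = harmonic(n_sample)
    rows, truths = [], []
    i = 0
    for gamma in gamma_values:
        l_g = sojourn_l(float(gamma), n_sample)
        g_g = fixation_factor(float(gamma))
        for _ in range(genes_per_gamma):
            gid = f"mk{i:05d}"
            ps = int(rng.poisson(theta_s * a_n))
            ds = int(rng.poisson(theta_s * tau))
            pn = int(rng.poisson(theta_r * l_g))
            dn = int(rng.poisson(theta_r * tau * g_g))
            rows.append({"gene_id": gid, "ds": ds, "ps": ps, "dn": dn,
                         "pn": pn, "n_sample": n_sample})
            truths.append({"gene_id": gid, "true_gamma": float(gamma)})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# codon alignment pairs
# ---------------------------------------------------------------------------

def gen_codon_pairs(n_codons: int, n_syn_diffs: int, n_nonsyn_diffs: int,
                    seed: int = 0) -> tuple[str, str]:
    """Codon alignment pair with exactly the requested counted differences.

    Synonymous differences are placed at the fourfold-degenerate third
    position of glycine codons (GGG -> GGA); nonsynonymous differences use
    tryptophan codons, whose changes are all nonsynonymous (TGG -> TGC).
    """
    if n_syn_diffs + n_nonsyn_diffs > n_codons:
        raise SimulationError("more differences requested than codons available")
    rng = substream(seed, "codons")
    slots = rng.permutation(n_codons)
    syn_slots = set(slots[:n_syn_diffs].tolist())
    nonsyn_slots = set(slots[n_syn_diffs:n_syn_diffs + n_nonsyn_diffs].tolist())
    c1, c2 = [], []
    for i in range(n_codons):
        if i in syn_slots:
            c1.append("GGG"); c2.append("GGA")
        elif i in nonsyn_slots:
            c1.append("TGG"); c2.append("TGC")
        else:
            c1.append("GGG"); c2.append("GGG")
    return "".join(c1), "".join(c2)
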