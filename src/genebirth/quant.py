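"""Read-count quantification with mappability correction and count-based DE.

Expression is measured as RPMK — read count per million mapped reads per
kilobase of *mappable* gene length, where the mappable length of a gene is
the number of distinct 32-mers occurring in its transcripts and nowhere
else in the transcriptome.  Reads (exact 32-mers here) matching more than
one gene are discarded, so paralogs sharing recent duplicated sequence do
not leak counts into each other; the unique-k-mer length corrects the
denominator for the same effect.

Differential expression between two pooled sample groups uses a binomial
generalized likelihood-ratio test on (count, total) pairs with a
chi-square(1) reference and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

DEFAULT_K = 32

_COMP = str.maketrans("ACGT", "TGCA")


class QuantError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _gene_kmers(seqs: Iterable[str], k: int) -> set[str]:
    out: set[str] = set()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            out.add(seq[i:i + k])
    return out


def kmer_index(transcripts: Mapping[str, Iterable[str]], k: int = DEFAULT_K
               ) -> dict[str, set[str]]:
    """Map each k-mer to the set of genes whose transcripts contain it."""
    index: dict[str, set[str]] = {}
    for gene, seqs in transcripts.items():
        for km in _gene_kmers(seqs, k):
            index.setdefault(km, set()).add(gene)
    return index


def effective_length(transcripts: Mapping[str, Iterable[str]], k: int = DEFAULT_K
                     ) -> dict[str, int]:
    """Unique k-mer count per gene (the mappability-corrected gene length).

    A k-mer counts toward a gene iff it occurs in that gene's transcripts
    and in no other gene's; duplicates within one gene count once.  Genes
    whose transcripts are all shorter than k get length 0.
    """
    if k < 1:
        raise QuantError("k must be >= 1")
    index = kmer_index(transcripts, k)
    lengths = {gene: 0 for gene in transcripts}
    for km, genes in index.items():
        if len(genes) == 1:
            lengths[next(iter(genes))] += 1
    return lengths


@dataclass
class ReadAssignment:
    counts: pd.Series          # per-gene assigned read counts
    total_assigned: int
    n_multi_gene: int          # discarded: matched more than one gene
    n_unmatched: int           # discarded: matched nothing
    n_input: int


def assign_reads(reads: Iterable[str], transcripts: Mapping[str, Iterable[str]],
                 k: int | None = None, stranded: bool = False) -> ReadAssignment:
    """Exact-match toy mapper for fixed-length error-free reads.

    A read counts for gene g iff its sequence (or reverse complement unless
    ``stranded``) occurs in g's transcripts and in no other gene's.  Reads
    hitting zero or more than one gene are discarded; assigned + discarded
    equals the input count.
    """
    reads = list(reads)
    if reads:
        lengths = {len(r) for r in reads}
        if len(lengths) > 1:
            raise QuantError("reads must all have the same length")
        read_len = lengths.pop()
        if k is None:
            k = read_len
        elif k != read_len:
            raise QuantError(f"reads are {read_len} nt but k={k}")
    elif k is None:
        k = DEFAULT_K
    index = kmer_index(transcripts, k)
    counts: dict[str, int] = {gene: 0 for gene in transcripts}
    multi = unmatched = assigned = 0
    empty: set[str] = set()
    for read in reads:
        genes = index.get(read, empty)
        if not stranded:
            genes = genes | index.get(revcomp(read), empty)
        if len(genes) == 1:
            counts[next(iter(genes))] += 1
            assigned += 1
        elif genes:
            multi += 1
        else:
            unmatched += 1
    return ReadAssignment(
        counts=pd.Series(counts, name="count", dtype=int),
        total_assigned=assigned, n_multi_gene=multi,
        n_unmatched=unmatched, n_input=len(reads),
    )


def rpmk(count: float, effective_length_bp: float, total_mapped: float) -> float:
    """Reads per million mapped per kilobase of mappable length."""
    if effective_length_bp <= 0:
        raise QuantError("effective length must be positive (gene should be excluded upstream)")
    if total_mapped <= 0:
        raise QuantError("total mapped reads must be positive")
    return count / (total_mapped / 1e6) / (effective_length_bp / 1e3)


_DUPLICATION_MECHANISMS = frozenset({"dna_duplicate", "retrogene"})


def filter_short_mappable(catalog: pd.DataFrame, lengths: Mapping[str, int],
                          min_bp: int = 30) -> tuple[list[str], list[str]]:
    """Drop duplicated genes whose unique mappable region is < ``min_bp``.

    Only duplication-born genes (DNA-level duplicates and retrogenes) are
    subject to the filter; de novo genes keep their (possibly short)
    mappable regions because they have no paralog to confound mapping.
    Returns (retained gene ids, excluded gene ids).
    """
    retained, excluded = [], []
    for _, row in catalog.iterrows():
        gid = row["gene_id"]
        if gid not in lengths:
            raise QuantError(f"no effective length for gene {gid!r}")
        if row.get("mechanism") in _DUPLICATION_MECHANISMS and lengths[gid] < min_bp:
            excluded.append(gid)
        else:
            retained.append(gid)
    return retained, excluded


def _binom_loglik(x, n, p):
    # binomial log-likelihood up to the constant log C(n, x); 0*log 0 == 0
    return xlogy(x, p) + xlogy(n - x, 1.0 - p)


def lrt_de(x1, n1, x2, n2):
    """Binomial two-group generalized likelihood-ratio test (vectorized).

    Lambda = 2 [ l(x1; n1, x1/n1) + l(x2; n2, x2/n2)
                 - l(x1; n1, p0) - l(x2; n2, p0) ],  p0 = (x1+x2)/(n1+n2),
    with p = chi-square(1) upper tail.  Equals the G-test of the 2x2 table
    [[x1, n1-x1], [x2, n2-x2]].
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise QuantError("group totals must be positive")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > n1) or np.any(x2 > n2):
        raise QuantError("counts must satisfy 0 <= x <= N")
    p0 = (x1 + x2) / (n1 + n2)
    lam = 2.0 * (
        _binom_loglik(x1, n1, np.where(n1 > 0, x1 / n1, 0.0))
        + _binom_loglik(x2, n2, np.where(n2 > 0, x2 / n2, 0.0))
        - _binom_loglik(x1, n1, p0)
        - _binom_loglik(x2, n2, p0)
    )
    lam = np.maximum(lam, 0.0)  # clip -0.0 / rounding at the null
    p = stats.chi2.sf(lam, df=1)
    if lam.ndim == 0:
        return float(lam), float(p)
    return lam, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise QuantError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


GROUP1 = "group1-biased"
GROUP2 = "group2-biased"
UNBIASED = "unbiased"


def de_table(counts1, total1: int, counts2, total2: int,
             fdr: float = 0.05,
             labels: tuple[str, str] = (GROUP1, GROUP2)) -> pd.DataFrame:
    """Per-gene DE calls between two pooled groups.

    ``counts1``/``counts2`` are per-gene Series sharing an index; totals are
    each group's total mapped reads.  Direction is assigned at q < fdr; a
    gene whose group proportions tie is unbiased regardless of q.
    """
    c1 = pd.Series(counts1).astype(float)
    c2 = pd.Series(counts2).reindex(c1.index).astype(float)
    lam, p = lrt_de(c1.to_numpy(), total1, c2.to_numpy(), total2)
    q = bh_fdr(p)
    r1 = c1.to_numpy() / total1
    r2 = c2.to_numpy() / total2
    direction = np.where(
        (q < fdr) & (r1 > r2), labels[0],
        np.where((q < fdr) & (r2 > r1), labels[1], UNBIASED),
    )
    return pd.DataFrame({
        "gene_id": c1.index, "count1": c1.to_numpy(dtype=int), "total1": total1,
        "count2": c2.to_numpy(dtype=int), "total2": total2,
        "llr": lam, "p": p, "q": q, "direction": direction,
    })


def group_samples(expr: pd.DataFrame) -> dict[str, int]:
    """Split samples into two groups by expression similarity.

    Hierarchical clustering with distance 1 - Pearson correlation between
    sample profiles, average linkage, cut into exactly two clusters.
    ``expr`` is genes x samples.  Raises on degenerate input where all
    pairwise distances are zero.
    """
    if expr.shape[1] < 2:
        raise QuantError("need at least 2 samples")
    if expr.shape[1] == 2:
        return {expr.columns[0]: 1, expr.columns[1]: 2}
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(expr.to_numpy(), rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if np.allclose(dist, 0.0):
        raise QuantError("all sample profiles identical: no defensible 2-way split")
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return dict(zip(expr.columns, (int(v) for v in labels)))
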