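"""Sequence-evolution layer: Ka/Ks, McDonald-Kreitman tests, and a
Poisson-random-field (PRF) selection-intensity estimator.

Ka/Ks uses the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction: per-codon synonymous site fractions are averaged between the two
sequences, multi-step codon differences are averaged over mutational
pathways, and proportions are corrected by d = -(3/4) ln(1 - 4p/3).

The MK test contrasts fixed vs polymorphic, synonymous vs nonsynonymous
counts in a 2x2 table.  Under the PRF model with scaled selection intensity
gamma = 2Ns, the expected counts are

    E[ps] = theta_s * L(0, n)     E[ds] = theta_s * tau
    E[pn] = theta_r * L(gamma, n) E[dn] = theta_r * tau * G(gamma)

where G(gamma) = 2*gamma / (1 - exp(-2*gamma)) is the relative fixation
probability and L(gamma, n) the expected number of segregating sites per
unit mutation rate in a sample of n chromosomes.  The neutrality index
NI = (pn/ps)/(dn/ds) then has model value R(gamma) = [L(gamma,n)/L(0,n)] /
G(gamma), a strictly decreasing function of gamma, so gamma is estimated by
1-D root finding on R(gamma) = observed NI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats
from scipy.special import xlogy

from Bio.Data.CodonTable import standard_dna_table

_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"
_BASES = "ACGT"


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    gene_id: str | None
    n_codons: int
    S: float                 # synonymous sites (averaged over both sequences)
    N: float                 # nonsynonymous sites
    Sd: float                # synonymous differences (pathway-averaged)
    Nd: float                # nonsynonymous differences
    pS: float
    pN: float
    Ks: float                # Jukes-Cantor corrected
    Ka: float
    ratio: float             # Ka/Ks (nan when Ks == 0 or undefined)
    trimmed_ratio: float     # min(ratio, 1) for plotting
    jc_defined: bool         # False when p >= 3/4 makes the correction blow up
    passes_filters: bool     # > min_codons AND estimated syn substitutions >= 1
    filter_reasons: tuple[str, ...]


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous.

    Changes to stop codons count as nonsynonymous, so every position
    contributes a full site and S + N = 3 * codons exactly.
    """
    aa = _CODE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if _CODE[alt] == aa and aa != "*":
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over mutational pathways.

    Pathways passing through a stop codon are excluded unless every pathway
    does, in which case all are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        steps = []
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODE[nxt] == "*" and nxt != c2:
                hits_stop = True
            steps.append(1.0 if _CODE[nxt] == _CODE[cur] and _CODE[cur] != "*" else 0.0)
            cur = nxt
        paths.append((hits_stop, steps))
    usable = [steps for hits, steps in paths if not hits]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = sum(sum(steps) for steps in usable) / len(usable)
    total = len(diff_pos)
    return syn, total - syn


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); undefined (inf) at p >= 3/4."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(seq1: str, seq2: str, min_codons: int = 100,
              gene_id: str | None = None) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for a gap-free in-frame pair of coding sequences.

    Filters mirror the analysis defaults: the alignable region must cover
    more than ``min_codons`` codons and carry at least one estimated
    synonymous substitution (Ks * S >= 1); pairs failing either are flagged
    rather than dropped.  Ratios above 1 are additionally reported trimmed
    to 1 for plotting.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise SelectionError("sequences differ in length")
    if len(seq1) % 3:
        raise SelectionError("sequence length not a multiple of 3")
    if set(seq1 + seq2) - set(_BASES):
        raise SelectionError("sequences must be gap-free ACGT")
    codons1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]
    for c in codons1[:-1] + codons2[:-1]:
        if _CODE[c] == "*":
            raise SelectionError(f"internal stop codon {c}")
    n_codons = len(codons1)

    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S1 += s1; N1 += n1; S2 += s2; N2 += n2
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd; Nd += nd
    S = (S1 + S2) / 2.0
    N = (N1 + N2) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    jc_defined = math.isfinite(Ks) and math.isfinite(Ka)
    ratio = Ka / Ks if jc_defined and Ks > 0 else math.nan

    reasons = []
    if n_codons <= min_codons:
        reasons.append(f"alignable region <= {min_codons} codons")
    if not jc_defined:
        reasons.append("substitution proportion >= 3/4, JC correction undefined")
    elif Ks * S < 1.0:
        reasons.append("fewer than one estimated synonymous substitution")
    return KaKsResult(
        gene_id=gene_id, n_codons=n_codons, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, Ks=Ks, Ka=Ka, ratio=ratio,
        trimmed_ratio=min(ratio, 1.0) if not math.isnan(ratio) else math.nan,
        jc_defined=jc_defined, passes_filters=not reasons,
        filter_reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# McDonald-Kreitman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MKCounts:
    """Divergence/polymorphism counts: dn, ds fixed; pn, ps polymorphic."""
    dn: int
    ds: int
    pn: int
    ps: int
    n_sample: int = 40

    def __post_init__(self):
        for name in ("dn", "ds", "pn", "ps"):
            if getattr(self, name) < 0:
                raise SelectionError(f"{name} must be nonnegative")
        if self.n_sample < 2:
            raise SelectionError("n_sample must be >= 2")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.ds, self.ps], [self.dn, self.pn]])


def mk_fet(counts: MKCounts) -> tuple[float, float, float]:
    """Two-sided Fisher's exact test on [[ds, ps], [dn, pn]], with the
    neutrality index NI = (pn/ps)/(dn/ds) and alpha = 1 - (ds*pn)/(dn*ps).

    NI/alpha are NaN when a needed denominator is zero; the exact test
    tolerates zero cells (an all-zero table is an error).
    """
    tab = counts.table
    if tab.sum() == 0:
        raise SelectionError("all-zero MK table")
    p = stats.fisher_exact(tab, alternative="two-sided")[1]
    if counts.ps > 0 and counts.ds > 0 and counts.dn > 0:
        ni = (counts.pn / counts.ps) / (counts.dn / counts.ds)
        alpha = 1.0 - ni
    else:
        ni = alpha = math.nan
    return p, ni, alpha


# ---------------------------------------------------------------------------
# PRF selection intensity
# ---------------------------------------------------------------------------

def harmonic(n: int) -> float:
    """Watterson constant a_n = sum_{i=1}^{n-1} 1/i (this is L(0, n))."""
    return sum(1.0 / i for i in range(1, n))


def fixation_factor(gamma: float) -> float:
    """G(gamma) = 2*gamma / (1 - exp(-2*gamma)); G(0) = 1."""
    if gamma == 0.0:
        return 1.0
    denom = -math.expm1(-2.0 * gamma)
    if denom == 0.0 or not math.isfinite(denom):
        # gamma very negative: G ~ -2*gamma*exp(2*gamma) -> 0+
        return -2.0 * gamma * math.exp(2.0 * gamma)
    return 2.0 * gamma / denom


def sojourn_l(gamma: float, n: int) -> float:
    """Expected segregating sites per unit mutation rate, sample size n.

    L(gamma, n) = Int_0^1 [(1 - e^{-2g(1-q)}) / ((1 - e^{-2g}) q (1-q))]
                  * (1 - q^n - (1-q)^n) dq,
    with the gamma -> 0 limit Int_0^1 (1 - q^n - (1-q)^n)/q dq = a_n.
    The integrand is bounded at both endpoints.
    """
    if n < 2:
        raise SelectionError("sample size must be >= 2")
    if gamma == 0.0:
        def f0(q):
            return (1.0 - q ** n - (1.0 - q) ** n) / q
        val, _ = integrate.quad(f0, 0.0, 1.0, epsabs=1e-12, epsrel=1e-12, limit=200)
        return val
    denom = -math.expm1(-2.0 * gamma)

    def f(q):
        num = -math.expm1(-2.0 * gamma * (1.0 - q))
        tail = 1.0 - q ** n - (1.0 - q) ** n
        return (num / denom) * tail / (q * (1.0 - q))

    val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val


def ni_curve(gamma: float, n: int) -> float:
    """Model neutrality index R(gamma) = [L(gamma,n)/L(0,n)] / G(gamma).

    Strictly decreasing in gamma with R(0) = 1; estimation inverts it.
    """
    return (sojourn_l(gamma, n) / harmonic(n)) / fixation_factor(gamma)


@dataclass
class PRFResult:
    gamma_hat: float
    lrt_lambda: float
    p: float
    status: str            # "ok" | "boundary" | "declined"
    reason: str | None = None


def _g_statistic(tab: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence on a 2x2 table.

    This equals 2*(l_full - l_{gamma=0}) of the PRF Poisson model: the full
    model (theta_s, theta_r, tau, gamma free) is saturated whenever gamma_hat
    is finite, and the gamma=0 ML fit is the standard independence fit.
    """
    total = tab.sum()
    if total == 0:
        return 0.0
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(tab, tab) - xlogy(tab, expected)
    return float(2.0 * np.nansum(terms))


def prf_gamma(counts: MKCounts, bracket: float = 30.0,
              max_bracket: float = 200.0) -> PRFResult:
    """Per-gene MLE of the scaled selection intensity gamma = 2Ns.

    Solves R(gamma) = NI_observed by monotone root finding; the LRT against
    gamma = 0 uses Poisson likelihoods and a chi-square(1) reference.
    Estimation is declined when NI is undefined (ps, ds or dn zero); NI = 0
    (pn = 0) pins gamma at +infinity and is flagged as a boundary estimate
    with the LRT still reported.
    """
    n = counts.n_sample
    if counts.ps == 0 or counts.ds == 0 or counts.dn == 0:
        return PRFResult(math.nan, math.nan, math.nan, "declined",
                         "NI undefined: zero ps, ds or dn")
    ni = (counts.pn / counts.ps) / (counts.dn / counts.ds)
    lam = _g_statistic(counts.table)
    p = float(stats.chi2.sf(lam, df=1))
    if counts.pn == 0:
        return PRFResult(math.inf, lam, p, "boundary", "pn = 0 drives gamma to +inf")

    def f(g):
        return ni_curve(g, n) - ni

    lo, hi = -bracket, bracket
    while f(lo) * f(hi) > 0:
        lo *= 2.0
        hi *= 2.0
        if hi > max_bracket:
            side = math.inf if ni < ni_curve(max_bracket, n) else -math.inf
            return PRFResult(side, lam, p, "boundary",
                             f"no root in [-{max_bracket}, {max_bracket}]")
    gamma_hat = optimize.brentq(f, lo, hi, xtol=1e-8, rtol=1e-12)
    return PRFResult(float(gamma_hat), lam, p, "ok")


def classify_positively_selected(results: pd.DataFrame, threshold: float = 0.1,
                                 p_col: str = "p") -> pd.DataFrame:
    """Rows with p strictly below the threshold (default p < 0.1)."""
    if p_col not in results.columns:
        raise SelectionError(f"missing column {p_col!r}")
    return results[results[p_col] < threshold]


def selection_enrichment(set_a: tuple[int, int], set_b: tuple[int, int],
                         alternative: str = "two-sided") -> float:
    """FET p comparing the positively-selected fraction between two gene sets.

    Each argument is (selected, total).
    """
    (sa, ta), (sb, tb) = set_a, set_b
    if ta == 0 or tb == 0:
        raise SelectionError("zero totals")
    if sa > ta or sb > tb:
        raise SelectionError("selected exceeds total")
    tab = [[sa, ta - sa], [sb, tb - sb]]
    return float(stats.fisher_exact(tab, alternative=alternative)[1])


def load_fetal_brain_mk_table() -> pd.DataFrame:
    """Published MK counts for 16 young fetal-brain-biased human genes.

    Columns: refseq, symbol, ds, ps, dn, pn, p, u, sd, where p/u/sd are the
    source study's posterior summary of the selection intensity (p is the
    probability-like score against 2Ns > 0; five genes fall below 0.1).
    """
    with resources.files("genebirth.data").joinpath("mk_fetal_brain_young.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
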