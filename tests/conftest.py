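import numpy as np
import pandas as pd
import pytest

from genebirth.dating import FocalPath

FIVE_TIP_NEWICK = "(fish,(frog,(mouse,(chimp,human))));"


@pytest.fixture(scope="session")
def five_tip_tree() -> FocalPath:
    """(fish,(frog,(mouse,(chimp,human)))) with human focal: branches 0..4."""
    return FocalPath.from_newick(FIVE_TIP_NEWICK, focal="human")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_catalog(genes, ages=None, branches=None, chrom="chr1", spacing=10_000,
                 span=1_000, mechanism="unknown") -> pd.DataFrame:
    """Minimal gene catalog for enrichment-style tests."""
    n = len(genes)
    ages = ages if ages is not None else ["old"] * n
    branches = branches if branches is not None else [0] * n
    start = np.arange(n) * spacing
    return pd.DataFrame({
        "gene_id": list(genes), "chromosome": chrom, "start": start,
        "end": start + span, "strand": "+", "branch": branches,
        "age_class": ages, "mechanism": mechanism,
    })


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided FET p.

    Sums the probabilities of every table with the observed margins whose
    point probability does not exceed the observed table's (with the usual
    1 + 1e-7 relative guard against floating-point ties).
    """
    from scipy.stats import hypergeom
    n_row1, n_row2 = a + b, c + d
    n_col1 = a + c
    total = n_row1 + n_row2
    lo = max(0, n_col1 - n_row2)
    hi = min(n_row1, n_col1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, total, n_col1, n_row1)
    p_obs = hypergeom.pmf(a, total, n_col1, n_row1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def binom_two_sided_oracle(k: int, n: int, p: float = 0.5) -> float:
    """Exhaustive two-sided binomial p: sum of outcomes no more likely."""
    from scipy.stats import binom
    support = np.arange(n + 1)
    probs = binom.pmf(support, n, p)
    return float(probs[probs <= binom.pmf(k, n, p) * (1 + 1e-7)].sum())


def dollo_oracle(tree: FocalPath, present: set[str]) -> int:
    """Brute-force branch dating by hypothesis enumeration.

    A gene arising on branch b can (with losses) be present only in the
    focal tip and clades diverging at or after b; a presence in an older
    clade would require regain, which Dollo forbids.  Scanning hypotheses
    from youngest to oldest, the first one whose reachable tip set covers
    every observed presence is the most parsimonious no-regain assignment.
    """
    for b in range(tree.n_branches, -1, -1):
        reachable = {tree.focal}
        for i, clade in enumerate(tree.outgroups):
            if i >= b:
                reachable |= clade
        if present <= reachable:
            return b
    raise AssertionError("unreachable: branch 0 covers every tip")
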