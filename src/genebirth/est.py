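"""EST-based expression presence calls and young-gene enrichment statistics.

An EST (expressed sequence tag) is a single cDNA read; a gene is called
expressed in a tissue (optionally tissue x stage) when at least ``min_ests``
ESTs from normal-sample libraries support it.  Enrichment of young genes in
a tissue's transcriptome is measured as the proportion of young genes among
all genes expressed there, compared between species with a two-sided
Fisher's exact test and Bonferroni correction over tissue categories.

Two resampling controls guard against unequal sequencing depth:

* ``bootstrap_background`` resamples ESTs with replacement within each
  (species, tissue) cell to the original depth and reports the mean and sd
  of the young proportion across replicates (plotted as mean +/- 2 sd).
* ``subsample_control`` repeatedly draws equal-size EST samples without
  replacement from two species and counts how often the first species'
  young proportion fails to exceed the second's; ties count as failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EST_COLUMNS = ["library_id", "species", "tissue", "stage", "normal_flag",
               "gene_id", "est_count"]
STAGES = ("fetal", "infant", "adult", "other", "unknown")


class EstError(ValueError):
    pass


def _validate(est: pd.DataFrame) -> pd.DataFrame:
    missing = set(EST_COLUMNS) - set(est.columns)
    if missing:
        raise EstError(f"EST table missing columns: {sorted(missing)}")
    if (est["est_count"] < 0).any():
        raise EstError("negative EST counts")
    return est


def call_expression(est: pd.DataFrame, min_ests: int = 2,
                    by_stage: bool = False) -> pd.DataFrame:
    """Presence calls: gene x (species, tissue[, stage]) cells with support.

    Only normal-sample libraries contribute.  Returns a frame with columns
    species, tissue, [stage,] gene_id, est_count restricted to cells with
    ``est_count >= min_ests``.  Unrecognized stage labels are routed to
    "unknown" with a warning when ``by_stage`` is set.
    """
    if min_ests < 1:
        raise EstError("min_ests must be >= 1")
    est = _validate(est)
    est = est[est["normal_flag"].astype(bool)]
    keys = ["species", "tissue"]
    if by_stage:
        est = est.copy()
        bad = ~est["stage"].isin(STAGES)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} records with unknown stage labels routed to 'unknown'"
            )
            est.loc[bad, "stage"] = "unknown"
        keys.append("stage")
    agg = (est.groupby(keys + ["gene_id"], as_index=False)["est_count"].sum())
    return agg[agg["est_count"] >= min_ests].reset_index(drop=True)


def young_proportion(calls: pd.DataFrame, catalog: pd.DataFrame,
                     species: str, tissue: str,
                     stage: str | None = None) -> tuple[int, int, float]:
    """(young expressed, all expressed, proportion) in one tissue cell."""
    ages = catalog.set_index("gene_id")["age_class"]
    sub = calls[(calls["species"] == species) & (calls["tissue"] == tissue)]
    if stage is not None:
        if "stage" not in sub.columns:
            raise EstError("calls lack a stage column; rerun call_expression(by_stage=True)")
        sub = sub[sub["stage"] == stage]
    uncovered = set(sub["gene_id"]) - set(ages.index)
    if uncovered:
        raise EstError(f"genes missing from catalog: {sorted(uncovered)[:5]} ...")
    total = len(sub)
    if total == 0:
        raise EstError(f"no expressed genes in {species}/{tissue}/{stage}")
    young = int((ages.loc[sub["gene_id"]] == "young").sum())
    return young, total, young / total


def compare_proportions(a: tuple[int, int], b: tuple[int, int],
                        m_tests: int = 1) -> tuple[float, float]:
    """Two-sided FET on the gene-level 2x2 (young/old x species), Bonferroni.

    ``a`` and ``b`` are (young expressed, total expressed).  The two-sided
    p sums all hypergeometric outcomes no more probable than the observed
    one; the adjusted p is min(1, p * m_tests).
    """
    (ya, ta), (yb, tb) = a, b
    if ya > ta or yb > tb:
        raise EstError("young count exceeds total")
    if ta == 0 or tb == 0:
        raise EstError("zero totals")
    table = [[ya, ta - ya], [yb, tb - yb]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return p, min(1.0, p * m_tests)


def _tissue_gene_counts(est: pd.DataFrame, by_stage: bool = False) -> pd.DataFrame:
    keys = ["species", "tissue"] + (["stage"] if by_stage else [])
    est = est[est["normal_flag"].astype(bool)]
    return est.groupby(keys + ["gene_id"], as_index=False)["est_count"].sum()


def bootstrap_background(est: pd.DataFrame, catalog: pd.DataFrame,
                         n_reps: int = 100, seed: int = 0,
                         min_ests: int = 2) -> pd.DataFrame:
    """Bootstrap mean and sd of the young proportion per (species, tissue).

    Each replicate resamples the cell's ESTs with replacement to the
    original depth (multinomial over genes), re-calls presence at
    ``min_ests`` and recomputes the proportion.
    """
    if n_reps < 2:
        raise EstError("n_reps must be >= 2")
    _validate(est)
    ages = catalog.set_index("gene_id")["age_class"]
    rng = np.random.default_rng(seed)
    rows = []
    for (species, tissue), cell in _tissue_gene_counts(est).groupby(["species", "tissue"]):
        counts = cell["est_count"].to_numpy()
        depth = int(counts.sum())
        if depth == 0:
            raise EstError(f"no ESTs in {species}/{tissue}")
        young_mask = (ages.reindex(cell["gene_id"]).to_numpy() == "young")
        draws = rng.multinomial(depth, counts / depth, size=n_reps)
        present = draws >= min_ests
        totals = present.sum(axis=1)
        with np.errstate(invalid="ignore"):
            props = (present & young_mask).sum(axis=1) / totals
        rows.append({
            "species": species, "tissue": tissue,
            "bootstrap_mean": float(np.nanmean(props)),
            "bootstrap_sd": float(np.nanstd(props, ddof=1)),
        })
    return pd.DataFrame(rows)


@dataclass
class SubsampleResult:
    n_reps: int
    n_a_le_b: int              # replicates where species a's proportion <= b's
    empirical_p: float
    reported: str              # "p = x" or "p < 1/n_reps" when the count is 0


def subsample_control(est_a: pd.DataFrame, est_b: pd.DataFrame,
                      catalog: pd.DataFrame, sample_size: int,
                      n_reps: int = 1000, seed: int = 0,
                      min_ests: int = 2) -> SubsampleResult:
    """Depth-matched subsampling control between two species' EST pools.

    Per replicate, ``sample_size`` ESTs are drawn without replacement from
    each table, presence is re-called and young proportions compared; the
    empirical p is the fraction of replicates in which a fails to beat b
    (ties count against a, the conservative direction).
    """
    ages = catalog.set_index("gene_id")["age_class"]
    rng = np.random.default_rng(seed)

    def pool(est):
        cell = _validate(est)
        cell = cell[cell["normal_flag"].astype(bool)]
        agg = cell.groupby("gene_id", as_index=False)["est_count"].sum()
        counts = agg["est_count"].to_numpy()
        young = (ages.reindex(agg["gene_id"]).to_numpy() == "young")
        return counts, young

    counts_a, young_a = pool(est_a)
    counts_b, young_b = pool(est_b)
    for counts, name in ((counts_a, "a"), (counts_b, "b")):
        if sample_size > counts.sum():
            raise EstError(f"sample_size exceeds table {name}'s EST total")
    n_le = 0
    for _ in range(n_reps):
        da = rng.multivariate_hypergeometric(counts_a, sample_size) >= min_ests
        db = rng.multivariate_hypergeometric(counts_b, sample_size) >= min_ests
        prop_a = (da & young_a).sum() / max(da.sum(), 1)
        prop_b = (db & young_b).sum() / max(db.sum(), 1)
        if prop_a <= prop_b:
            n_le += 1
    p = n_le / n_reps
    reported = f"p < {1 / n_reps:g}" if n_le == 0 else f"p = {p:g}"
    return SubsampleResult(n_reps=n_reps, n_a_le_b=n_le, empirical_p=p, reported=reported)


def enrichment_table(est_a: pd.DataFrame, est_b: pd.DataFrame,
                     catalog: pd.DataFrame, min_ests: int = 2,
                     n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per-tissue young-proportion comparison between two species' tables.

    One row per tissue shared by both tables: proportions, FET p,
    Bonferroni-adjusted p (m = number of shared tissues) and species-a
    bootstrap mean/sd.
    """
    calls_a = call_expression(est_a, min_ests=min_ests)
    calls_b = call_expression(est_b, min_ests=min_ests)
    tissues = sorted(set(calls_a["tissue"]) & set(calls_b["tissue"]))
    m = len(tissues)
    boot = bootstrap_background(est_a, catalog, n_reps=n_boot, seed=seed,
                                min_ests=min_ests).set_index("tissue")
    sp_a = est_a["species"].iloc[0]
    sp_b = est_b["species"].iloc[0]
    rows = []
    for tissue in tissues:
        a = young_proportion(calls_a, catalog, sp_a, tissue)
        b = young_proportion(calls_b, catalog, sp_b, tissue)
        p, p_bonf = compare_proportions(a[:2], b[:2], m_tests=m)
        rows.append({
            "tissue": tissue,
            "young_a": a[0], "total_a": a[1], "proportion_a": a[2],
            "young_b": b[0], "total_b": b[1], "proportion_b": b[2],
            "fet_p": p, "bonferroni_p": p_bonf, "m_tests": m,
            "bootstrap_mean": boot.loc[tissue, "bootstrap_mean"],
            "bootstrap_sd": boot.loc[tissue, "bootstrap_sd"],
        })
    return pd.DataFrame(rows)
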