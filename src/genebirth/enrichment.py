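"""Crossing gene age with differential-expression calls.

The central question: do genes that originated recently contribute more
than expected to one side of an expression contrast (e.g. fetal- vs
adult-brain biased, neocortex- vs non-neocortex upregulated)?  The module
provides the 2x2 age-by-bias Fisher table, per-origination-branch bias
profiles with exact binomial tests, pooling of neighboring same-age
same-bias genes into genomic clusters (to discount duplication blocks as a
single event), proximity of genes to regulatory features, and generic
fold-enrichment arithmetic for annotation terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quant import UNBIASED, bh_fdr


class EnrichmentError(ValueError):
    pass


@dataclass
class BiasTable:
    """2x2 of age class x bias direction among biased genes."""
    counts: pd.DataFrame       # index: age class, columns: directions
    p: float                   # two-sided FET
    proportions: pd.DataFrame  # row-normalized

    def __repr__(self):  # compact for summaries
        return f"BiasTable(p={self.p:.3g})\n{self.counts}"


def bias_table(calls: pd.DataFrame, catalog: pd.DataFrame) -> BiasTable:
    """Age x direction contingency of biased genes with two-sided FET.

    ``calls`` needs gene_id and direction; unbiased genes are excluded.
    ``catalog`` supplies age_class per gene.
    """
    merged = calls.merge(catalog[["gene_id", "age_class"]], on="gene_id", how="left")
    if merged["age_class"].isna().any():
        missing = merged.loc[merged["age_class"].isna(), "gene_id"].tolist()[:5]
        raise EnrichmentError(f"genes without age class: {missing} ...")
    biased = merged[merged["direction"] != UNBIASED]
    tab = pd.crosstab(biased["age_class"], biased["direction"])
    if tab.shape != (2, 2):
        raise EnrichmentError(
            f"need a 2x2 table (got {tab.shape}); empty margin in age or direction"
        )
    tab = tab.loc[sorted(tab.index, reverse=True)]  # young first for readability
    p = float(stats.fisher_exact(tab.to_numpy())[1])
    props = tab.div(tab.sum(axis=1), axis=0)
    return BiasTable(counts=tab, p=p, proportions=props)


def branch_profile(calls: pd.DataFrame, catalog: pd.DataFrame,
                   n_branches: int, up_label: str, down_label: str) -> pd.DataFrame:
    """Per-origination-branch bias profile with exact binomial tests.

    For every branch 0..n_branches: gene counts up/down/unbiased, the
    proportion biased each way, an exact two-sided binomial test of up vs
    down against 0.5 among biased genes (with the one-sided 'greater' p
    alongside), and Bonferroni adjustment over branches with a defined test.
    Branches with zero biased genes get NaN p-values and are flagged.
    """
    merged = calls.merge(catalog[["gene_id", "branch"]], on="gene_id", how="inner")
    rows = []
    for b in range(n_branches + 1):
        sub = merged[merged["branch"] == b]
        up = int((sub["direction"] == up_label).sum())
        down = int((sub["direction"] == down_label).sum())
        n = len(sub)
        if up + down > 0:
            p_two = stats.binomtest(up, up + down, 0.5, alternative="two-sided").pvalue
            p_one = stats.binomtest(up, up + down, 0.5, alternative="greater").pvalue
        else:
            p_two = p_one = math.nan
        rows.append({
            "branch": b, "n_genes": n, "n_up": up, "n_down": down,
            "prop_up": up / n if n else math.nan,
            "prop_down": down / n if n else math.nan,
            "binom_p": p_two, "binom_p_one_sided": p_one,
            "testable": up + down > 0,
        })
    prof = pd.DataFrame(rows)
    m = int(prof["testable"].sum())
    prof["bonferroni_p"] = np.minimum(1.0, prof["binom_p"] * m)
    return prof


def pool_clusters(catalog: pd.DataFrame, distance_cutoff: int) -> pd.DataFrame:
    """Pool neighboring same-branch same-bias genes into clusters.

    Input rows need gene_id, chromosome, start, end, branch, direction
    (biased genes only; coordinates 0-based half-open).  Along each
    chromosome's coordinate-sorted gene list, successive genes merge iff
    they share branch and direction and the gap from the previous gene's
    end to the next gene's start is <= cutoff (overlaps merge).  Returns one
    row per cluster with member ids, span, and shared labels.
    """
    if distance_cutoff < 0:
        raise EnrichmentError("distance cutoff must be nonnegative")
    if (catalog["direction"] == UNBIASED).any():
        raise EnrichmentError("pool_clusters expects biased genes only")
    if (catalog["start"] >= catalog["end"]).any():
        raise EnrichmentError("invalid coordinates: start must be < end")
    clusters = []
    srt = catalog.sort_values(["chromosome", "start", "end", "gene_id"], kind="mergesort")
    for chrom, genes in srt.groupby("chromosome", sort=True):
        cur: list[pd.Series] = []
        for _, g in genes.iterrows():
            if cur and (
                g["branch"] == cur[-1]["branch"]
                and g["direction"] == cur[-1]["direction"]
                and g["start"] - cur[-1]["end"] <= distance_cutoff
            ):
                cur.append(g)
            else:
                if cur:
                    clusters.append(cur)
                cur = [g]
        if cur:
            clusters.append(cur)
    rows = []
    for i, members in enumerate(clusters):
        rows.append({
            "cluster_id": f"{members[0]['chromosome']}:{i}",
            "chromosome": members[0]["chromosome"],
            "start": int(min(m["start"] for m in members)),
            "end": int(max(m["end"] for m in members)),
            "n_genes": len(members),
            "branch": members[0]["branch"],
            "direction": members[0]["direction"],
            "members": ",".join(m["gene_id"] for m in members),
        })
    return pd.DataFrame(rows)


def cluster_bias_table(catalog: pd.DataFrame, distance_cutoff: int,
                       age_of_branch) -> BiasTable:
    """Cluster-level age x bias FET: clusters, not genes, are the units."""
    clusters = pool_clusters(catalog, distance_cutoff)
    calls = pd.DataFrame({"gene_id": clusters["cluster_id"],
                          "direction": clusters["direction"]})
    cat = pd.DataFrame({"gene_id": clusters["cluster_id"],
                        "age_class": clusters["branch"].map(age_of_branch)})
    return bias_table(calls, cat)


def feature_association(catalog: pd.DataFrame, features: pd.DataFrame,
                        cutoff_bp: int,
                        group_cols: tuple[str, ...] = ("age_class", "direction"),
                        ) -> pd.DataFrame:
    """Fraction of genes with a regulatory feature within ``cutoff_bp``.

    Distance between two half-open intervals is 0 when they overlap or abut,
    else the nearest-end gap; a gene is associated iff its nearest feature
    on the same chromosome is at distance <= cutoff.  Fractions are reported
    per combination of ``group_cols`` (default age class x bias direction).
    """
    if cutoff_bp < 0:
        raise EnrichmentError("cutoff must be nonnegative")
    feats = {chrom: sub[["start", "end"]].to_numpy()
             for chrom, sub in features.groupby("chromosome")}
    associated = []
    for _, g in catalog.iterrows():
        arr = feats.get(g["chromosome"])
        if arr is None or len(arr) == 0:
            associated.append(False)
            continue
        gap = np.maximum(arr[:, 0] - g["end"], g["start"] - arr[:, 1])
        dist = np.maximum(gap, 0).min()
        associated.append(bool(dist <= cutoff_bp))
    out = catalog.copy()
    out["associated"] = associated
    frac = (out.groupby(list(group_cols))["associated"]
            .agg(n_genes="size", n_associated="sum", fraction="mean")
            .reset_index())
    return frac


def term_enrichment(gene_list: set[str], background: set[str],
                    term_map: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Fold enrichment + one-sided FET + BH FDR for annotation terms.

    ``term_map`` has columns gene_id, term.  fold = (hits_in_list /
    list_size) / (hits_in_background / background_size).  Returns all terms
    with their statistics and an ``enriched`` flag at the FDR threshold.
    """
    if not gene_list <= background:
        raise EnrichmentError("gene list must be a subset of the background")
    tm = term_map[term_map["gene_id"].isin(background)]
    orphan_terms = set(term_map["term"]) - set(tm["term"])
    if orphan_terms:
        raise EnrichmentError(f"terms with no background genes: {sorted(orphan_terms)[:5]}")
    n_list, n_bg = len(gene_list), len(background)
    rows = []
    for term, genes in tm.groupby("term")["gene_id"]:
        gset = set(genes)
        k = len(gset & gene_list)
        K = len(gset)
        fold = (k / n_list) / (K / n_bg) if n_list else math.nan
        tab = [[k, n_list - k], [K - k, n_bg - n_list - (K - k)]]
        p = float(stats.fisher_exact(tab, alternative="greater")[1])
        rows.append({"term": term, "hits_in_list": k, "list_size": n_list,
                     "hits_in_background": K, "background_size": n_bg,
                     "fold_enrichment": fold, "p": p})
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["fdr"] = bh_fdr(out["p"])
    out["enriched"] = out["fdr"] < fdr
    return out
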