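"""End-to-end orchestration: simulate -> date -> profile -> quantify -> cross.

``run_all`` executes the stages in order, writing one TSV per result plus a
JSON manifest with a sha256 digest, per-stage inputs/outputs, timings and
collected warnings.  In synthetic mode every input is generated by
:mod:`genebirth.simulate` from the run seed; in user mode stages whose
inputs are missing are skipped with a logged reason.  Truth files are
written under ``truth/`` and are never listed as a stage input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dating, enrichment, est, io, quant, selection
from .simulate import (DEMO_YOUNG_BRANCHES, SimConfig, demo_tree, gen_catalog,
                       gen_est_table, gen_mk_counts, gen_rnaseq,
                       gen_transcripts)

log = logging.getLogger("genebirth")


@dataclass
class RunConfig:
    """Run-level configuration; thresholds default to the analysis standards:
    2 ESTs for presence, 32-mers, 30 bp minimum mappable region, FDR 0.05,
    positive selection at p < 0.1, cluster cutoffs 100 kb and 1 Mb,
    100 bootstrap and 1,000 subsample replicates."""
    seed: int = 0
    outdir: str = "genebirth_out"
    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    inputs: dict = field(default_factory=dict)   # user-mode file paths
    min_ests: int = 2
    k: int = 32
    min_mappable: int = 30
    fdr: float = 0.05
    ps_threshold: float = 0.1
    cluster_cutoffs: tuple[int, int] = (100_000, 1_000_000)
    bootstrap_reps: int = 100
    subsample_reps: int = 1000
    young_branches: tuple[int, ...] = DEMO_YOUNG_BRANCHES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    def __init__(self, seed: int):
        self.data = {"seed": seed, "stages": {}, "warnings": []}

    def stage(self, name: str, inputs: list[str], outputs: list[Path],
              elapsed: float, note: str = "") -> None:
        self.data["stages"][name] = {
            "inputs": inputs,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(elapsed, 3),
            "note": note,
        }

    def skip(self, name: str, reason: str) -> None:
        self.data["stages"][name] = {"skipped": True, "reason": reason}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def validate_inputs(catalog: pd.DataFrame | None = None,
                    est_table: pd.DataFrame | None = None,
                    presence: pd.DataFrame | None = None,
                    tree: dating.FocalPath | None = None,
                    calls: pd.DataFrame | None = None) -> list[str]:
    """Schema, coordinate and cross-reference checks; returns failure strings."""
    failures: list[str] = []
    if catalog is not None:
        need = {"gene_id", "chromosome", "start", "end", "strand", "branch",
                "age_class", "mechanism"}
        missing = need - set(catalog.columns)
        if missing:
            failures.append(f"catalog missing columns {sorted(missing)}")
        else:
            bad = catalog[catalog["start"] >= catalog["end"]]
            for gid in bad["gene_id"]:
                failures.append(f"catalog coordinate failure (end <= start): {gid}")
    if est_table is not None:
        missing = set(est.EST_COLUMNS) - set(est_table.columns)
        if missing:
            failures.append(f"EST table missing columns {sorted(missing)}")
        elif catalog is not None and "gene_id" in catalog:
            unknown = set(est_table["gene_id"]) - set(catalog["gene_id"])
            for gid in sorted(unknown):
                failures.append(f"EST table gene absent from catalog: {gid}")
    if presence is not None and tree is not None:
        extra = set(presence.columns) - tree.tips
        if extra:
            failures.append(f"presence matrix species not in tree: {sorted(extra)}")
        if tree.focal in presence.columns and not presence[tree.focal].all():
            failures.append("presence matrix has genes absent in the focal species")
    if calls is not None and catalog is not None:
        unknown = set(calls["gene_id"]) - set(catalog["gene_id"])
        for gid in sorted(unknown):
            failures.append(f"DE call gene absent from catalog: {gid}")
    return failures


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns {name: DataFrame/value} of results.

    Synthetic mode generates its own inputs; the focal species gets the
    configured young-gene fetal-brain boost while the comparison species is
    generated under the null (enrichment 1), mirroring a human-vs-mouse
    contrast with a planted human signal.
    """
    out = Path(config.outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config.seed)
    results: dict = {}
    sim = replace(config.sim, seed=config.seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # -- dating -------------------------------------------------------
        t0 = time.perf_counter()
        tree = demo_tree()
        catalog, presence_truth = gen_catalog(tree, sim, config.young_branches)
        from .simulate import gen_presence
        presence, _ = gen_presence(tree, sim)
        assigned = dating.date_catalog(tree, presence)
        dated = catalog.drop(columns=["branch", "age_class"]).merge(
            assigned.rename("branch").rename_axis("gene_id").reset_index(),
            on="gene_id")
        dated["age_class"] = [dating.classify_age(b, config.young_branches)
                              for b in dated["branch"]]
        io.write_tsv(presence.reset_index(), out / "presence.tsv")
        io.write_tsv(dated, out / "catalog.tsv")
        io.write_tsv(presence_truth, out / "truth" / "presence_truth.tsv")
        manifest.stage("dating", [str(out / "presence.tsv")],
                       [out / "presence.tsv", out / "catalog.tsv"],
                       time.perf_counter() - t0)
        results["catalog"] = dated

        # -- EST profiling --------------------------------------------------
        t0 = time.perf_counter()
        est_a, est_truth = gen_est_table(dated, sim, species="human")
        null_sim = replace(sim, young_fetal_enrichment=1.0)
        est_b, _ = gen_est_table(dated, null_sim, species="mouse")
        enrich = est.enrichment_table(est_a, est_b, dated,
                                      min_ests=config.min_ests,
                                      n_boot=config.bootstrap_reps,
                                      seed=config.seed)
        io.write_tsv(est_a, out / "est_human.tsv")
        io.write_tsv(est_b, out / "est_mouse.tsv")
        io.write_tsv(enrich, out / "est_enrichment.tsv")
        io.write_tsv(est_truth, out / "truth" / "est_truth.tsv")
        manifest.stage("est_profiling",
                       [str(out / "est_human.tsv"), str(out / "est_mouse.tsv"),
                        str(out / "catalog.tsv")],
                       [out / "est_enrichment.tsv"], time.perf_counter() - t0)
        results["est_enrichment"] = enrich

        # -- quantification / DE -------------------------------------------
        t0 = time.perf_counter()
        transcripts, mapp_truth = gen_transcripts(dated, sim)
        reads, drawn_counts, de_truth = gen_rnaseq(dated, transcripts, sim)
        lengths = quant.effective_length(transcripts, k=config.k)
        retained, excluded = quant.filter_short_mappable(
            dated, lengths, min_bp=config.min_mappable)
        asg = {grp: quant.assign_reads((s for _, s in reads[grp]), transcripts,
                                       k=config.k) for grp in reads}
        counts1 = asg["fetal"].counts.loc[retained]
        counts2 = asg["adult"].counts.loc[retained]
        calls = quant.de_table(counts1, asg["fetal"].total_assigned,
                               counts2, asg["adult"].total_assigned,
                               fdr=config.fdr, labels=("fetal", "adult"))
        expr = pd.DataFrame({
            "gene_id": retained,
            "rpmk_fetal": [quant.rpmk(counts1[g], lengths[g],
                                      asg["fetal"].total_assigned)
                           if lengths[g] > 0 else np.nan for g in retained],
            "rpmk_adult": [quant.rpmk(counts2[g], lengths[g],
                                      asg["adult"].total_assigned)
                           if lengths[g] > 0 else np.nan for g in retained],
        })
        io.write_transcripts(transcripts, out / "transcripts.fa")
        io.write_tsv(pd.DataFrame({"gene_id": list(lengths),
                                   "effective_length": list(lengths.values())}),
                     out / "effective_length.tsv")
        io.write_tsv(calls, out / "de_calls.tsv")
        io.write_tsv(expr, out / "rpmk.tsv")
        io.write_tsv(de_truth, out / "truth" / "de_truth.tsv")
        io.write_tsv(mapp_truth, out / "truth" / "mappability_truth.tsv")
        manifest.stage("expression_quant",
                       [str(out / "transcripts.fa"), str(out / "catalog.tsv")],
                       [out / "effective_length.tsv", out / "de_calls.tsv",
                        out / "rpmk.tsv"], time.perf_counter() - t0,
                       note=f"{len(excluded)} duplicated genes excluded for "
                            f"mappable region < {config.min_mappable} bp")
        results["de_calls"] = calls
        results["excluded_short_mappable"] = excluded

        # -- age x bias enrichment -----------------------------------------
        t0 = time.perf_counter()
        biased = calls[calls["direction"] != quant.UNBIASED]
        bt = enrichment.bias_table(biased, dated)
        prof = enrichment.branch_profile(calls, dated, tree.n_branches,
                                         up_label="fetal", down_label="adult")
        cat_bias = dated.merge(biased[["gene_id", "direction"]], on="gene_id")
        young = set(config.young_branches)
        age_of = lambda b: "young" if b in young else "old"
        cluster_tables = {}
        for cutoff in config.cluster_cutoffs:
            try:
                cluster_tables[cutoff] = enrichment.cluster_bias_table(
                    cat_bias, cutoff, age_of)
            except enrichment.EnrichmentError as exc:
                log.warning("cluster FET at cutoff %d undefined: %s", cutoff, exc)
        bias_out = bt.counts.reset_index()
        bias_out["fet_p"] = bt.p
        io.write_tsv(bias_out, out / "bias_table.tsv")
        io.write_tsv(prof, out / "branch_profile.tsv")
        manifest.stage("age_enrichment",
                       [str(out / "de_calls.tsv"), str(out / "catalog.tsv")],
                       [out / "bias_table.tsv", out / "branch_profile.tsv"],
                       time.perf_counter() - t0)
        results["bias_table"] = bt
        results["branch_profile"] = prof
        results["cluster_tables"] = cluster_tables

        # -- selection ------------------------------------------------------
        t0 = time.perf_counter()
        mk, mk_truth = gen_mk_counts(sim.gamma_values, sim.theta_s, sim.theta_r,
                                     sim.tau, sim.n_sample, config.seed,
                                     genes_per_gamma=5)
        rows = []
        for _, r in mk.iterrows():
            counts = selection.MKCounts(dn=r["dn"], ds=r["ds"], pn=r["pn"],
                                        ps=r["ps"], n_sample=r["n_sample"])
            try:
                fet_p, ni, alpha = selection.mk_fet(counts)
            except selection.SelectionError:
                fet_p = ni = alpha = np.nan
            prf = selection.prf_gamma(counts)
            rows.append({"gene_id": r["gene_id"], "ds": r["ds"], "ps": r["ps"],
                         "dn": r["dn"], "pn": r["pn"], "fet_p": fet_p,
                         "ni": ni, "alpha": alpha, "gamma_hat": prf.gamma_hat,
                         "p": prf.p, "status": prf.status})
        sel = pd.DataFrame(rows)
        flagged = selection.classify_positively_selected(
            sel.dropna(subset=["p"]), threshold=config.ps_threshold)
        flagged = flagged[flagged["gamma_hat"] > 0]
        io.write_tsv(mk, out / "mk_counts.tsv")
        io.write_tsv(sel, out / "selection.tsv")
        io.write_tsv(mk_truth, out / "truth" / "mk_truth.tsv")
        manifest.stage("selection", [str(out / "mk_counts.tsv")],
                       [out / "selection.tsv"], time.perf_counter() - t0)
        results["selection"] = sel
        results["positively_selected"] = flagged

        manifest.data["warnings"] = [str(w.message) for w in caught]
    manifest.write(out / "manifest.json")
    results["manifest"] = manifest.data
    return results


def summarize(results: dict) -> pd.DataFrame:
    """One headline row per analysis with its test name and threshold."""
    rows = []
    if "est_enrichment" in results:
        enr = results["est_enrichment"]
        brain = enr[enr["tissue"] == "brain"]
        if len(brain):
            r = brain.iloc[0]
            rows.append({
                "analysis": "EST young-gene brain enrichment (species a vs b)",
                "statistic": "two-sided FET, Bonferroni over tissues",
                "value": f"{r['proportion_a']:.3f} vs {r['proportion_b']:.3f}",
                "p": r["bonferroni_p"], "threshold": 0.05,
                "significant": r["bonferroni_p"] < 0.05,
                "family_size": int(r["m_tests"]),
            })
    if "bias_table" in results:
        bt = results["bias_table"]
        rows.append({
            "analysis": "age x fetal/adult bias (gene level)",
            "statistic": "two-sided FET", "value": str(bt.counts.to_numpy().tolist()),
            "p": bt.p, "threshold": 0.05, "significant": bt.p < 0.05,
            "family_size": 1,
        })
    for cutoff, ct in results.get("cluster_tables", {}).items():
        rows.append({
            "analysis": f"age x bias at cluster level (cutoff {cutoff:,} bp)",
            "statistic": "two-sided FET", "value": str(ct.counts.to_numpy().tolist()),
            "p": ct.p, "threshold": 0.05, "significant": ct.p < 0.05,
            "family_size": 1,
        })
    if "positively_selected" in results:
        sel = results["selection"]
        n_est = int(sel["p"].notna().sum())
        rows.append({
            "analysis": "positively selected genes (PRF gamma > 0)",
            "statistic": "chi-square(1) LRT", "value": len(results["positively_selected"]),
            "p": np.nan, "threshold": 0.1, "significant": np.nan,
            "family_size": n_est,
        })
    return pd.DataFrame(rows, columns=["analysis", "statistic", "value", "p",
                                       "threshold", "significant", "family_size"])
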