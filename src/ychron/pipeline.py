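"""End-to-end orchestration from a YAML config.

Stages run in dependency order: input loading (or simulation), tree
building, haplotype-identity counts, rho dating of clades, STR dating and
SNP/STR comparison, branch-length heterogeneity, recurrence summary and
the singleton-enrichment selection test. Optional stages degrade
gracefully (a missing STR table skips the STR stages with a logged note);
a missing mandatory input aborts before any stage runs. The report is
deterministic given identical inputs and seeds.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dating_snp, dating_str, phylogeny, population_tests, \
    selection_recurrence, synthetic
from .formats import (HaplotypeMatrix, read_haploid_vcf, read_metadata,
                      read_str_table, write_events, write_newick)

log = logging.getLogger("ychron")

__all__ = ["RunReport", "run_full_analysis"]


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)  # name -> status
    params: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not serializable: {type(o)}")
        return json.dumps(
            {"stages": self.stages, "params": self.params,
             "input_digests": self.input_digests, "outputs": self.outputs,
             "summary": self.summary},
            indent=2, sort_keys=True, default=default)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_analysis(config: str | dict, output_dir: str | None = None
                      ) -> RunReport:
    """Execute the full pipeline from a YAML config path or dict."""
    if isinstance(config, str):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    report = RunReport()
    out_dir = output_dir or cfg.get("output_dir")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    # ---- inputs (validated before any stage runs) ----
    inputs = cfg.get("inputs", {})
    sim_cfg = cfg.get("simulate")
    if not sim_cfg and "vcf" not in inputs:
        raise ValueError("config needs either 'simulate' or inputs.vcf")
    for key, path in inputs.items():
        if not os.path.exists(path):
            raise FileNotFoundError(f"input {key!r}: {path}")
        report.input_digests[key] = _digest(path)

    rates = dating_snp.RateModel(**cfg.get("rates", {}))
    report.params = {
        "seed": cfg.get("seed"),
        "snp_rate": rates.snp_rate, "snp_rate_ci": list(rates.snp_rate_ci),
        "target_length": rates.target_length,
        "generation_time": rates.generation_time,
    }

    context = None
    strs = meta = None
    str_root = None
    if sim_cfg:
        sim_cfg = dict(sim_cfg)
        sim_cfg.setdefault("seed", cfg.get("seed", 0))
        sc = synthetic.SimConfig(**sim_cfg)
        ds = synthetic.simulate_dataset(sc)
        matrix, strs, meta, context = ds.matrix, ds.strs, ds.meta, ds.context
        str_root = ds.str_root
        report.params["simulate"] = {"n": sc.n, "seed": sc.seed,
                                     "genealogy": sc.genealogy,
                                     "sites_model": sc.sites_model}
        report.stages["simulate"] = "ok"
    else:
        matrix = read_haploid_vcf(inputs["vcf"])
        anc = cfg.get("ancestral_source", "ref-is-ancestral")
        matrix = phylogeny.polarize(matrix, anc)
        if "str" in inputs:
            strs = read_str_table(inputs["str"])
        if "meta" in inputs:
            meta = read_metadata(inputs["meta"])
        report.stages["load"] = "ok"

    # ---- tree ----
    tree, compat = phylogeny.build_tree(matrix)
    report.stages["build_tree"] = "ok"
    report.summary["n_samples"] = matrix.n_samples
    report.summary["n_sites"] = matrix.n_sites
    report.summary["n_recurrent_sites"] = compat.n_recurrent
    if out_dir:
        nwk = os.path.join(out_dir, "tree.nwk")
        with open(nwk, "w") as fh:
            fh.write(write_newick(tree) + "\n")
        ev = os.path.join(out_dir, "events.tsv")
        write_events(tree, ev)
        report.outputs["tree"] = nwk
        report.outputs["events"] = ev

    # ---- identity ----
    ident = phylogeny.identical_groups(matrix)
    report.summary["snp_identity"] = {
        "n_haplotypes": ident.n_classes, "n_identical_pairs": ident.n_pairs,
        "n_identical_trios": ident.n_trios}
    report.stages["identity"] = "ok"

    # ---- SNP dating ----
    min_tips = int(cfg.get("min_clade_tips", 3))
    clades = cfg.get("clades")
    if clades is None:
        clades = [n.id for n in tree.preorder()
                  if not n.is_tip and tree.n_descendant_tips(n.id) >= min_tips]
    estimates = [dating_snp.date_clade(tree, c, rates) for c in clades]
    date_table = pd.DataFrame([{
        "clade": e.clade_id, "n": e.n_tips, "rho": e.rho, "sigma": e.sigma,
        "tmrca_ka": e.tmrca_ka, "range_lo_ka": e.tmrca_range_ka[0],
        "range_hi_ka": e.tmrca_range_ka[1]} for e in estimates])
    report.summary["clade_dates"] = date_table.to_dict(orient="records")
    report.stages["date_snp"] = "ok"
    if out_dir:
        p = os.path.join(out_dir, "clade_dates.tsv")
        date_table.to_csv(p, sep="\t", index=False)
        report.outputs["clade_dates"] = p

    # ---- STR dating + comparison ----
    if strs is not None:
        het_cfg = cfg.get("str_dating", {})
        subsets = het_cfg.get("subsets", ["set21", "set17", "set13"])
        regimes = het_cfg.get("regimes", ["evolutionary", "pedigree"])
        str_estimates = []
        for e in estimates:
            members = [s for s in tree.clade_samples(e.clade_id)
                       if s in strs.profiles.index]
            if len(members) < 2:
                continue
            for subset in subsets:
                roots = {"modal": dating_str.modal_haplotype(
                    strs, members, subset)}
                if str_root is not None:
                    roots["ancestral"] = dating_str.RootHaplotype(
                        dict(str_root), "ancestral")
                for prov, root in roots.items():
                    for method, fn in (("asd", dating_str.asd),
                                       ("rho", dating_str.rho_str)):
                        stat = fn(strs, members, root, subset)
                        for regime in regimes:
                            str_estimates.append(dating_str.tmrca_str(
                                stat, method, subset, regime, rates,
                                clade_id=e.clade_id, root_provenance=prov))
        comparison = dating_str.compare_estimates(estimates, str_estimates)
        report.summary["str_comparison"] = comparison.to_dict(
            orient="records")
        report.stages["date_str"] = "ok"
        if out_dir:
            p = os.path.join(out_dir, "str_comparison.tsv")
            comparison.to_csv(p, sep="\t", index=False)
            report.outputs["str_comparison"] = p
    else:
        report.stages["date_str"] = "skipped (no STR table)"
        log.info("STR table absent; skipping STR stages")

    # ---- heterogeneity ----
    if meta is not None:
        counts = phylogeny.mutations_to_root(tree)
        labels = {m.sample_id: (m.haplogroup or "NA") for m in meta}
        het_cfg = cfg.get("heterogeneity", {})
        shared = [s for s in counts.index if s in labels]
        try:
            results = population_tests.subsampled_pairwise_test(
                counts.loc[shared].to_numpy(),
                [labels[s] for s in shared],
                k=int(het_cfg.get("k", 10)),
                replicates=int(het_cfg.get("replicates", 100)),
                alpha=float(het_cfg.get("alpha", 0.05)),
                seed=int(cfg.get("seed", 0)))
            report.summary["heterogeneity"] = [{
                "pair": list(r.pair),
                "proportion_significant": r.proportion_significant,
                "flagged": r.flagged} for r in results]
            report.stages["heterogeneity"] = "ok"
        except ValueError as exc:
            report.stages["heterogeneity"] = f"skipped ({exc})"
        tissues = {m.sample_id: m.tissue_source for m in meta}
        by_tissue = {}
        for s in shared:
            by_tissue.setdefault(tissues[s], []).append(counts[s])
        usable = [v for v in by_tissue.values() if len(v) >= 2]
        if len(usable) >= 2:
            try:
                f, p = population_tests.anova_one_way(*usable)
                report.summary["tissue_anova"] = {"F": f, "p": p}
            except ValueError as exc:
                report.summary["tissue_anova"] = {"note": str(exc)}
    else:
        report.stages["heterogeneity"] = "skipped (no metadata)"

    # ---- recurrence ----
    rec = selection_recurrence.recurrence_summary(compat, context)
    report.summary["recurrence"] = {
        "n_recurrent": rec.n_recurrent, "total_events": rec.total_events,
        "fraction_recurrent": rec.fraction_recurrent,
        "cpg_fraction": rec.cpg_fraction}
    report.stages["recurrence"] = "ok"

    # ---- selection ----
    if "annotation" in inputs:
        variants = selection_recurrence.read_annotated_variants(
            inputs["annotation"])
        n_singletons = int(((matrix.calls == 1).sum(axis=0) == 1).sum())
        background = tuple(cfg.get("selection", {}).get(
            "background", (n_singletons, matrix.n_sites)))
        predictors = sorted({p for v in variants for p in v.damaging})
        sel = {}
        for pred in predictors:
            try:
                r = selection_recurrence.singleton_enrichment(
                    variants, pred, background)
                sel[pred] = {"p": r.p_value, "chi2": r.statistic,
                             "direction": r.direction}
            except ValueError as exc:
                sel[pred] = {"note": str(exc)}
        report.summary["selection"] = sel
        report.stages["selection"] = "ok"
    else:
        report.stages["selection"] = "skipped (no annotation)"

    if out_dir:
        p = os.path.join(out_dir, "report.json")
        with open(p, "w") as fh:
            fh.write(report.to_json() + "\n")
        report.outputs["report"] = p
    return report
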