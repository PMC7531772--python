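"""End-to-end orchestration of the comparative analysis.

One call runs the whole study on either real input files or a simulated
dataset: curated-gene-set mapping, clade enrichment/depletion scans,
phylogenetic signal of repertoire size and genome size, the genome-size
regression control, Dollo histories of domains and orthogroups, the CCA
association test, and the per-orthogroup PGLS domain scan. Every stage's
tabular output is written next to a machine-readable JSON report carrying a
provenance block (seed, config hash, input digests, package version). The
report contains no timestamp, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import blomberg_k, ols_r2, pagel_lambda, pgls_scan
from .dollo import dollo_reconstruct, gain_loss_table, write_ancestral_states, write_event_table
from .enrichment import clade_enrichment_scan, depletion_contrast, enrichment_table
from .ordination import cca_permutation_test
from .phylo import read_clade_partition, read_newick
from .repertoire import (
    CountMatrix,
    map_gene_set,
    read_count_matrix,
    read_domain_architectures,
    read_gene_set_map,
    repertoire_size,
    tabulate_domain_counts,
)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline", "report_render", "load_report"]

DEFAULTS = {
    "clade_a": ["Lophotrochozoa", "Deuterostomia"],
    "clade_b": ["Ecdysozoa"],
    "fdr": 0.1,
    "n_perm_enrichment": 9_999,
    "n_perm_cca": 999,
    "pseudocount": 1.0,
    "pgls_transform": "log1p",
    "pgls_adjust": "global",
    "pgls_alpha": 0.05,
    "focal_tag": "focal",
}


@dataclass
class PipelineReport:
    """Per-stage results plus provenance; serializes losslessly to JSON."""

    stages: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def load_report(path) -> PipelineReport:
    with open(path) as fh:
        payload = json.load(fh)
    return PipelineReport(stages=payload["stages"], provenance=payload["provenance"])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _load_inputs(cfg: dict, seed: int):
    """Assemble (tree, partition, tagged matrix, summary, profile, log_gs, truth)."""
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        sim = SimulationConfig(**sim_kwargs)
        ds = simulate_dataset(sim)
        matrix, summary = map_gene_set(
            ds.gene_set, ds.counts, tag=DEFAULTS["focal_tag"]
        )
        return ds.tree, ds.partition, matrix, summary, ds.domain_profile, ds.log_genome_size, ds.truth, None
    inputs = cfg["inputs"]
    paths = {k: Path(v) for k, v in inputs.items()}
    tree = read_newick(paths["tree"])
    partition = read_clade_partition(paths["clades"])
    partition.validate_against(
        tree, require_monophyly=cfg.get("require_monophyly", True)
    )
    matrix = read_count_matrix(paths["counts"], taxa=tree.tip_labels)
    gene_set = read_gene_set_map(paths["geneset"])
    matrix, summary = map_gene_set(gene_set, matrix, tag=DEFAULTS["focal_tag"])
    records = read_domain_architectures(paths["domains"])
    profile = tabulate_domain_counts(records)
    profile = profile.reindex(tree.tip_labels, fill_value=0)
    log_gs = None
    if "genome_size" in paths:
        gs = pd.read_csv(paths["genome_size"], sep="\t", index_col=0).iloc[:, 0]
        log_gs = gs.astype(float)
    digests = {k: _digest(p) for k, p in paths.items()}
    return tree, partition, matrix, summary, profile, log_gs, None, digests


def _signal_block(y: pd.Series, tree) -> dict:
    k = blomberg_k(y, tree)
    lam = pagel_lambda(y, tree)
    return {
        "blomberg_k": round(float(k.estimate), 6),
        "pagel_lambda": round(float(lam.estimate), 6),
        "lambda_loglik": round(float(lam.loglik), 6),
    }


def run_pipeline(config, outdir) -> PipelineReport:
    """Run every analysis stage; write stage TSVs and the JSON report.

    *config* is a YAML path or a dict with either a ``simulate`` block
    (keyword arguments of :class:`repevo.simulate.SimulationConfig`) or an
    ``inputs`` block of file paths (tree, counts, domains, geneset, clades,
    optionally genome_size). Stage errors abort with the stage named.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    opts = {**DEFAULTS, **{k: v for k, v in cfg.items() if k in DEFAULTS}}
    stages: dict = {}
    t0 = time.perf_counter()

    stage = "load"
    try:
        (tree, partition, matrix, summary, profile, log_gs, truth,
         digests) = _load_inputs(cfg, seed)
        stage = "gene_set"
        stages["gene_set"] = {
            "total_genes": summary.total,
            "unmapped_genes": summary.unmapped,
            "mapped_genes": summary.mapped,
            "distinct_orthogroups": summary.distinct,
            "genes_sharing_orthogroup": summary.shared,
        }
        focal_ogs = sorted(matrix.tagged(opts["focal_tag"]))

        stage = "enrichment"
        focal_matrix = CountMatrix(
            matrix.data[focal_ogs], tags={opts["focal_tag"]: focal_ogs}
        )
        results = clade_enrichment_scan(
            focal_matrix, partition, opts["clade_a"], opts["clade_b"],
            n_perm=opts["n_perm_enrichment"], seed=seed + 1, alpha=opts["fdr"],
        )
        etable = enrichment_table(results)
        etable.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        stages["enrichment"] = {
            "n_focal": len(focal_ogs),
            "n_enriched_in_a": int((etable.direction == "enriched_in_a").sum()),
            "n_depleted_in_a": int((etable.direction == "depleted_in_a").sum()),
            "fdr": opts["fdr"],
        }

        stage = "depletion"
        dep = depletion_contrast(
            matrix, partition, opts["clade_a"], opts["clade_b"],
            focal=opts["focal_tag"], pseudocount=opts["pseudocount"],
        )
        dep.ratios.to_csv(outdir / "depletion.tsv", sep="\t", index=False)
        stages["depletion"] = {
            "wilcoxon_w": dep.w_statistic,
            "p": dep.p,
            "n_focal": dep.n_focal,
            "n_background": dep.n_background,
        }

        stage = "signal"
        rep_size = repertoire_size(matrix, opts["focal_tag"])
        stages["signal"] = {"repertoire_size": _signal_block(rep_size.astype(float), tree)}
        if log_gs is not None:
            stages["signal"]["genome_size"] = _signal_block(log_gs, tree)

        stage = "genome_size_control"
        if log_gs is not None:
            slope, r2, p = ols_r2(rep_size.loc[log_gs.index].astype(float), log_gs)
            stages["genome_size_control"] = {
                "slope": round(slope, 6), "r2": round(r2, 6), "p": float(p),
            }

        stage = "dollo"
        domain_presence = (profile.loc[tree.tip_labels] > 0).astype(int)
        recon_dom = dollo_reconstruct(tree, domain_presence)
        write_event_table(recon_dom, outdir / "dollo_domains.tsv")
        og_presence = (matrix.data.loc[tree.tip_labels, focal_ogs] > 0).astype(int)
        recon_og = dollo_reconstruct(tree, og_presence)
        write_event_table(recon_og, outdir / "dollo_orthogroups.tsv")
        write_ancestral_states(recon_og, outdir / "dollo_ancestral_states.tsv")
        events = gain_loss_table(recon_og)
        loss_tips = partition.tips(opts["clade_b"])
        loss_clade_nodes = {
            tree.node_label(nd)
            for nd in tree.mrca(loss_tips).preorder_iter()
        } if len(loss_tips) > 1 else set(loss_tips)
        losses = events[events.event == "loss"]
        stages["dollo"] = {
            "domain_losses": int((gain_loss_table(recon_dom).event == "loss").sum()),
            "orthogroup_losses": int(len(losses)),
            "orthogroup_losses_in_clade_b": int(
                losses.branch.isin(loss_clade_nodes).sum()
            ),
        }

        stage = "cca"
        Y = matrix.data.loc[tree.tip_labels, focal_ogs]
        cca = cca_permutation_test(
            Y, profile.loc[tree.tip_labels], n_perm=opts["n_perm_cca"], seed=seed + 2
        )
        stages["cca"] = {
            "pseudo_f": round(cca.pseudo_f, 6),
            "p": cca.p,
            "df_num": cca.df_num,
            "df_den": cca.df_den,
            "total_inertia": round(cca.total_inertia, 6),
            "constrained_inertia": round(cca.constrained_inertia, 6),
        }
        cca.site_scores.to_csv(outdir / "cca_site_scores.tsv", sep="\t",
                               index_label="taxon")
        cca.species_scores.to_csv(outdir / "cca_species_scores.tsv", sep="\t",
                                  index_label="orthogroup")
        cca.biplot_scores.to_csv(outdir / "cca_biplot_scores.tsv", sep="\t",
                                 index_label="constraint")

        stage = "pgls"
        covariates = None
        if log_gs is not None:
            covariates = log_gs.to_frame("genome_size")
        scan = pgls_scan(
            matrix, profile, tree, focal=opts["focal_tag"],
            covariates=covariates, transform=opts["pgls_transform"],
            adjust=opts["pgls_adjust"], alpha=opts["pgls_alpha"],
        )
        scan.to_csv(outdir / "pgls_scan.tsv", sep="\t", index=False)
        sig_ogs = scan.loc[scan.significant, "orthogroup"].unique()
        stages["pgls"] = {
            "n_orthogroups": len(focal_ogs),
            "n_significant_orthogroups": int(len(sig_ogs)),
            "alpha": opts["pgls_alpha"],
            "adjust": opts["pgls_adjust"],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    elapsed = time.perf_counter() - t0
    logger.info("pipeline finished in %.1fs", elapsed)
    provenance = {
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "n_taxa": tree.n_tips,
    }
    if digests is not None:
        provenance["input_digests"] = digests
    report = PipelineReport(stages=stages, provenance=provenance)
    report.write(outdir / "report.json")
    return report


def report_render(report: PipelineReport) -> str:
    """Human-readable markdown summary of a pipeline report."""
    s = report.stages
    lines = ["# Gene-repertoire evolution report", ""]

    def stage(name):
        if name not in s:
            lines.append(f"- {name}: stage skipped")
            return None
        return s[name]

    g = stage("gene_set")
    if g:
        lines.append(
            f"- Gene set: {g['total_genes']} curated genes, "
            f"{g['unmapped_genes']} unmapped, {g['mapped_genes']} mapped into "
            f"{g['distinct_orthogroups']} distinct orthogroups "
            f"({g['genes_sharing_orthogroup']} sharing an orthogroup)."
        )
    e = stage("enrichment")
    if e:
        lines.append(
            f"- Enrichment: {e['n_enriched_in_a']} of {e['n_focal']} focal "
            f"orthogroups enriched and {e['n_depleted_in_a']} depleted in "
            f"clade A at FDR {e['fdr']}."
        )
    d = stage("depletion")
    if d:
        lines.append(
            f"- Depletion contrast: Wilcoxon rank-sum W = {d['wilcoxon_w']:.0f}, "
            f"P = {d['p']:.4g} (focal n={d['n_focal']} vs background "
            f"n={d['n_background']})."
        )
    sig = stage("signal")
    if sig:
        r = sig["repertoire_size"]
        lines.append(
            f"- Phylogenetic signal of repertoire size: Blomberg's K = "
            f"{r['blomberg_k']:.2f}; Pagel's lambda = {r['pagel_lambda']:.2f}."
        )
        if "genome_size" in sig:
            gs = sig["genome_size"]
            lines.append(
                f"- Phylogenetic signal of genome size: K = "
                f"{gs['blomberg_k']:.2f}; lambda = {gs['pagel_lambda']:.2f}."
            )
    gc = stage("genome_size_control")
    if gc:
        lines.append(
            f"- Genome-size control: repertoire size vs log genome size "
            f"r^2 = {gc['r2']:.2f} (P = {gc['p']:.3g})."
        )
    dl = stage("dollo")
    if dl:
        lines.append(
            f"- Dollo parsimony: {dl['orthogroup_losses']} orthogroup losses "
            f"({dl['orthogroup_losses_in_clade_b']} on loss-clade branches); "
            f"{dl['domain_losses']} domain losses."
        )
    c = stage("cca")
    if c:
        lines.append(
            f"- CCA: pseudo-F({c['df_num']},{c['df_den']}) = "
            f"{c['pseudo_f']:.2f}, P = {c['p']:.4g}."
        )
    p = stage("pgls")
    if p:
        lines.append(
            f"- PGLS scan: {p['n_significant_orthogroups']} of "
            f"{p['n_orthogroups']} focal orthogroups predicted by at least "
            f"one domain (q < {p['alpha']}, {p['adjust']} adjustment)."
        )
    lines.append("")
    pv = report.provenance
    lines.append(
        f"Provenance: seed {pv['seed']}, config {pv['config_hash']}, "
        f"version {pv['version']}, {pv['n_taxa']} taxa."
    )
    return "\n".join(lines)
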