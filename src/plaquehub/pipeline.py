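"""End-to-end orchestration: simulate/read inputs, run every stage, write TSVs.

Stage functions are plain functions over in-memory objects plus an output
directory; the CLI subcommands call the same functions the orchestrator
does, so a subcommand re-run on the orchestrated run's intermediate files
reproduces the orchestrated outputs byte for byte.  All randomness flows
from the single config seed; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, diagnostics, diffexpr, enrichment, immune, io_formats, ppi, proximity, synthetic
from .errors import InputError, PlaquehubError

log = logging.getLogger("plaquehub")


class PipelineStageError(PlaquehubError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SimulateParams:
    """Synthetic study design: a desk-scale analogue of a 4-vs-4 plaque cohort."""

    n_genes: int = 300
    n_case: int = 4
    n_control: int = 4
    n_de: int = 60
    effect: float = 2.0
    sigma: float = 0.5
    n_nodes: int = 120
    module_sizes: tuple[int, ...] = (8, 5, 4)
    p_background: float = 0.01
    n_signatures: int = 28
    genes_per_sig: int = 5
    coupling: float = -0.9
    n_proximal_drugs: int = 5
    n_random_drugs: int = 40
    targets_per_drug: int = 4


@dataclass
class RunConfig:
    """Thresholds default to the study's printed settings."""

    seed: int = 1
    out_dir: str = "plaquehub_out"
    # input files; None means simulate
    expression: str | None = None
    labels: str | None = None
    edges: str | None = None
    signatures: str | None = None
    drug_targets: str | None = None
    disease_genes: str | None = None
    simulate: SimulateParams = field(default_factory=SimulateParams)
    # stage thresholds
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    min_confidence: int = 400
    mcode: ppi.McodeParams = field(default_factory=ppi.McodeParams)
    top_k_hubs: int = 5
    r_min: float = 0.9
    p_max: float = 0.001
    d_max: float = 1.2
    proximity_fdr_max: float = 0.05
    n_permutations: int = 10_000
    ssgsea_alpha: float = 0.25
    svm_C: float = 1.0

    def validate(self) -> None:
        if self.lfc_min <= 0 or self.fdr_max <= 0 or self.r_min <= 0 or self.p_max <= 0:
            raise InputError("thresholds must be positive")
        if not 0 <= self.min_confidence <= 1000:
            raise InputError("min_confidence must lie in [0, 1000]")
        if self.n_permutations < 1:
            raise InputError("n_permutations must be >= 1")
        if self.d_max <= 0 or self.proximity_fdr_max <= 0:
            raise InputError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulateParams(**{k: tuple(v) if k == "module_sizes" else v
                                for k, v in raw.pop("simulate", {}).items()})
        mcode = ppi.McodeParams(**raw.pop("mcode", {}))
        cfg = cls(simulate=sim, mcode=mcode, **raw)
        cfg.validate()
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"]["module_sizes"] = list(d["simulate"]["module_sizes"])
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def simulate_inputs(cfg: RunConfig, out_dir: Path) -> dict[str, Path]:
    """Generate and write the five input files plus the ground truth."""
    p = cfg.simulate
    expr, truth_e = synthetic.synth_expression(
        p.n_genes, p.n_case, p.n_control, p.n_de, p.effect, p.sigma, cfg.seed
    )
    edges, truth_g = synthetic.synth_ppi(p.n_nodes, list(p.module_sizes), p.p_background, cfg.seed)
    hub = truth_g.hub_gene
    sigs, expr = synthetic.synth_signatures(
        expr, hub, p.n_signatures, p.genes_per_sig, p.coupling, cfg.seed
    )
    nodes = sorted(set(edges.records["gene_a"]) | set(edges.records["gene_b"]))
    disease = sorted({g for g, _ in truth_e.de_genes} | set(nodes[: p.n_nodes // 3]))
    # proximal drugs are planted around the hub's module: the neighbourhood
    # the anchor-seeded proximity screen is meant to rediscover
    hub_module = max(truth_g.planted_modules, key=len) & set(nodes)
    drugs, truth_d = synthetic.synth_drug_targets(
        edges, hub_module, p.n_proximal_drugs, p.n_random_drugs,
        p.targets_per_drug, cfg.seed,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "labels": out_dir / "labels.tsv",
        "edges": out_dir / "ppi_edges.tsv",
        "signatures": out_dir / "signatures.gmt",
        "drug_targets": out_dir / "drug_targets.tsv",
        "disease_genes": out_dir / "disease_genes.txt",
    }
    io_formats.write_expression(expr, paths["expression"], paths["labels"])
    io_formats.write_edge_list(edges, paths["edges"])
    io_formats.write_gmt(sigs, paths["signatures"])
    io_formats.write_drug_targets(drugs, paths["drug_targets"])
    io_formats.write_gene_list(disease, paths["disease_genes"])
    truth = {
        "de_genes": truth_e.to_dict()["de_genes"],
        "planted_modules": truth_g.to_dict()["planted_modules"],
        "hub_gene": hub,
        "proximal_drugs": truth_d.to_dict()["proximal_drugs"],
        "coupling": p.coupling,
    }
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------- stages


def stage_degs(expr, disease_genes, cfg: RunConfig, out_dir: Path):
    table, params = diffexpr.fit_moderated_t(expr)
    _write_tsv(table, out_dir / "deg_table.tsv")
    degs = diffexpr.screen_degs(table, cfg.lfc_min, cfg.fdr_max)
    related = sorted(diffexpr.intersect_sets(degs, disease_genes))
    io_formats.write_gene_list(related, out_dir / "as_related_degs.txt")
    return table, params, degs, related


def stage_enrich(related, annotations, universe, out_dir: Path):
    ora = enrichment.ora_test(related, annotations, universe)
    _write_tsv(ora, out_dir / "ora_results.tsv")
    return ora


def stage_network(edges, cfg: RunConfig, out_dir: Path):
    g = ppi.build_graph(edges, cfg.min_confidence)
    modules = ppi.mcode_find_clusters(g, cfg.mcode)
    rows = [
        (i + 1, round(score, 6), seed, len(cluster), ";".join(sorted(cluster)))
        for i, (cluster, score, seed) in enumerate(
            zip(modules.clusters, modules.scores, modules.seed_nodes)
        )
    ]
    df = pd.DataFrame(rows, columns=["cluster", "score", "seed", "size", "members"]).set_index("cluster")
    _write_tsv(df, out_dir / "clusters.tsv")
    return g, modules


def stage_hubs(g, cfg: RunConfig, out_dir: Path):
    topo = ppi.topology_table(g)
    _write_tsv(topo, out_dir / "topology.tsv")
    hubs = ppi.rank_hubs(ppi.centralities(g), k=min(cfg.top_k_hubs, g.number_of_nodes()))
    io_formats.write_gene_list(hubs, out_dir / "hub_genes.txt")
    return topo, hubs


def stage_diagnose(expr, genes, cfg: RunConfig, out_dir: Path):
    labels = np.array([1 if expr.groups[s] == io_formats.CASE else 0 for s in expr.sample_ids])
    rows = []
    usable = [g for g in genes if g in expr.data.index]
    for gene in usable:
        vals = expr.data.loc[gene].to_numpy(dtype=float)
        _, p = diagnostics.wilcoxon_exact(vals[labels == 1], vals[labels == 0])
        roc = diagnostics.roc_auc(vals, labels)
        rows.append((gene, p, roc.auc, max(roc.auc, 1 - roc.auc)))
    diag = pd.DataFrame(
        rows, columns=["gene", "wilcoxon_p", "auc", "direction_free_auc"]
    ).set_index("gene")
    _write_tsv(diag, out_dir / "diagnostics.tsv")
    loocv = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample"))
    loocv_auc = float("nan")
    if usable:
        feats = expr.data.loc[usable].to_numpy(dtype=float).T
        scores = diagnostics.loocv_scores(feats, labels, C=cfg.svm_C)
        loocv["score"] = scores
        loocv["label"] = labels
        loocv_auc = diagnostics.roc_auc(scores, labels).auc
    _write_tsv(loocv, out_dir / "svm_loocv.tsv")
    return diag, loocv_auc


def stage_immune(expr, sigs, anchor, cfg: RunConfig, out_dir: Path):
    scores = immune.ssgsea_scores(expr, sigs, alpha=cfg.ssgsea_alpha)
    _write_tsv(scores.rename_axis("signature"), out_dir / "ssgsea_scores.tsv")
    agg = immune.immune_score(scores)
    with_agg = pd.concat([scores, agg.to_frame("IMMUNE_SCORE").T])
    corr = immune.correlate_with_scores(expr, anchor, with_agg)
    _write_tsv(corr, out_dir / "correlations.tsv")
    related = sorted(immune.related_gene_set(expr, anchor, cfg.r_min, cfg.p_max))
    io_formats.write_gene_list(related, out_dir / "related_genes.txt")
    return scores, corr, related


def stage_proximity(g, anchor_set, drugs, cfg: RunConfig, out_dir: Path):
    results = proximity.drug_proximity(
        g, anchor_set, drugs,
        n_permutations=cfg.n_permutations, seed=cfg.seed,
        d_max=cfg.d_max, fdr_max=cfg.proximity_fdr_max,
    )
    _write_tsv(results, out_dir / "proximity.tsv")
    screened = proximity.screen_drugs(results, cfg.d_max, cfg.proximity_fdr_max)
    io_formats.write_gene_list(screened, out_dir / "screened_drugs.txt")
    density = proximity.distance_density_table(results)
    _write_tsv(density, out_dir / "distance_density.tsv")
    return results, screened


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write ``summary.json``."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if cfg.expression is None:
            paths = simulate_inputs(cfg, out_dir)
        else:
            required = ["expression", "labels", "edges", "signatures", "drug_targets", "disease_genes"]
            missing = [k for k in required if getattr(cfg, k) is None]
            if missing:
                raise InputError(f"missing input paths: {missing}")
            paths = {k: Path(getattr(cfg, k)) for k in required}
        expr = io_formats.read_expression(paths["expression"], paths["labels"])
        edges = io_formats.read_edge_list(paths["edges"])
        sigs = io_formats.read_gmt(paths["signatures"])
        drugs = io_formats.read_drug_targets(paths["drug_targets"])
        disease = io_formats.read_gene_list(paths["disease_genes"])

        stage = "degs"
        deg_table, mod_params, degs, related_degs = stage_degs(expr, disease, cfg, out_dir)
        stage = "enrich"
        ora = stage_enrich(related_degs or degs, sigs, expr.gene_ids, out_dir)
        stage = "network"
        g, modules = stage_network(edges, cfg, out_dir)
        stage = "hubs"
        topo, hubs = stage_hubs(g, cfg, out_dir)
        stage = "diagnose"
        diag, loocv_auc = stage_diagnose(expr, hubs, cfg, out_dir)
        stage = "immune"
        anchor = next((h for h in hubs if h in expr.data.index), None)
        if anchor is None:
            raise InputError("no hub gene is measured on the expression matrix")
        scores, corr, related_genes = stage_immune(expr, sigs, anchor, cfg, out_dir)
        stage = "proximity"
        anchor_set = ({anchor} | set(related_genes)) & set(g.nodes)
        if not anchor_set:
            raise InputError("anchor-related set empty after network restriction")
        prox, screened = stage_proximity(g, anchor_set, drugs, cfg, out_dir)
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise PipelineStageError(stage, exc) from exc

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "n_genes": len(expr.gene_ids),
        "n_samples": len(expr.sample_ids),
        "n_degs": len(degs),
        "n_as_related_degs": len(related_degs),
        "n_enriched_sets_fdr": int((ora["fdr"] < cfg.fdr_max).sum()),
        "moderation": {
            "d0": mod_params.d0 if np.isfinite(mod_params.d0) else None,
            "s0_sq": mod_params.s0_sq,
            "fallback": mod_params.fallback,
        },
        "network_nodes": g.number_of_nodes(),
        "network_edges": g.number_of_edges(),
        "n_clusters": len(modules.clusters),
        "hub_genes": hubs,
        "anchor": anchor,
        "loocv_auc": loocv_auc if np.isfinite(loocv_auc) else None,
        "n_related_genes": len(related_genes),
        "anchor_set_size": len(anchor_set),
        "n_drugs": len(drugs),
        "n_screened_drugs": len(screened),
        "screened_drugs": screened,
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return summary


def hash_outputs(out_dir) -> dict[str, str]:
    """SHA-256 of every regular file under out_dir (for determinism checks)."""
    out = {}
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
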