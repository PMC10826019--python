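"""Seeded synthetic data with the statistical structure the pipeline assumes.

Each generator is a pure function of its arguments, including the seed.  A
single global seed feeds a named substream per generator, so regenerating
one input (say the PPI) never perturbs another (say the expression matrix).

The generators emulate, at desk scale, the study design the pipeline was
built for: two small groups of plaque samples (4 unstable vs 4 stable) with
log2-scale Gaussian expression and planted fold-changes, a protein network
with planted dense modules and a designated hub, immune/pathway signatures
whose member genes are negatively coupled to the hub, and drug target sets
planted at controlled distance from a disease gene set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import CASE, CONTROL, DrugTargetMap, EdgeTable, ExpressionMatrix, GeneSetCollection

# fixed substream ids: changing one generator's draws never shifts another's
_STREAMS = {"expression": 11, "ppi": 23, "drugs": 37, "signatures": 53}

MODULE_CONFIDENCE = 900  # planted edges sit above any plausible build threshold


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    de_genes: list[tuple[str, float]] = field(default_factory=list)
    planted_modules: list[set[str]] = field(default_factory=list)
    hub_gene: str | None = None
    proximal_drugs: list[str] = field(default_factory=list)
    coupling: float = 0.0

    def to_dict(self) -> dict:
        return {
            "de_genes": [[g, f] for g, f in self.de_genes],
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "hub_gene": self.hub_gene,
            "proximal_drugs": list(self.proximal_drugs),
            "coupling": self.coupling,
        }


def gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def synth_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    n_de: int,
    effect: float,
    sigma: float,
    seed: int,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 expression with planted symmetric fold-changes.

    Per-gene baselines are drawn once (N(baseline_mean, baseline_sd^2), a
    microarray-like log2 scale); sample noise is i.i.d. N(0, sigma^2).  The
    first ``n_de`` genes are shifted by +-``effect`` in the case group, half
    up and half down.  ``effect=0`` yields an empty truth list by convention.
    """
    if n_de > n_genes:
        raise ParameterError(f"n_de={n_de} exceeds n_genes={n_genes}")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if n_case < 2 or n_control < 2:
        raise ParameterError("need at least 2 samples per group")
    rng = _rng(seed, "expression")
    genes = [gene_name(i) for i in range(n_genes)]
    case_ids = [f"U{i + 1}" for i in range(n_case)]
    control_ids = [f"S{i + 1}" for i in range(n_control)]
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    vals = base[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_case + n_control))
    signs = np.ones(n_de)
    signs[n_de // 2 :] = -1.0
    if effect != 0:
        vals[:n_de, :n_case] += signs[:, None] * effect
    data = pd.DataFrame(
        vals, index=pd.Index(genes, name="gene"), columns=case_ids + control_ids
    )
    groups = {s: CASE for s in case_ids} | {s: CONTROL for s in control_ids}
    truth = SyntheticTruth(
        de_genes=[(genes[i], float(signs[i] * effect)) for i in range(n_de)]
        if effect != 0
        else []
    )
    return ExpressionMatrix(data, groups), truth


def synth_ppi(
    n_nodes: int,
    module_sizes: list[int],
    p_background: float,
    seed: int,
) -> tuple[EdgeTable, SyntheticTruth]:
    """PPI edge list with planted cliques, a designated hub, and ER background.

    Modules occupy the first ``sum(module_sizes)`` genes, in order, each a
    clique at confidence 900.  The hub is the first member of the largest
    module and is additionally wired to one member of every other module,
    guaranteeing it the top degree and betweenness among module genes.
    Background edges are Erdos-Renyi(p_background) with confidence uniform
    in [400, 900].
    """
    if sum(module_sizes) > n_nodes:
        raise ParameterError("module sizes exceed n_nodes")
    if any(m < 3 for m in module_sizes):
        raise ParameterError("module size < 3 can never survive a 3-core filter")
    if not 0 <= p_background < 1:
        raise ParameterError("p_background must be in [0, 1)")
    rng = _rng(seed, "ppi")
    nodes = [gene_name(i) for i in range(n_nodes)]
    modules: list[set[str]] = []
    pos = 0
    for size in module_sizes:
        modules.append(set(nodes[pos : pos + size]))
        pos += size
    edge_conf: dict[tuple[str, str], int] = {}

    def put(a: str, b: str, conf: int) -> None:
        key = (a, b) if a < b else (b, a)
        edge_conf[key] = max(edge_conf.get(key, 0), conf)

    for mod in modules:
        for a, b in itertools.combinations(sorted(mod), 2):
            put(a, b, MODULE_CONFIDENCE)
    hub = None
    if modules:
        largest = max(modules, key=len)
        hub = sorted(largest)[0]
        for mod in modules:
            if mod is largest:
                continue
            put(hub, sorted(mod)[0], MODULE_CONFIDENCE)
    # ER background over all node pairs, skipping pairs already planted
    if p_background > 0:
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < p_background:
                key = (a, b)
                if key not in edge_conf:
                    edge_conf[key] = int(rng.integers(400, 901))
    recs = [(a, b, c) for (a, b), c in sorted(edge_conf.items())]
    df = pd.DataFrame(recs, columns=["gene_a", "gene_b", "confidence"])
    df["confidence"] = df["confidence"].astype(int)
    truth = SyntheticTruth(planted_modules=modules, hub_gene=hub)
    return EdgeTable(df), truth


def synth_drug_targets(
    network: EdgeTable,
    disease_set: set[str],
    n_proximal: int,
    n_random: int,
    targets_per_drug: int,
    seed: int,
) -> tuple[DrugTargetMap, SyntheticTruth]:
    """Drug target sets planted either near a disease set or uniformly.

    Proximal drugs sample their targets from the disease set plus its direct
    network neighbours, with at least one target inside the disease set
    itself (a drug that never touches the disease genes is not a planted
    positive); random drugs sample uniformly from all nodes.
    """
    rng = _rng(seed, "drugs")
    nodes: set[str] = set(network.records["gene_a"]) | set(network.records["gene_b"])
    disease = set(disease_set) & nodes
    if not disease:
        raise ParameterError("disease_set has no members on the network")
    neighbors: set[str] = set()
    for rec in network.records.itertuples(index=False):
        if rec.gene_a in disease:
            neighbors.add(rec.gene_b)
        if rec.gene_b in disease:
            neighbors.add(rec.gene_a)
    proximal_pool = sorted(disease | neighbors)
    all_pool = sorted(nodes)
    if targets_per_drug > len(proximal_pool) or targets_per_drug > len(all_pool):
        raise ParameterError("targets_per_drug exceeds the candidate pool")
    drugs: DrugTargetMap = {}
    proximal_ids = []
    disease_sorted = sorted(disease)
    for i in range(n_proximal):
        did = f"DRUG_P{i + 1:03d}"
        anchor = str(rng.choice(disease_sorted))
        rest = [n for n in proximal_pool if n != anchor]
        picked = {anchor} | set(rng.choice(rest, size=targets_per_drug - 1, replace=False))
        drugs[did] = picked
        proximal_ids.append(did)
    for i in range(n_random):
        did = f"DRUG_R{i + 1:03d}"
        drugs[did] = set(rng.choice(all_pool, size=targets_per_drug, replace=False))
    truth = SyntheticTruth(proximal_drugs=proximal_ids)
    return drugs, truth


def synth_signatures(
    expr: ExpressionMatrix,
    hub: str,
    n_signatures: int,
    genes_per_sig: int,
    coupling: float,
    seed: int,
) -> tuple[GeneSetCollection, ExpressionMatrix]:
    """Signatures whose member expression is coupled to the hub gene.

    Member genes' expression is rewritten as
    ``mean + sd * (coupling * z_hub + sqrt(1-coupling^2) * noise)`` where
    ``z_hub`` is the standardized hub profile, so the sample-level
    correlation between hub expression and each member is ``coupling`` in
    expectation (exactly ``coupling`` when |coupling| = 1).  Signature
    ssGSEA scores then correlate with the hub with the same sign.  Returns
    the collection together with the mutated copy of the matrix.
    """
    if hub not in expr.data.index:
        raise ParameterError(f"hub gene {hub!r} not in expression matrix")
    if not -1 <= coupling <= 0:
        raise ParameterError("coupling must lie in [-1, 0]")
    rng = _rng(seed, "signatures")
    data = expr.data.copy()
    hub_vec = data.loc[hub].to_numpy(dtype=float)
    hub_sd = hub_vec.std(ddof=0)
    z_hub = (hub_vec - hub_vec.mean()) / (hub_sd if hub_sd > 0 else 1.0)
    pool = [g for g in expr.gene_ids if g != hub]
    need = n_signatures * genes_per_sig
    if need > len(pool):
        raise ParameterError("not enough non-hub genes for the requested signatures")
    chosen = rng.choice(pool, size=need, replace=False)
    resid_scale = float(np.sqrt(max(0.0, 1.0 - coupling**2)))
    sets: dict[str, list[str]] = {}
    n_samp = data.shape[1]
    for k in range(n_signatures):
        members = list(chosen[k * genes_per_sig : (k + 1) * genes_per_sig])
        sets[f"SIG_{k + 1:02d}"] = members
        for g in members:
            row = data.loc[g].to_numpy(dtype=float)
            mu, sd = row.mean(), row.std(ddof=0)
            sd = sd if sd > 0 else 1.0
            noise = rng.normal(size=n_samp)
            data.loc[g] = mu + sd * (coupling * z_hub + resid_scale * noise)
    collection = GeneSetCollection(sets, {name: "synthetic signature" for name in sets})
    return collection, ExpressionMatrix(data, dict(expr.groups))
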