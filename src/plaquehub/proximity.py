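"""Weighted network proximity of drug target sets to a disease gene set.

The observed statistic for a drug with target set T against the disease
(anchor-related) set S on the PPI network is

    d(S, T) = (1/|T'|) * sum_{t in T'} [ min_{s in S} d(s, t) + omega_t ]

with hop-count shortest paths, where T' keeps the on-network targets
reachable from S, and omega_t = -ln(D_t + 1) if t itself belongs to S (D_t
the degree of t in the full network), else 0.  Because omega_t does not
depend on s, summing it outside the minimum is equivalent to the literal
"min over s of (d + omega)" reading.  Self-targeting drugs (T within S)
therefore score <= 0.

The reference distribution redraws same-size target sets uniformly from
the network nodes; after n_perm repetitions (10,000 by default) the
observed distance is standardized,

    z(S, T) = (d(S, T) - mu_d(S, R)) / sigma_d(S, R),

and the one-sided empirical p (small distance = proximal) uses the add-one
estimator p = (1 + #{null <= d_obs}) / (1 + n_perm).  Drugs are screened at
d(S, T) < 1.2 and BH FDR < 0.05 by default.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import bh_adjust
from .errors import InputError, ParameterError
from .io_formats import DrugTargetMap

_MAX_REDRAWS = 1000


def _bfs_from_set(g: nx.Graph, sources) -> dict[str, int]:
    """Hop distance from the nearest source, for every reachable node."""
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


@dataclass
class ProximityField:
    """Precomputed distance-to-S and omega terms over one (network, S)."""

    nodes: list[str]
    dist_to_s: dict[str, int]
    omega: dict[str, float]

    def score(self, targets) -> tuple[float, int]:
        """d(S, T) and the number of targets used (on-network, reachable)."""
        total = 0.0
        used = 0
        for t in targets:
            d = self.dist_to_s.get(t)
            if d is None:
                continue  # off-network or unreachable from every s
            total += d + self.omega.get(t, 0.0)
            used += 1
        if used == 0:
            return math.nan, 0
        return total / used, used


def prepare_field(network: nx.Graph, S) -> ProximityField:
    """One multi-source BFS from S; omega for targets inside S."""
    S = set(S) & set(network.nodes)
    if not S:
        raise InputError("disease set S empty after restriction to the network")
    dist = _bfs_from_set(network, S)
    omega = {s: -math.log(network.degree[s] + 1.0) for s in S}
    return ProximityField(nodes=sorted(network.nodes), dist_to_s=dist, omega=omega)


def weighted_distance(network: nx.Graph, S, T) -> tuple[float, int]:
    """Observed weighted distance d(S, T); NaN with n_used=0 if unevaluable."""
    return prepare_field(network, S).score(set(T))


def null_distribution(
    network: nx.Graph,
    S,
    target_size: int,
    n_perm: int,
    seed: int,
    field: ProximityField | None = None,
) -> np.ndarray:
    """n_perm distances of uniformly drawn same-size random target sets."""
    field = field or prepare_field(network, S)
    nodes = field.nodes
    if target_size > len(nodes):
        raise ParameterError("target_size exceeds the node count")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    node_arr = np.array(nodes)
    for i in range(n_perm):
        for _ in range(_MAX_REDRAWS):
            draw = rng.choice(node_arr, size=target_size, replace=False)
            d, used = field.score(draw)
            if used > 0:
                out[i] = d
                break
        else:
            raise InputError("random target sets repeatedly unreachable from S")
    return out


def z_and_p(d_obs: float, null) -> tuple[float, float]:
    """Standardized score and add-one one-sided empirical p."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise InputError("null distribution is empty")
    mu = float(null.mean())
    sigma = float(null.std(ddof=1)) if null.size > 1 else 0.0
    z = (d_obs - mu) / sigma if sigma > 0 else math.nan
    p = (1.0 + float(np.sum(null <= d_obs))) / (1.0 + null.size)
    return z, p


def drug_proximity(
    network: nx.Graph,
    S,
    drugs: DrugTargetMap,
    n_permutations: int = 10_000,
    seed: int = 0,
    d_max: float = 1.2,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Full per-drug proximity table: d_obs, null moments, z, p, FDR, verdict.

    One null distribution is computed per distinct evaluable target size
    (the reference redraws "the same number of nodes as the target size");
    the substream for size k is seeded with (seed, k) so results do not
    depend on drug order.  Unevaluable drugs (no on-network reachable
    target) carry NaN statistics and are excluded from the BH adjustment.
    """
    field = prepare_field(network, S)
    names = sorted(drugs)
    obs = {}
    for name in names:
        obs[name] = field.score(set(drugs[name]))
    sizes = sorted({used for _, used in obs.values() if used > 0})
    nulls = {}
    for k in sizes:
        sub_seed = int(np.random.SeedSequence((int(seed), int(k))).generate_state(1)[0] % (2**31))
        nulls[k] = null_distribution(network, S, k, n_permutations, sub_seed, field=field)
    rows = []
    for name in names:
        d, used = obs[name]
        if used == 0:
            rows.append((name, math.nan, 0, math.nan, math.nan, math.nan, math.nan))
            continue
        null = nulls[used]
        z, p = z_and_p(d, null)
        rows.append((name, d, used, float(null.mean()), float(null.std(ddof=1)), z, p))
    df = pd.DataFrame(
        rows, columns=["drug", "d_obs", "n_targets_used", "mu_null", "sigma_null", "z", "p_emp"]
    ).set_index("drug")
    evaluable = df["n_targets_used"] > 0
    fdr = np.full(len(df), math.nan)
    if evaluable.any():
        fdr[evaluable.to_numpy()] = bh_adjust(df.loc[evaluable, "p_emp"].to_numpy())
    df["fdr"] = fdr
    df["screened"] = evaluable & (df["d_obs"] < d_max) & (df["fdr"] < fdr_max)
    return df


def screen_drugs(results: pd.DataFrame, d_max: float = 1.2, fdr_max: float = 0.05) -> list[str]:
    """Drugs with d_obs < d_max and FDR < fdr_max, ordered by ascending z."""
    keep = results[
        (results["n_targets_used"] > 0)
        & (results["d_obs"] < d_max)
        & (results["fdr"] < fdr_max)
    ]
    return list(keep.sort_values(["z", "drug"], kind="mergesort").index)


def distance_density_table(results: pd.DataFrame, nulls: np.ndarray | None = None, bins: int = 30) -> pd.DataFrame:
    """Binned densities of observed drug distances (and optionally a null)."""
    d = results["d_obs"].dropna().to_numpy()
    if d.size == 0:
        raise InputError("no evaluable drugs")
    lo = float(d.min() if nulls is None else min(d.min(), np.min(nulls)))
    hi = float(d.max() if nulls is None else max(d.max(), np.max(nulls)))
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, bins + 1)
    obs_dens, _ = np.histogram(d, bins=edges, density=True)
    out = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "observed_density": obs_dens}
    )
    if nulls is not None:
        null_dens, _ = np.histogram(np.asarray(nulls, float), bins=edges, density=True)
        out["null_density"] = null_dens
    return out
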