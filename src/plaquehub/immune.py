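"""Single-sample GSEA, aggregate immune score, and small-n correlation tests.

ssGSEA follows the rank-weighted running-sum statistic: per sample, genes
are ranked by expression (rank N = highest) and the enrichment score of a
signature is

    ES = sum_i [ P_in^w(i) - P_out(i) ]

where, walking positions i = 1..N from the top, P_in^w(i) is the cumulative
rank^alpha mass of signature genes at positions <= i over the signature
total, and P_out(i) the cumulative proportion of non-signature genes.
alpha defaults to 0.25 (the standard weighting; raw, un-normalized scores
by default so small examples stay closed-form).  The aggregate immune
score of a sample is the sum of its immune-signature scores — a documented
stand-in for platform-calibrated immune scoring.

Correlations are Spearman on midranks; with n <= 9 tie-free observations
the two-sided p is exact by full enumeration of all n! rank permutations
(at most 362,880 — sub-second), otherwise the t approximation is used and
flagged.  The anchor-related gene set uses Pearson r with the t-test p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .errors import InputError, ParameterError
from .io_formats import ExpressionMatrix, GeneSetCollection

EXACT_N_MAX = 9


def ssgsea_scores(
    expr: ExpressionMatrix,
    sigs: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Signatures x samples enrichment-score table.

    Ties in expression are broken by row order (stable), which matters only
    for degenerate constant profiles.  With ``normalize`` the whole table
    is divided by its max - min spread.
    """
    genes = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    memberships = {}
    for name, members in sigs.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if idx.size == 0:
            raise InputError(f"signature {name!r} has no measured genes")
        if idx.size == n:
            raise InputError(f"signature {name!r} covers every measured gene")
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        memberships[name] = mask
    values = expr.data.to_numpy(dtype=float)
    out = np.zeros((len(memberships), values.shape[1]))
    rank_weights = np.arange(n, 0, -1, dtype=float) ** alpha  # position 1 = rank N
    for j in range(values.shape[1]):
        order = np.argsort(-values[:, j], kind="mergesort")  # descending
        for si, (name, mask) in enumerate(memberships.items()):
            in_set = mask[order]
            w = np.where(in_set, rank_weights, 0.0)
            p_in = np.cumsum(w) / w.sum()
            n_out = n - in_set.sum()
            p_out = np.cumsum(~in_set) / n_out
            out[si, j] = float((p_in - p_out).sum())
    df = pd.DataFrame(out, index=list(memberships), columns=expr.sample_ids)
    if normalize:
        spread = out.max() - out.min()
        if spread > 0:
            df = df / spread
    return df


def immune_score(scores: pd.DataFrame) -> pd.Series:
    """Per-sample sum of signature enrichment scores."""
    if scores.shape[0] < 1:
        raise InputError("need at least one signature")
    return scores.sum(axis=0)


@dataclass
class CorrelationResult:
    coefficient: float
    p: float
    n: int
    method: str  # spearman_exact | spearman_approx | pearson
    degenerate: bool = False


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    n = rx.size
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))


def spearman_exact(x, y) -> CorrelationResult:
    """Spearman rank correlation with exact small-sample enumeration p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise InputError("correlation undefined for a constant vector")
    n = x.size
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _spearman_rho(rx, ry)
    ties = np.unique(rx).size < n or np.unique(ry).size < n
    if n <= EXACT_N_MAX and not ties:
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        d2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
        rho_perm = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
        # rho under permutation of one margin is the full null
        count = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, count / perms.shape[0], n, "spearman_exact")
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, "spearman_approx", degenerate=True)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, p, n, "spearman_approx")


def pearson_corr_test(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t-test p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise InputError("correlation undefined for a constant vector")
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(math.copysign(1.0, r), 0.0, n, "pearson", degenerate=True)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, p, n, "pearson")


def related_gene_set(
    expr: ExpressionMatrix,
    anchor: str,
    r_min: float = 0.9,
    p_max: float = 0.001,
    absolute: bool = False,
) -> set[str]:
    """Genes whose Pearson correlation with the anchor passes r > r_min
    and p < p_max (both strict); positive correlations only unless
    ``absolute``.  The anchor itself is excluded."""
    if anchor not in expr.data.index:
        raise ParameterError(f"anchor gene {anchor!r} not measured")
    anchor_vec = expr.data.loc[anchor].to_numpy(dtype=float)
    out = set()
    for gene, row in expr.data.iterrows():
        if gene == anchor:
            continue
        vec = row.to_numpy(dtype=float)
        if np.unique(vec).size == 1:
            continue
        res = pearson_corr_test(anchor_vec, vec)
        coef = abs(res.coefficient) if absolute else res.coefficient
        if coef > r_min and res.p < p_max:
            out.add(gene)
    return out


def correlate_with_scores(
    expr: ExpressionMatrix, anchor: str, scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman (exact where possible) of the anchor gene vs each score row."""
    if anchor not in expr.data.index:
        raise ParameterError(f"anchor gene {anchor!r} not measured")
    anchor_vec = expr.data.loc[anchor].reindex(scores.columns).to_numpy(dtype=float)
    rows = []
    for name in scores.index:
        res = spearman_exact(anchor_vec, scores.loc[name].to_numpy(dtype=float))
        rows.append((name, res.coefficient, res.p, res.n, res.method))
    return pd.DataFrame(rows, columns=["target", "rho", "p", "n", "method"]).set_index("target")
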