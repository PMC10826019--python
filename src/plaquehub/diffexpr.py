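"""Moderated-t differential expression, BH adjustment, and DEG screening.

The test statistic is the empirical-Bayes moderated t: per-gene pooled
variances s2_g (d_g residual df) are shrunk toward a prior (d0, s0^2)
estimated by moment matching on log variances,

    s2_post,g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)
    t_g       = (mean_case - mean_control) / (s_post,g * sqrt(1/n1 + 1/n2))

with p-values from a t distribution on d0 + d_g degrees of freedom.  The
prior is fit exactly as in the classic variance-shrinkage recipe: the log
pooled variances z_g = log s2_g satisfy E z_g = digamma(d_g/2) - log(d_g/2)
+ log s0^2 + (digamma(d0/2) - log(d0/2) shift), Var z_g = trigamma(d_g/2) +
trigamma(d0/2); solving the second for d0 by Newton inversion of the
trigamma function and substituting back gives s0^2.

With fewer than 10 genes (or a diverging inversion) the moment estimates
are meaningless, so the fit falls back to the ordinary pooled-variance t
(d0 = 0) and records the fallback.

Input expression is assumed already log2-scale; the fold change is the
plain difference of group means (case minus control, i.e. unstable minus
stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io_formats import ExpressionMatrix


@dataclass
class ModerationParams:
    d0: float  # prior degrees of freedom; inf = complete shrinkage; 0 = none
    s0_sq: float  # prior variance
    fallback: bool = False  # True when the ordinary pooled t was used


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            return np.inf
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log pooled variances with common df."""
    ok = s2 > 0
    if ok.sum() < 2:
        raise FloatingPointError("too few positive variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    target = e_var * n / (n - 1) - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        half_d0 = _trigamma_inverse(float(target))
        d0 = 2.0 * half_d0
        if np.isinf(d0):
            s0_sq = float(np.exp(e_mean))
        else:
            s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        raise FloatingPointError("prior variance estimate diverged")
    return float(d0), s0_sq


def fit_moderated_t(expr: ExpressionMatrix) -> tuple[pd.DataFrame, ModerationParams]:
    """Per-gene moderated t between the unstable and stable groups.

    Returns a table indexed by gene with columns log2FC, t_stat, p_raw,
    fdr, direction, flagged, plus the fitted :class:`ModerationParams`.
    Genes with zero variance in both groups and zero mean difference get
    t = 0, p = 1 and are flagged.
    """
    case = expr.data[expr.case_samples].to_numpy(dtype=float)
    ctrl = expr.data[expr.control_samples].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs at least 2 samples")
    n_genes = case.shape[0]
    if n_genes < 1:
        raise InputError("need at least one gene")
    delta = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid

    params: ModerationParams
    if n_genes < 10:
        params = ModerationParams(d0=0.0, s0_sq=float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0, fallback=True)
        s2_post = s2.copy()
        df_total = np.full(n_genes, float(df_resid))
    else:
        try:
            d0, s0_sq = _fit_prior(s2, float(df_resid))
            params = ModerationParams(d0=d0, s0_sq=s0_sq, fallback=False)
            if np.isinf(d0):
                s2_post = np.full(n_genes, s0_sq)
                df_total = np.full(n_genes, np.inf)
            else:
                s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
                df_total = np.full(n_genes, d0 + df_resid)
        except FloatingPointError:
            params = ModerationParams(d0=0.0, s0_sq=1.0, fallback=True)
            s2_post = s2.copy()
            df_total = np.full(n_genes, float(df_resid))

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros(n_genes)
    p = np.ones(n_genes)
    flagged = np.zeros(n_genes, dtype=bool)
    nonzero = se > 0
    t[nonzero] = delta[nonzero] / se[nonzero]
    finite_df = np.isfinite(df_total)
    m = nonzero & finite_df
    p[m] = 2.0 * stats.t.sf(np.abs(t[m]), df_total[m])
    m = nonzero & ~finite_df
    p[m] = 2.0 * stats.norm.sf(np.abs(t[m]))
    # degenerate genes: zero posterior variance
    degenerate = ~nonzero
    exact_shift = degenerate & (delta != 0)
    t[exact_shift] = np.sign(delta[exact_shift]) * np.inf
    p[exact_shift] = 0.0
    flagged[degenerate] = True
    flagged[s2 == 0] = True  # no within-group variability: t rests on the prior alone

    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FC": delta,
            "t_stat": t,
            "p_raw": p,
            "fdr": fdr,
            "direction": np.where(delta >= 0, "up", "down"),
            "flagged": flagged,
        },
        index=expr.data.index,
    )
    return table, params


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def screen_degs(table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05) -> set[str]:
    """Genes with |log2FC| > lfc_min and fdr < fdr_max (both strict)."""
    if lfc_min <= 0 or fdr_max <= 0:
        raise InputError("thresholds must be positive")
    keep = (table["log2FC"].abs() > lfc_min) & (table["fdr"] < fdr_max)
    return set(table.index[keep])


def intersect_sets(a, b) -> set[str]:
    """Case-sensitive set intersection after whitespace stripping."""
    norm = lambda s: {str(g).strip() for g in s}
    return norm(a) & norm(b)
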