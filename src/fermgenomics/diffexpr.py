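"""Bayesian-regularized two-class differential expression (CyberT-style).

With only a handful of arrays per condition, per-gene variance estimates
are unstable.  The regularized t-test shrinks each gene's pooled variance
toward a local background: the mean pooled variance of the genes in a
sliding window (default 101 genes) ranked by mean expression.  With prior
weight ``lambda`` pseudo-observations,

    s2_reg = (lambda * s2_background + (nA + nB - 2) * s2_pooled)
             / (lambda + nA + nB - 2)

and the t statistic uses s2_reg with lambda + nA + nB - 2 degrees of
freedom.  ``lambda = 0`` recovers the ordinary pooled-variance two-sample
t-test exactly.  Two-sided p-values are corrected with Benjamini–Hochberg
FDR across all genes; the per-gene "ratio" is 2**(mean_A − mean_B), i.e.
the fold change on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError


@dataclass
class CybertParams:
    window: int = 101  # expression-rank neighbourhood for the variance prior
    prior_df: float = 10.0  # lambda: weight of the prior in pseudo-observations
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError(f"window must be odd and >= 1, got {self.window}")
        if self.prior_df < 0:
            raise ConfigError(f"prior_df must be >= 0, got {self.prior_df}")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window mean, truncated at the edges."""
    if window >= values.size:
        return np.full_like(values, values.mean())
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(values.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, values.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def cybert_test(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: CybertParams | None = None,
) -> pd.DataFrame:
    """Regularized t-test of group A vs group B for every gene.

    ``expr`` is a genes × samples log2 matrix; the groups name disjoint
    sample columns with at least two members each.  Returns a DataFrame
    indexed by gene with mean_A, mean_B, ratio, t, df, p, q and a
    ``significant`` flag (q < params.fdr_threshold).
    """
    params = params or CybertParams()
    params.validate()
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValidationError(f"group {name} needs >= 2 samples, got {len(grp)}")
        missing = [s for s in grp if s not in expr.columns]
        if missing:
            raise ValidationError(f"group {name} samples not in matrix: {missing}")

    xa = expr[group_a].to_numpy(float)
    xb = expr[group_b].to_numpy(float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    df_pool = na + nb - 2
    s2_pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df_pool

    # background: window mean of pooled variances along the expression rank
    overall_mean = np.concatenate([xa, xb], axis=1).mean(axis=1)
    rank_order = np.argsort(overall_mean, kind="stable")
    s2_bg = np.empty_like(s2_pooled)
    s2_bg[rank_order] = _window_mean(s2_pooled[rank_order], params.window)

    lam = params.prior_df
    s2_reg = (lam * s2_bg + df_pool * s2_pooled) / (lam + df_pool)
    dof = lam + df_pool
    se = np.sqrt(s2_reg * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "ratio": 2.0 ** (mean_a - mean_b),
            "t": t,
            "df": dof,
            "p": p,
            "q": q,
            "significant": q < params.fdr_threshold,
        },
        index=expr.index,
    )
    out.index.name = "gene_id"
    return out


def write_de_result(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id")


def read_de_result(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["significant"] = df["significant"].astype(bool)
    return df
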