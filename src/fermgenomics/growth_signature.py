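"""Iterative grouped-gene correlation with the maximum growth rate.

Single transcripts rarely track µmax well at array noise levels, but the
*average* expression of a well-chosen gene group can.  The procedure:

1. iteration k scores gene groups of size k (k starts at 1 and grows by one
   each iteration), each group by the Pearson correlation between its
   per-fermentation average expression and µmax;
2. the genes making up the ``top_n`` (default 300) best-scoring groups form
   the pool for the next iteration — genes that matter recur in many top
   groups, so the pool shrinks;
3. iteration stops when the pool stops shrinking (the previous, smaller
   pool is the result) or the group size exceeds the pool.

Groups are k-subsets of the current pool: enumerated exhaustively while the
number of combinations stays below ``max_candidates``, otherwise sampled
uniformly at random (seeded).  Scoring uses |Pearson r| so strongly
anti-correlated groups are retained; the final set is reported with both
Pearson and Spearman correlations of its averaged expression against µmax.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

_CHUNK = 20000  # groups scored per vectorized block


@dataclass
class IterationTrace:
    """Record of one full run of the iterative procedure."""

    iterations: list[dict] = field(default_factory=list)
    final_genes: list[str] = field(default_factory=list)
    final_pearson: float = float("nan")
    final_spearman: float = float("nan")

    def pool_sizes(self) -> list[int]:
        return [it["pool_after"] for it in self.iterations]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "iterations": self.iterations,
            "final_genes": self.final_genes,
            "final_pearson": self.final_pearson,
            "final_spearman": self.final_spearman,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def geneset_correlation(
    expr: pd.DataFrame, genes: Sequence[str], mumax: pd.Series | Sequence[float]
) -> tuple[float, float, pd.Series]:
    """Correlation of a gene set's averaged expression with µmax.

    Returns (Pearson r, Spearman rho, per-sample averaged expression).
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene set is empty")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:5]}")
    if isinstance(mumax, pd.Series):
        y = mumax.loc[expr.columns].to_numpy(float)
    else:
        y = np.asarray(mumax, dtype=float)
    if expr.shape[1] < 3:
        raise ValidationError("need >= 3 samples")
    avg = expr.loc[genes].mean(axis=0)
    if float(avg.std()) == 0.0 or float(np.std(y)) == 0.0:
        raise ValidationError("correlation undefined: a constant vector")
    pearson = float(stats.pearsonr(avg.to_numpy(), y).statistic)
    spearman = float(stats.spearmanr(avg.to_numpy(), y).statistic)
    return pearson, spearman, avg


def _score_groups(xc: np.ndarray, yc: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """|Pearson r| between group-average expression and µmax, vectorized.

    ``xc``: genes × samples, rows centered; ``yc``: centered µmax;
    ``groups``: n_groups × k matrix of row indices into ``xc``.
    """
    y_norm = float(np.linalg.norm(yc))
    out = np.empty(len(groups))
    for start in range(0, len(groups), _CHUNK):
        block = groups[start : start + _CHUNK]
        sums = xc[block].sum(axis=1)  # n × samples (mean ∝ sum; scale cancels)
        num = sums @ yc
        den = np.linalg.norm(sums, axis=1) * y_norm
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        out[start : start + len(block)] = np.abs(r)
    return out


def _sample_groups(
    rng: np.random.Generator, pool_size: int, k: int, n_groups: int
) -> np.ndarray:
    """Uniformly sampled k-subsets (distinct members within each group)."""
    need = n_groups
    chunks = []
    while need > 0:
        draw = rng.integers(0, pool_size, size=(int(need * 1.3) + 8, k))
        draw.sort(axis=1)
        ok = np.all(np.diff(draw, axis=1) > 0, axis=1) if k > 1 else np.ones(len(draw), bool)
        good = draw[ok][:need]
        chunks.append(good)
        need -= len(good)
    return np.concatenate(chunks)


def iterate_signature(
    expr: pd.DataFrame,
    mumax: pd.Series | Sequence[float],
    top_n: int = 300,
    max_candidates: int = 200000,
    seed: int = 0,
) -> IterationTrace:
    """Run the iterative grouped-gene µmax correlation (see module docstring)."""
    genes = list(expr.index)
    if len(genes) < top_n:
        raise ValidationError(
            f"matrix has {len(genes)} genes but top_n={top_n}; need genes >= top_n"
        )
    if expr.shape[1] < 5:
        raise ValidationError("need >= 5 samples")
    if isinstance(mumax, pd.Series):
        y = mumax.loc[expr.columns].to_numpy(float)
    else:
        y = np.asarray(mumax, dtype=float)
        if y.size != expr.shape[1]:
            raise ValidationError("mumax length does not match sample count")
    if np.std(y) == 0:
        raise ValidationError("constant µmax: correlation undefined")

    x = expr.to_numpy(float)
    xc_all = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    rng = np.random.default_rng(seed)

    trace = IterationTrace()
    pool = np.arange(len(genes))
    k = 0
    while True:
        k += 1
        if k > len(pool):
            break
        n_comb = math.comb(len(pool), k)
        if n_comb <= max_candidates:
            groups = np.fromiter(
                itertools.chain.from_iterable(itertools.combinations(range(len(pool)), k)),
                dtype=np.int64,
            ).reshape(-1, k)
        else:
            groups = _sample_groups(rng, len(pool), k, max_candidates)
        xc = xc_all[pool]
        scores = _score_groups(xc, yc, groups)
        n_keep = min(top_n, len(groups))
        top_idx = np.argsort(-scores, kind="stable")[:n_keep]
        new_pool = pool[np.unique(groups[top_idx].ravel())]
        trace.iterations.append(
            {
                "k": k,
                "n_candidates": int(len(groups)),
                "exhaustive": bool(n_comb <= max_candidates),
                "n_retained": int(n_keep),
                "pool_before": int(len(pool)),
                "pool_after": int(len(new_pool)),
            }
        )
        if len(new_pool) >= len(pool):
            break
        pool = new_pool

    trace.final_genes = [genes[i] for i in pool]
    pearson, spearman, _ = geneset_correlation(expr, trace.final_genes, y)
    trace.final_pearson = pearson
    trace.final_spearman = spearman
    return trace


def write_signature(trace: IterationTrace, expr: pd.DataFrame,
                    mumax: pd.Series | Sequence[float], prefix: str | Path) -> None:
    """Write the trace (JSON), final gene set (TSV) and the per-sample
    averaged-expression scatter data (TSV)."""
    prefix = Path(prefix)
    trace.to_json(prefix.with_suffix(".json"))
    pd.Series(trace.final_genes, name="gene_id").to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index=False
    )
    _, _, avg = geneset_correlation(expr, trace.final_genes, mumax)
    if isinstance(mumax, pd.Series):
        y = mumax.loc[expr.columns]
    else:
        y = pd.Series(np.asarray(mumax, float), index=expr.columns)
    pd.DataFrame({"mu_max": y, "avg_expression": avg}).to_csv(
        prefix.with_suffix(".scatter.tsv"), sep="\t", index_label="ferm_id"
    )
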