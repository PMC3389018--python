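"""Random-forest association of transcript levels with metabolite phenotypes.

A continuous metabolite phenotype (e.g. endpoint citrate concentration) is
dichotomized into low/high classes; a random-forest classifier is trained
with the transcriptome as predictors, and the mean-decrease-Gini feature
importances rank genes by their association with the phenotype.  Rankings
from two phenotypes can be compared via their top-k overlap, and two
differential-expression runs via their significance/direction concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ValidationError


def dichotomize(values: pd.Series | Sequence[float], rule: str = "median") -> pd.Series:
    """Split a phenotype into 'low'/'high' classes.

    ``rule='median'``: values <= median are 'low', the rest 'high'.
    ``rule='tertiles'``: only the extreme tertiles are labelled; the middle
    third is left unlabelled (None) and should be dropped by the caller.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise ValidationError(f"need >= 4 samples to dichotomize, got {len(s)}")
    if s.nunique() == 1:
        raise ValidationError("all phenotype values identical: no low/high split exists")
    if rule == "median":
        med = float(s.median())
        labels = pd.Series(np.where(s <= med, "low", "high"), index=s.index, dtype=object)
        if (labels == "high").sum() == 0:
            # more than half the values sit exactly at the median; break by rank
            order = s.rank(method="first")
            labels = pd.Series(
                np.where(order <= len(s) / 2, "low", "high"), index=s.index, dtype=object
            )
    elif rule == "tertiles":
        lo, hi = s.quantile([1 / 3, 2 / 3])
        labels = pd.Series([None] * len(s), index=s.index, dtype=object)
        labels[s <= lo] = "low"
        labels[s > hi] = "high"
    else:
        raise ValidationError(f"unknown dichotomization rule {rule!r}")
    return labels


@dataclass
class ImportanceRanking:
    """Mean-decrease-Gini importances, rank 1 = most important."""

    table: pd.DataFrame  # index gene_id; columns importance, rank
    phenotype: str = ""
    n_trees: int = 0
    seed: int | None = None

    def top(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ValidationError(f"k={k} exceeds the {len(self.table)}-gene universe")
        return list(self.table.sort_values("rank").index[:k])

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def rf_importances(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 1000,
    seed: int | None = 0,
    phenotype: str = "",
) -> ImportanceRanking:
    """Rank genes by random-forest mean-decrease-Gini importance.

    ``expr`` is genes × samples (log2); ``labels`` maps sample → 'low'/'high'
    (samples with a null label are dropped).  The forest uses Gini impurity
    and sqrt(p) features per split; results are deterministic given the seed.
    """
    labels = labels.dropna()
    samples = [s for s in expr.columns if s in labels.index]
    y = labels.loc[samples]
    classes = set(y)
    if len(classes) < 2:
        raise ValidationError("labels must contain both classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValidationError("need >= 2 samples per class")
    x = expr[samples].to_numpy(float).T  # samples × genes
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, y.to_numpy())
    importance = forest.feature_importances_
    order = np.argsort(-importance, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    table = pd.DataFrame({"importance": importance, "rank": rank}, index=expr.index)
    table.index.name = "gene_id"
    return ImportanceRanking(table, phenotype=phenotype, n_trees=n_trees, seed=seed)


def top_overlap(rank_a: ImportanceRanking, rank_b: ImportanceRanking, k: int) -> set[str]:
    """Genes shared between the two top-k importance sets."""
    if set(rank_a.table.index) != set(rank_b.table.index):
        raise ValidationError("rankings cover different gene universes")
    return set(rank_a.top(k)) & set(rank_b.top(k))


def concordance(de_a: pd.DataFrame, de_b: pd.DataFrame) -> tuple[int, int]:
    """Cross-contrast agreement of two differential-expression results.

    Returns ``(n_both_significant, n_same_direction)``: genes flagged
    significant in both contrasts, and among those, genes whose fold-change
    directions (ratio above vs below 1) agree.
    """
    if set(de_a.index) != set(de_b.index):
        raise ValidationError("DE results cover different gene universes")
    b = de_b.loc[de_a.index]
    both = de_a["significant"].to_numpy() & b["significant"].to_numpy()
    sign_a = np.sign(np.log2(de_a["ratio"].to_numpy(float)))
    sign_b = np.sign(np.log2(b["ratio"].to_numpy(float)))
    same = both & (sign_a == sign_b)
    return int(both.sum()), int(same.sum())
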