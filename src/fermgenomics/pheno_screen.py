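"""Mann-Whitney U screen linking fermentation factors to phenotypes.

For every factor comparison (the four two-level factors plus the three
pairwise pH contrasts) and every phenotype with data, the fermentors at the
two levels are compared with a two-sided Mann-Whitney U test.  p-values are
corrected with Benjamini–Hochberg FDR across the whole screen grid, and each
cell carries a direction: ``+`` when the second (higher) level has the
higher median, ``-`` when lower, undefined on tied medians.

The U statistic is reported for the first group.  Exact enumeration is used
for small tie-free inputs (nA + nB <= 12); otherwise the tie-corrected
normal approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .errors import ValidationError
from .study_model import CORE_PHENOTYPES, ORGANIC_ACIDS, StudyTable

log = logging.getLogger(__name__)

#: (label, factor, level_A, level_B); B is the higher/second level.
COMPARISONS: list[tuple[str, str, object, object]] = [
    ("T", "temperature_C", 28.0, 37.0),
    ("AA", "aa_factor", 1.1, 2.0),
    ("O2", "aeration", "N2", "O2"),
    ("pH5.2_vs_5.8", "pH", 5.2, 5.8),
    ("pH5.2_vs_6.4", "pH", 5.2, 6.4),
    ("pH5.8_vs_6.4", "pH", 5.8, 6.4),
    ("NaCl", "nacl_mM", 0.0, 300.0),
]

EXACT_LIMIT = 12  # largest nA+nB for which tie-free exact enumeration is used


class MwuResult(NamedTuple):
    u: float  # U statistic of group A
    p: float  # two-sided
    direction: str | None  # '+' if median(B) > median(A), '-' if lower


def mwu_test(
    values_a: Sequence[float], values_b: Sequence[float], mode: str = "auto"
) -> MwuResult:
    """Two-sided Mann-Whitney U test of two samples.

    ``mode='auto'`` picks exact enumeration when the combined sample is
    small (<= 12) and tie-free, the tie-corrected normal approximation
    otherwise; ``mode='exact'`` forces exact enumeration.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("exact", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact":
        method = "exact"
    else:
        method = "exact" if (a.size + b.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = None if med_a == med_b else ("+" if med_b > med_a else "-")
    return MwuResult(float(res.statistic), min(float(res.pvalue), 1.0), direction)


@dataclass
class ScreenResult:
    """Long-format screen table plus grid accessors."""

    table: pd.DataFrame  # columns: comparison, phenotype, n_A, n_B, U, p, q, direction
    alpha: float = 0.05
    skipped: list[str] = field(default_factory=list)

    def grid(self, value: str = "p") -> pd.DataFrame:
        """Comparisons × phenotypes pivot of one column."""
        return self.table.pivot(index="comparison", columns="phenotype", values=value)

    def cell(self, comparison: str, phenotype: str) -> pd.Series:
        sub = self.table[
            (self.table["comparison"] == comparison)
            & (self.table["phenotype"] == phenotype)
        ]
        if sub.empty:
            raise KeyError((comparison, phenotype))
        return sub.iloc[0]

    def write(self, path: str | Path) -> None:
        """Long-format TSV plus a companion ``p|q|direction`` grid TSV."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        cells = self.table.copy()
        cells["cell"] = cells.apply(
            lambda r: f"{r['p']:.4g}|{r['q']:.4g}|{r['direction'] or '.'}", axis=1
        )
        grid = cells.pivot(index="comparison", columns="phenotype", values="cell")
        grid.to_csv(path.with_suffix(".grid.tsv"), sep="\t")


def phenotype_screen(
    table: StudyTable,
    include_f30: bool = True,
    phenotypes: Sequence[str] | None = None,
    alpha: float = 0.05,
    mode: str = "auto",
) -> ScreenResult:
    """Run the full comparison × phenotype Mann-Whitney screen.

    ``include_f30=False`` drops records flagged as having no transcriptome
    sampling, to mirror analyses restricted to the 29 profiled fermentors.
    BH correction spans all cells of the screen.
    """
    records = table.records if include_f30 else table.transcriptome_records()
    sub = StudyTable(records, table.factor_levels)
    if phenotypes is None:
        phenotypes = [
            p
            for p in CORE_PHENOTYPES + ORGANIC_ACIDS
            if any(r.phenotype(p) is not None for r in sub)
        ]
    rows = []
    skipped: list[str] = []
    for label, factor, level_a, level_b in COMPARISONS:
        ids_a = [r.ferm_id for r in sub if getattr(r, factor) == level_a]
        ids_b = [r.ferm_id for r in sub if getattr(r, factor) == level_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            skipped.append(label)
            log.warning("comparison %s skipped: fewer than 2 records per level", label)
            continue
        for pheno in phenotypes:
            va = sub.phenotype_series(pheno, ids_a)
            vb = sub.phenotype_series(pheno, ids_b)
            if va.empty or vb.empty:
                continue
            res = mwu_test(va.to_numpy(), vb.to_numpy(), mode=mode)
            rows.append(
                {
                    "comparison": label,
                    "phenotype": pheno,
                    "n_A": len(va),
                    "n_B": len(vb),
                    "U": res.u,
                    "p": res.p,
                    "direction": res.direction,
                }
            )
    if not rows:
        raise ValidationError("no testable comparison/phenotype cells")
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df[["comparison", "phenotype", "n_A", "n_B", "U", "p", "q", "direction"]]
    return ScreenResult(df, alpha=alpha, skipped=skipped)
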