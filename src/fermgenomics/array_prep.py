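"""Two-channel microarray preprocessing.

Three steps, in the order they run on raw probe intensities:

1. :func:`lowess_normalize` — per-array intensity-dependent (MA) lowess
   detrending of the log-ratio M = log2(cy5/cy3), with the fitted trend
   split symmetrically between the channels so the average probe intensity
   A is preserved;
2. :func:`interslide_scale` — a single multiplicative factor per array so
   that all arrays share the same total (linear) signal, targeting the
   geometric mean of the observed totals;
3. :func:`collapse_probes` — per (gene, array), the median over that gene's
   probes of the mean-channel log2 intensity.

The result is a genes × arrays matrix of absolute log2 expression levels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError

log = logging.getLogger(__name__)

PROBE_COLUMNS = ["array_id", "probe_id", "gene_id", "cy5", "cy3"]


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: probe table missing column(s) {missing}")
    return df


def write_probe_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes-as-rows, samples-as-columns TSV of log2 values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def lowess_normalize(array_probes: pd.DataFrame, frac: float = 0.4) -> pd.DataFrame:
    """Remove the intensity-dependent dye trend from one array.

    Expects columns probe_id, gene_id, cy5, cy3 (positive linear
    intensities) for a single array.  Fits lowess (tricube weights, 3
    robustness iterations) of M = log2(cy5/cy3) against
    A = (log2 cy5 + log2 cy3)/2 and subtracts the fit, splitting the
    correction symmetrically between channels so A is unchanged per probe.

    Returns a copy with ``log2_cy5``/``log2_cy3`` columns added.
    """
    if len(array_probes) < 20:
        raise ValidationError(
            f"need >= 20 probes to fit a lowess trend, got {len(array_probes)}"
        )
    cy5 = array_probes["cy5"].to_numpy(float)
    cy3 = array_probes["cy3"].to_numpy(float)
    if np.any(cy5 <= 0) or np.any(cy3 <= 0):
        raise ValidationError("all probe intensities must be positive")
    a = 0.5 * (np.log2(cy5) + np.log2(cy3))
    m = np.log2(cy5) - np.log2(cy3)
    trend = lowess(m, a, frac=frac, it=3, return_sorted=False)
    m_norm = m - trend
    out = array_probes.copy()
    out["log2_cy5"] = a + m_norm / 2.0
    out["log2_cy3"] = a - m_norm / 2.0
    return out


def interslide_scale(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Rescale arrays to a common total linear signal.

    Each array's channel intensities are multiplied by one scalar so all
    totals equal the geometric mean of the observed totals.  A single-array
    input is returned unchanged with a warning.
    """
    if not tables:
        raise ValidationError("no arrays to scale")
    totals = {}
    for array_id, df in tables.items():
        if df.empty:
            raise ValidationError(f"array {array_id!r} has no probes")
        totals[array_id] = float(
            np.sum(2.0 ** df["log2_cy5"]) + np.sum(2.0 ** df["log2_cy3"])
        )
    if len(tables) < 2:
        log.warning("interslide_scale called with a single array; returning unchanged")
        return {k: v.copy() for k, v in tables.items()}
    target = float(np.exp(np.mean(np.log(list(totals.values())))))
    out = {}
    for array_id, df in tables.items():
        shift = np.log2(target / totals[array_id])
        scaled = df.copy()
        scaled["log2_cy5"] = scaled["log2_cy5"] + shift
        scaled["log2_cy3"] = scaled["log2_cy3"] + shift
        out[array_id] = scaled
    return out


def collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a normalized probe table to a genes × arrays log2 matrix.

    The per-probe abundance is the mean of the two channels' log2 values;
    the gene-level value is the median over the gene's probes (for an even
    probe count, the mean of the two middle values).  A gene absent from an
    array yields a missing value, which is logged.
    """
    df = table.copy()
    if "log2_cy5" not in df.columns:
        if np.any(df["cy5"] <= 0) or np.any(df["cy3"] <= 0):
            raise ValidationError("all probe intensities must be positive")
        df["log2_cy5"] = np.log2(df["cy5"])
        df["log2_cy3"] = np.log2(df["cy3"])
    df["abundance"] = 0.5 * (df["log2_cy5"] + df["log2_cy3"])
    matrix = df.pivot_table(
        index="gene_id", columns="array_id", values="abundance", aggfunc="median"
    )
    matrix.index.name = "gene_id"
    matrix.columns.name = None
    n_missing = int(matrix.isna().sum().sum())
    if n_missing:
        log.warning("%d (gene, array) cells have no probes; left missing", n_missing)
    return matrix


def normalize_probe_table(probes: pd.DataFrame, frac: float = 0.4) -> pd.DataFrame:
    """Full preprocessing: per-array lowess, inter-slide scaling, collapse."""
    tables = {
        array_id: lowess_normalize(sub, frac=frac)
        for array_id, sub in probes.groupby("array_id", sort=False)
    }
    tables = interslide_scale(tables)
    combined = pd.concat(tables.values(), ignore_index=True)
    return collapse_probes(combined)
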