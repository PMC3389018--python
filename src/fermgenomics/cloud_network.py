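"""Condition-response clouds, the regulatory network, and class enrichment.

A *response cloud* for one fermentation factor is the set of genes whose
expression changes significantly (q below a threshold) and strongly (fold
change above a threshold) between the factor's levels, split by direction.
Clouds across factors assemble into a bipartite factor→gene network
(exportable to Cytoscape as SIF or GraphML), genes are partitioned by the
exact set of factors they respond to ("single" vs "shared" responses), and
functional-class overrepresentation in any gene set is scored with the
hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .errors import ConfigError, ValidationError


@dataclass
class ResponseCloud:
    """Per-factor sets of responding genes with direction."""

    factor: str
    up: pd.DataFrame  # index gene_id; columns ratio, q (higher at high level)
    down: pd.DataFrame
    q_max: float = 0.05
    fold_min: float = 1.5

    @property
    def genes(self) -> set[str]:
        return set(self.up.index) | set(self.down.index)

    def direction_of(self, gene: str) -> str:
        if gene in self.up.index:
            return "up"
        if gene in self.down.index:
            return "down"
        raise KeyError(gene)


def build_clouds(
    de_by_factor: Mapping[str, pd.DataFrame],
    q_max: float = 0.05,
    fold_min: float = 1.5,
) -> dict[str, ResponseCloud]:
    """Threshold per-factor differential-expression tables into clouds.

    A gene joins factor f's cloud iff q < ``q_max`` and
    max(ratio, 1/ratio) > ``fold_min``; its direction follows the ratio
    (above 1 → up at the high level).
    """
    if fold_min < 1:
        raise ConfigError(f"fold_min must be >= 1, got {fold_min}")
    universes = {frozenset(de.index) for de in de_by_factor.values()}
    if len(universes) > 1:
        raise ValidationError("DE results do not share one gene universe")
    clouds = {}
    for factor, de in de_by_factor.items():
        ratio = de["ratio"].to_numpy(float)
        fold = np.maximum(ratio, 1.0 / ratio)
        passing = (de["q"].to_numpy(float) < q_max) & (fold > fold_min)
        sel = de.loc[passing, ["ratio", "q"]]
        clouds[factor] = ResponseCloud(
            factor=factor,
            up=sel[sel["ratio"] > 1.0],
            down=sel[sel["ratio"] < 1.0],
            q_max=q_max,
            fold_min=fold_min,
        )
    return clouds


def build_ph_cloud(
    de_pairs: Mapping[str, pd.DataFrame],
    q_max: float = 0.05,
    fold_min: float = 1.5,
    direction_contrast: str | None = None,
) -> ResponseCloud:
    """Collapse the pairwise pH contrasts into one "pH" cloud.

    A gene is pH-responsive if it passes the thresholds in *any* pairwise
    contrast; its direction is taken from the widest contrast
    (``direction_contrast``, default the contrast between the extreme pH
    levels, falling back to the passing contrast when that ratio is 1).
    """
    per_pair = build_clouds(de_pairs, q_max=q_max, fold_min=fold_min)
    if direction_contrast is None:
        candidates = [k for k in de_pairs if "5.2" in k and "6.4" in k]
        direction_contrast = candidates[0] if candidates else next(iter(de_pairs))
    wide = de_pairs[direction_contrast]
    members: dict[str, str] = {}
    for pair, cloud in per_pair.items():
        for gene in cloud.genes:
            if gene in members:
                continue
            ratio = float(wide.loc[gene, "ratio"])
            if ratio > 1.0:
                members[gene] = "up"
            elif ratio < 1.0:
                members[gene] = "down"
            else:
                members[gene] = cloud.direction_of(gene)
    rows_up, rows_down = [], []
    for gene, direction in members.items():
        row = {"gene_id": gene, "ratio": float(wide.loc[gene, "ratio"]),
               "q": float(wide.loc[gene, "q"])}
        (rows_up if direction == "up" else rows_down).append(row)
    up = pd.DataFrame(rows_up).set_index("gene_id") if rows_up else pd.DataFrame(
        columns=["ratio", "q"])
    down = pd.DataFrame(rows_down).set_index("gene_id") if rows_down else pd.DataFrame(
        columns=["ratio", "q"])
    return ResponseCloud("pH", up, down, q_max=q_max, fold_min=fold_min)


def partition_by_signature(
    clouds: Mapping[str, ResponseCloud],
) -> dict[frozenset, list[str]]:
    """Group cloud members by the exact set of factors they respond to."""
    membership: dict[str, set[str]] = {}
    for factor, cloud in clouds.items():
        for gene in cloud.genes:
            membership.setdefault(gene, set()).add(factor)
    groups: dict[frozenset, list[str]] = {}
    for gene, factors in membership.items():
        groups.setdefault(frozenset(factors), []).append(gene)
    return {key: sorted(genes) for key, genes in groups.items()}


def build_network(clouds: Mapping[str, ResponseCloud]) -> nx.DiGraph:
    """Bipartite factor→gene network with direction attributes on edges."""
    graph = nx.DiGraph()
    groups = partition_by_signature(clouds)
    group_of = {
        gene: "+".join(sorted(key)) for key, genes in groups.items() for gene in genes
    }
    for factor, cloud in clouds.items():
        graph.add_node(factor, kind="factor")
        for gene in sorted(cloud.genes):
            if gene not in graph:
                graph.add_node(gene, kind="gene", group=group_of[gene])
            graph.add_edge(factor, gene, direction=cloud.direction_of(gene))
    return graph


def export_network(network: nx.DiGraph, fmt: str, path: str | Path) -> None:
    """Write the network as Cytoscape-compatible SIF or GraphML.

    SIF relations are ``responds_up``/``responds_down``; GraphML carries the
    per-edge direction and per-node kind/group attributes.
    """
    if network.number_of_edges() == 0:
        raise ValidationError("nothing to export: network has no edges")
    path = Path(path)
    if fmt.upper() == "SIF":
        lines = [
            f"{u}\tresponds_{data['direction']}\t{v}"
            for u, v, data in network.edges(data=True)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif fmt.upper() == "GRAPHML":
        nx.write_graphml(network, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")


def import_network(fmt: str, path: str | Path) -> nx.DiGraph:
    """Re-read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt.upper() == "SIF":
        graph = nx.DiGraph()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            u, rel, v = line.split("\t")
            graph.add_node(u, kind="factor")
            if v not in graph:
                graph.add_node(v, kind="gene")
            graph.add_edge(u, v, direction=rel.removeprefix("responds_"))
        return graph
    if fmt.upper() == "GRAPHML":
        return nx.read_graphml(path)
    raise ValidationError(f"unknown network format {fmt!r}")


def enrichment(
    geneset: Iterable[str],
    classification: Mapping[str, str] | pd.Series,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of functional classes in a gene set.

    For each class with K members in the N-gene universe and k members among
    the n drawn genes, p = P[X >= k] for X ~ Hypergeometric(N, K, n); q is
    BH-adjusted across classes.  The classification is a flat gene→class
    map (no ontology propagation).
    """
    geneset = set(geneset)
    universe = set(universe)
    if not geneset <= universe:
        extra = sorted(geneset - universe)[:5]
        raise ValidationError(f"gene set not contained in universe, e.g. {extra}")
    if isinstance(classification, pd.Series):
        classification = classification.to_dict()
    class_members: dict[str, set[str]] = {}
    for gene, cls in classification.items():
        if gene in universe:
            class_members.setdefault(cls, set()).add(gene)
    if not class_members:
        raise ValidationError("classification covers no universe gene")
    n_total = len(universe)
    n_draw = len(geneset)
    rows = []
    for cls, members in sorted(class_members.items()):
        big_k = len(members)
        k = len(geneset & members)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_draw))
        rows.append({"class": cls, "K": big_k, "k": k, "n": n_draw, "N": n_total,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def read_classification(path: str | Path) -> pd.Series:
    """Flat gene→class TSV (columns gene_id, class)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "class"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns gene_id, class")
    return df.set_index("gene_id")["class"]
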