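"""Inverted-repeat (palindromic) promoter motif discovery.

Dimeric transcription factors commonly bind DNA at inverted repeats:
an arm, an optional spacer, and the arm's reverse complement (e.g. the
oxygen-response site TTGTGCACAA = TTGTG + reverse complement of TTGTG).

Discovery is presence/absence based: every arm k-mer observed in the
foreground promoters defines candidate motifs arm + N^spacer + revcomp(arm);
each candidate is scored by the hypergeometric upper-tail probability of
its foreground presence count against the pooled foreground+background
promoter set.  Because the candidate family is symmetric under reverse
complement (the spacer is a wildcard), a single forward-strand scan counts
sites on either strand.  Candidates passing a minimum foreground fraction
are ranked by p, near-duplicate candidates (site-set Jaccard > 0.8) are
merged, and each reported motif carries its aligned-site position-weight
matrix (+0.5 pseudocounts) and per-column information content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .diffexpr import bh_fdr
from .errors import ConfigError, ValidationError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet ACGTN, case-folded to upper)."""
    upper = seq.upper()
    invalid = set(upper) - set("ACGTN")
    if invalid:
        raise ValidationError(f"non-DNA character(s) {sorted(invalid)} in sequence")
    return upper.translate(_COMPLEMENT)[::-1]


class Promoter(NamedTuple):
    gene_id: str
    seq: str
    truncated: bool


def read_fasta(path: str | Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                sequences[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_upstream(
    coords: pd.DataFrame,
    genome: Mapping[str, str],
    length: int = 300,
    genes: Iterable[str] | None = None,
) -> dict[str, Promoter]:
    """Extract upstream (promoter) regions from genome sequences.

    ``coords`` has columns gene_id, start, end, strand (0-based half-open;
    strand '+' or '-') and optionally contig (defaults to the sole genome
    sequence).  A '+' gene yields [start-length, start) on the forward
    strand; a '-' gene yields the reverse complement of [end, end+length).
    Regions running off a contig edge are truncated and flagged.
    """
    coords = coords.set_index("gene_id") if "gene_id" in coords.columns else coords
    if genes is None:
        genes = list(coords.index)
    single = next(iter(genome)) if len(genome) == 1 else None
    out: dict[str, Promoter] = {}
    for gene in genes:
        if gene not in coords.index:
            raise KeyError(gene)
        row = coords.loc[gene]
        contig = row["contig"] if "contig" in coords.columns else single
        if contig is None or contig not in genome:
            raise KeyError(f"{gene}: contig {contig!r} not in genome")
        seq = genome[contig]
        start, end, strand = int(row["start"]), int(row["end"]), str(row["strand"])
        if strand == "+":
            lo, hi = start - length, start
        elif strand == "-":
            lo, hi = end, end + length
        else:
            raise ValidationError(f"{gene}: strand must be '+' or '-', got {strand!r}")
        truncated = lo < 0 or hi > len(seq)
        region = seq[max(lo, 0) : min(hi, len(seq))].upper()
        if strand == "-":
            region = reverse_complement(region)
        out[gene] = Promoter(gene, region, truncated)
    return out


@dataclass
class MotifModel:
    """An inverted-repeat motif: arm + N^spacer + revcomp(arm)."""

    arm: str
    spacer: int
    sites: list[tuple[str, int, str]] = field(default_factory=list)  # (seq id, offset, strand)
    pwm: np.ndarray | None = None  # 4 × width, column-stochastic (rows A,C,G,T)
    information_content: np.ndarray | None = None  # bits per column
    p_value: float = float("nan")
    q_value: float = float("nan")
    n_foreground: int = 0
    n_background: int = 0
    foreground_size: int = 0
    background_size: int = 0
    background_freqs: np.ndarray | None = None

    @property
    def consensus(self) -> str:
        return self.arm + "N" * self.spacer + reverse_complement(self.arm)

    @property
    def width(self) -> int:
        return 2 * len(self.arm) + self.spacer

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "spacer": self.spacer,
            "consensus": self.consensus,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "n_foreground": self.n_foreground,
            "n_background": self.n_background,
            "foreground_size": self.foreground_size,
            "background_size": self.background_size,
            "sites": [list(s) for s in self.sites],
            "pwm": self.pwm.tolist() if self.pwm is not None else None,
            "information_content": (
                self.information_content.tolist()
                if self.information_content is not None
                else None
            ),
        }

    def write_pwm(self, path: str | Path) -> None:
        """4-row TSV (A, C, G, T) of column probabilities."""
        pd.DataFrame(self.pwm, index=list(_BASES)).to_csv(path, sep="\t", header=False)


def _scan_ir_occurrences(
    seq: str, arm_lengths: range, spacer_lengths: range
) -> dict[tuple[str, int], list[int]]:
    """All inverted-repeat occurrences in one sequence, keyed by (arm, spacer)."""
    found: dict[tuple[str, int], list[int]] = {}
    n = len(seq)
    for a in arm_lengths:
        for pos in range(n - 2 * a + 1):
            arm = seq[pos : pos + a]
            if "N" in arm:
                continue
            rc = reverse_complement(arm)
            for g in spacer_lengths:
                end = pos + a + g
                if end + a > n:
                    break
                if seq[end : end + a] == rc:
                    found.setdefault((arm, g), []).append(pos)
    return found


def build_pwm(
    sites: list[str], pseudocount: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Column-stochastic PWM and per-column information content (bits,
    uniform background) from equal-length site strings."""
    width = len(sites[0])
    counts = np.full((4, width), pseudocount)
    for site in sites:
        for j, base in enumerate(site):
            if base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1.0
    pwm = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return pwm, ic


def find_inverted_repeats(
    foreground: Mapping[str, str],
    background: Mapping[str, str],
    arm_range: tuple[int, int] = (4, 7),
    spacer_range: tuple[int, int] = (0, 6),
    min_fg_fraction: float = 0.3,
    merge_jaccard: float = 0.8,
) -> list[MotifModel]:
    """Rank inverted-repeat candidates by foreground enrichment.

    ``foreground``/``background`` map promoter ids to sequences.  Returns
    motifs present in at least ``min_fg_fraction`` of foreground promoters,
    ranked by hypergeometric enrichment p (BH q across all tested
    candidates); shifted variants of one repeat are merged by site-set
    Jaccard similarity, keeping the lowest-p representative.
    """
    from scipy import stats

    if arm_range[0] < 3:
        raise ConfigError("arm lengths below 3 give degenerate repeats")
    if not foreground or not background:
        raise ValidationError("foreground and background must both be non-empty")
    arms = range(arm_range[0], arm_range[1] + 1)
    spacers = range(spacer_range[0], spacer_range[1] + 1)

    fg_hits: dict[tuple[str, int], dict[str, list[int]]] = {}
    for pid, seq in foreground.items():
        for key, positions in _scan_ir_occurrences(seq.upper(), arms, spacers).items():
            fg_hits.setdefault(key, {})[pid] = positions
    bg_hits: dict[tuple[str, int], set[str]] = {}
    for pid, seq in background.items():
        for key in _scan_ir_occurrences(seq.upper(), arms, spacers):
            bg_hits.setdefault(key, set()).add(pid)

    n_fg, n_bg = len(foreground), len(background)
    total = n_fg + n_bg
    candidates: list[MotifModel] = []
    for (arm, spacer), per_promoter in fg_hits.items():
        k = len(per_promoter)
        if k / n_fg < min_fg_fraction:
            continue
        big_k = k + len(bg_hits.get((arm, spacer), set()))
        p = float(stats.hypergeom.sf(k - 1, total, big_k, n_fg))
        model = MotifModel(
            arm=arm,
            spacer=spacer,
            p_value=min(p, 1.0),
            n_foreground=k,
            n_background=big_k - k,
            foreground_size=n_fg,
            background_size=n_bg,
        )
        model.sites = [
            (pid, positions[0], "+") for pid, positions in sorted(per_promoter.items())
        ]
        candidates.append(model)

    if not candidates:
        return []
    qs = bh_fdr([m.p_value for m in candidates])
    for model, q in zip(candidates, qs):
        model.q_value = float(q)
    # ties on p resolve toward the most specific (longest-arm) candidate
    candidates.sort(key=lambda m: (m.p_value, -len(m.arm), m.arm, m.spacer))

    merged: list[MotifModel] = []
    kept_sites: list[set[str]] = []
    for model in candidates:
        promoters = {pid for pid, _, _ in model.sites}
        duplicate = False
        for other in kept_sites:
            union = len(promoters | other)
            if union and len(promoters & other) / union > merge_jaccard:
                duplicate = True
                break
        if duplicate:
            continue
        merged.append(model)
        kept_sites.append(promoters)

    # background base frequencies from the pooled promoter set
    pooled = "".join(foreground.values()) + "".join(background.values())
    counts = np.array([pooled.count(b) for b in _BASES], dtype=float)
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    for model in merged:
        width = model.width
        site_seqs = [
            foreground[pid][off : off + width] for pid, off, _ in model.sites
        ]
        model.pwm, model.information_content = build_pwm(site_seqs)
        model.background_freqs = freqs
    return merged


def scan(
    motif: MotifModel,
    sequences: Mapping[str, str],
    score_threshold: float = 0.8,
) -> pd.DataFrame:
    """Log-odds PWM scan of both strands.

    Reports hits scoring at least ``score_threshold`` × the PWM's maximum
    attainable score; offsets are forward-strand positions of the site
    start.  Sequences shorter than the PWM are skipped with a warning.
    """
    if motif.pwm is None:
        raise ValidationError("motif has no PWM; run find_inverted_repeats first")
    bg = motif.background_freqs if motif.background_freqs is not None else np.full(4, 0.25)
    logodds = np.log2(motif.pwm / bg[:, None])
    width = motif.pwm.shape[1]
    max_score = float(logodds.max(axis=0).sum())
    rows = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < width:
            log.warning("sequence %s shorter than PWM width %d; skipped", seq_id, width)
            continue
        for strand in ("+", "-"):
            s = seq if strand == "+" else reverse_complement(seq)
            for pos in range(len(s) - width + 1):
                window = s[pos : pos + width]
                score = 0.0
                for j, base in enumerate(window):
                    if base in _BASE_INDEX:
                        score += logodds[_BASE_INDEX[base], j]
                if score >= score_threshold * max_score:
                    offset = pos if strand == "+" else len(seq) - width - pos
                    rows.append((seq_id, offset, strand, score))
    df = pd.DataFrame(rows, columns=["seq_id", "offset", "strand", "score"])
    # a palindromic PWM scores both strands identically at one locus;
    # report such a site once, on the forward strand
    df = df.sort_values(["seq_id", "offset", "strand"], kind="stable")
    df = df.drop_duplicates(subset=["seq_id", "offset", "score"], keep="first")
    return df.reset_index(drop=True)


def write_motifs(motifs: list[MotifModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in motifs], indent=2))
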