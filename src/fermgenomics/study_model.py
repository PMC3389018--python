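"""Data model and I/O for fermentation condition/phenotype tables.

The central object is the :class:`StudyTable`: one row per batch fermentor,
carrying the five controlled condition factors (NaCl, amino-acid dose,
temperature, pH, sparging gas) together with endpoint physiological
phenotypes (maximum growth rate ``mu_max`` in h^-1, biomass yield proxy
``od_max`` at OD600, and optionally six organic-acid concentrations in mM).

A copy of the 30-fermentor *Lactobacillus plantarum* WCFS1 design ships with
the package (``fermgenomics.study_model.table1_path()``); it follows a
balanced fractional factorial layout with 24 distinct condition combinations
plus replicated controls.

Condition levels are compared as exact printed values (e.g. 300, 2.0, 37,
5.8, "N2") — they are categorical design codes, not measurements.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import FormatError, ParseError, ValidationError

FACTOR_COLUMNS = ["nacl_mM", "aa_factor", "temperature_C", "pH", "aeration"]

#: Declared level sets of the factorial design.
FACTOR_LEVELS: dict[str, tuple] = {
    "nacl_mM": (0.0, 300.0),
    "aa_factor": (1.1, 2.0),
    "temperature_C": (28.0, 37.0),
    "pH": (5.2, 5.8, 6.4),
    "aeration": ("N2", "O2"),
}

ORGANIC_ACIDS = ["lactate", "pyruvate", "acetate", "citrate", "succinate", "formate"]
CORE_PHENOTYPES = ["od_max", "mu_max"]
REQUIRED_COLUMNS = FACTOR_COLUMNS + CORE_PHENOTYPES + ["ferm_id"]


def table1_path() -> Path:
    """Path of the packaged 30-fermentor design/phenotype fixture."""
    return Path(importlib.resources.files("fermgenomics").joinpath("data/table1.tsv"))


@dataclass
class FermentationRecord:
    """One batch fermentor: condition factors plus endpoint phenotypes."""

    ferm_id: str
    nacl_mM: float
    aa_factor: float
    temperature_C: float
    pH: float
    aeration: str
    od_max: float
    mu_max: float
    organic_acids: dict[str, float] = field(default_factory=dict)
    day: int | None = None
    replicate_group: str | None = None
    #: False for fermentors without in-growth sampling (no transcriptome);
    #: such records take part in phenotype-only analyses but are excluded
    #: from any transcriptome-linked computation.
    transcriptome: bool = True

    def condition_tuple(self) -> tuple:
        return (self.nacl_mM, self.aa_factor, self.temperature_C, self.pH, self.aeration)

    def validate(self, strict: bool = True) -> None:
        if not self.mu_max > 0:
            raise ValidationError(f"{self.ferm_id}: mu_max must be > 0, got {self.mu_max}")
        if not self.od_max > 0:
            raise ValidationError(f"{self.ferm_id}: od_max must be > 0, got {self.od_max}")
        if self.aeration not in FACTOR_LEVELS["aeration"]:
            raise ValidationError(
                f"{self.ferm_id}: aeration must be one of {FACTOR_LEVELS['aeration']},"
                f" got {self.aeration!r}"
            )
        if strict:
            for factor in ("nacl_mM", "aa_factor", "temperature_C", "pH"):
                value = getattr(self, factor)
                if value not in FACTOR_LEVELS[factor]:
                    raise ValidationError(
                        f"{self.ferm_id}: {factor}={value} not in declared levels"
                        f" {FACTOR_LEVELS[factor]} (pass strict=False to allow)"
                    )

    def phenotype(self, name: str) -> float | None:
        """Value of a named phenotype, or None when absent."""
        if name in CORE_PHENOTYPES:
            return getattr(self, name)
        if name in ORGANIC_ACIDS:
            return self.organic_acids.get(name)
        raise KeyError(name)


class PhenotypeRange(NamedTuple):
    min: float
    max: float
    argmin: str
    argmax: str


@dataclass
class StudyTable:
    """Ordered collection of fermentation records sharing one factor set."""

    records: list[FermentationRecord]
    factor_levels: dict[str, tuple] = field(default_factory=lambda: dict(FACTOR_LEVELS))

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("empty table: no fermentation records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.ferm_id in seen:
                raise ValidationError(f"duplicate ferm_id {rec.ferm_id!r}")
            seen.add(rec.ferm_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.ferm_id for r in self.records]

    def get(self, ferm_id: str) -> FermentationRecord:
        for rec in self.records:
            if rec.ferm_id == ferm_id:
                return rec
        raise KeyError(ferm_id)

    def subset(self, ids: Iterable[str]) -> "StudyTable":
        wanted = set(ids)
        return StudyTable([r for r in self.records if r.ferm_id in wanted], self.factor_levels)

    def transcriptome_records(self) -> list[FermentationRecord]:
        """Records eligible for transcriptome-linked analyses."""
        return [r for r in self.records if r.transcriptome]

    def phenotype_series(self, name: str, ids: Iterable[str] | None = None) -> pd.Series:
        """Per-fermentor values of a phenotype (missing values dropped)."""
        recs = self.records if ids is None else [self.get(i) for i in ids]
        data = {r.ferm_id: r.phenotype(name) for r in recs}
        return pd.Series(data, dtype=float).dropna()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "ferm_id": r.ferm_id,
                "nacl_mM": r.nacl_mM,
                "aa_factor": r.aa_factor,
                "temperature_C": r.temperature_C,
                "pH": r.pH,
                "aeration": r.aeration,
                "od_max": r.od_max,
                "mu_max": r.mu_max,
            }
            for acid in ORGANIC_ACIDS:
                if acid in r.organic_acids:
                    row[acid] = r.organic_acids[acid]
            if r.day is not None:
                row["day"] = r.day
            if r.replicate_group is not None:
                row["replicate_group"] = r.replicate_group
            row["transcriptome"] = int(r.transcriptome)
            rows.append(row)
        return pd.DataFrame(rows)


def load_fermentation_table(path: str | Path, strict: bool = True) -> StudyTable:
    """Read a tab-delimited fermentation table into a :class:`StudyTable`.

    Required columns: ferm_id plus the five factors and the two core
    phenotypes; optional: the six organic acids (mM), day, replicate_group,
    transcriptome.  Row order is preserved; empty organic-acid cells become
    absent values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{path}: table has a header but no data rows")

    def parse_num(raw: str | float, column: str, row_label: str) -> float:
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric value {raw!r} in column {column!r} (row {row_label})"
            ) from None

    records: list[FermentationRecord] = []
    for idx, row in df.iterrows():
        ferm_id = str(row["ferm_id"]).strip()
        row_label = f"{idx + 1}, ferm_id={ferm_id}"
        acids: dict[str, float] = {}
        for acid in ORGANIC_ACIDS:
            if acid in df.columns and pd.notna(row[acid]) and str(row[acid]).strip() != "":
                acids[acid] = parse_num(row[acid], acid, row_label)
        day = None
        if "day" in df.columns and pd.notna(row["day"]) and str(row["day"]).strip() != "":
            day = int(float(row["day"]))
        rep = None
        if (
            "replicate_group" in df.columns
            and pd.notna(row["replicate_group"])
            and str(row["replicate_group"]).strip() != ""
        ):
            rep = str(row["replicate_group"]).strip()
        transcriptome = True
        if "transcriptome" in df.columns and pd.notna(row["transcriptome"]):
            transcriptome = bool(int(float(row["transcriptome"])))
        rec = FermentationRecord(
            ferm_id=ferm_id,
            nacl_mM=parse_num(row["nacl_mM"], "nacl_mM", row_label),
            aa_factor=parse_num(row["aa_factor"], "aa_factor", row_label),
            temperature_C=parse_num(row["temperature_C"], "temperature_C", row_label),
            pH=parse_num(row["pH"], "pH", row_label),
            aeration=str(row["aeration"]).strip(),
            od_max=parse_num(row["od_max"], "od_max", row_label),
            mu_max=parse_num(row["mu_max"], "mu_max", row_label),
            organic_acids=acids,
            day=day,
            replicate_group=rep,
            transcriptome=transcriptome,
        )
        rec.validate(strict=strict)
        records.append(rec)
    return StudyTable(records)


def load_table1(strict: bool = True) -> StudyTable:
    """Load the packaged 30-fermentor study table."""
    return load_fermentation_table(table1_path(), strict=strict)


def write_fermentation_table(table: StudyTable, path: str | Path) -> None:
    """Write a StudyTable in the same TSV dialect ``load_fermentation_table`` reads."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def distinct_conditions(table: StudyTable) -> tuple[int, dict[tuple, list[str]]]:
    """Count distinct condition tuples and group fermentors sharing one.

    Returns ``(count, groups)`` where ``groups`` maps each distinct
    (NaCl, AA, T, pH, aeration) tuple to the ordered fermentor ids run at it.
    Groups partition the table.
    """
    groups: dict[tuple, list[str]] = {}
    for rec in table:
        groups.setdefault(rec.condition_tuple(), []).append(rec.ferm_id)
    return len(groups), groups


def phenotype_range(table: StudyTable, phenotype: str) -> PhenotypeRange:
    """Min/max of a phenotype over the table, with the fermentors attaining them.

    Ties on an extreme resolve to the first record in table order.  Records
    missing the phenotype are ignored; a phenotype absent from every record
    raises ``KeyError``.
    """
    best_min = best_max = None
    arg_min = arg_max = None
    for rec in table:
        value = rec.phenotype(phenotype)  # raises KeyError on unknown names
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if best_min is None or value < best_min:
            best_min, arg_min = value, rec.ferm_id
        if best_max is None or value > best_max:
            best_max, arg_max = value, rec.ferm_id
    if best_min is None:
        raise KeyError(f"phenotype {phenotype!r} has no values in this table")
    return PhenotypeRange(best_min, best_max, arg_min, arg_max)


@dataclass
class BalanceReport:
    """Per-factor level counts over distinct design points, plus warnings
    for two-factor level combinations never realised in the design."""

    level_counts: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    n_design_points: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_design_points": self.n_design_points,
            "level_counts": {
                f: {str(level): n for level, n in counts.items()}
                for f, counts in self.level_counts.items()
            },
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def validate_design(table: StudyTable) -> BalanceReport:
    """Assess the balance of the factorial design.

    Counts, per factor, how many *distinct* design points sit at each level,
    and flags every pairwise level combination (over levels observed in the
    table) with zero design points — the hallmark of confounded or missing
    cells in a fractional factorial layout.
    """
    _, groups = distinct_conditions(table)
    design_points = list(groups.keys())
    report = BalanceReport(n_design_points=len(design_points))
    observed_levels: dict[str, list] = {}
    for fi, factor in enumerate(FACTOR_COLUMNS):
        counts: dict = {}
        for point in design_points:
            counts[point[fi]] = counts.get(point[fi], 0) + 1
        # deterministic level ordering
        report.level_counts[factor] = dict(sorted(counts.items(), key=lambda kv: str(kv[0])))
        observed_levels[factor] = list(report.level_counts[factor].keys())
    for i, fa in enumerate(FACTOR_COLUMNS):
        for j in range(i + 1, len(FACTOR_COLUMNS)):
            fb = FACTOR_COLUMNS[j]
            for la in observed_levels[fa]:
                for lb in observed_levels[fb]:
                    hit = any(p[i] == la and p[j] == lb for p in design_points)
                    if not hit:
                        report.warnings.append(
                            f"no design point with {fa}={la} and {fb}={lb}"
                        )
    return report
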