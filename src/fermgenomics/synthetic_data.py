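"""Synthetic fermentation studies with known planted structure.

Generates a complete study — factorial design, endpoint phenotypes,
gene-level (optionally probe-level two-channel) transcriptomes and promoter
sequences — in which every discoverable structure is planted explicitly:

* additive condition→phenotype effects (e.g. higher temperature raising
  the maximum growth rate),
* condition-responsive gene sets shifted up/down at the high factor level,
* a gene group whose expression tracks the maximum growth rate µmax,
* genes tied to a latent citrate↔succinate conversion activity (which also
  anti-correlates the two acid concentrations),
* a palindromic (inverted-repeat) motif seeded into the promoters of
  oxygen-induced genes.

The planted truth is returned alongside the data so that recovery by the
downstream analysis stages can be scored exactly.

A single global seed drives a fixed hierarchy of per-component generator
streams (``numpy`` SeedSequence spawning), so regenerating one component or
adding a new one never perturbs the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .study_model import (
    FACTOR_LEVELS,
    FermentationRecord,
    StudyTable,
    load_table1,
)

# Fixed stream order; append only.
_STREAMS = [
    "phenotypes",
    "baseline",
    "assignment",
    "expression_noise",
    "responsive",
    "signature",
    "metabolite",
    "promoters",
    "motif",
    "probes",
]

DNA = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1].upper()


@dataclass
class ResponsiveSpec:
    """Planted condition-responsive gene set for one factor."""

    n_up: int = 50
    n_down: int = 50
    log2_effect: float = 2.0
    #: genes shared with another factor's responsive sets, e.g. {"temperature_C": 15}
    #: meaning 15 of this factor's up genes (and 15 down genes) are drawn from
    #: that factor's up/down sets.  Only factors listed earlier in the
    #: responsive_sets mapping can be referenced.
    overlap: dict[str, int] = field(default_factory=dict)


@dataclass
class SignatureSpec:
    """Planted µmax-tracking gene group: expression = a·z(µmax) + noise."""

    n_genes: int = 47
    strength: float = 2.0  # log2 units per SD of µmax


@dataclass
class MetaboliteSpec:
    """Genes coupled to the latent citrate→succinate conversion activity."""

    n_genes: int = 5
    effect: float = 2.0  # log2 units per SD of the latent activity


@dataclass
class MotifSpec:
    """Inverted-repeat motif planted in oxygen-induced promoters."""

    core: str = "TTGTGCACAA"
    flank_5: str = ""
    flank_3: str = ""
    fraction: float = 0.8  # fraction of O2-up promoters that receive a site

    @property
    def site(self) -> str:
        return (self.flank_5 + self.core + self.flank_3).upper()


@dataclass
class ProbeSpec:
    """Two-channel probe-level emission with an intensity-dependent dye bias."""

    probes_per_gene: int = 3
    probe_affinity_sd: float = 0.3  # per-probe log2 offset, shared across arrays
    channel_noise_sd: float = 0.1
    dye_bias_slope: float = 0.5  # log2 bias added to cy5, linear in intensity


@dataclass
class SimulationConfig:
    n_genes: int = 3099
    design: StudyTable | str = "table1"
    seed: int = 0
    #: additive phenotype shift at the high factor level; for pH the shift is
    #: per pH step above/below the middle level 5.8.
    effect_condition_phenotype: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("temperature_C", "mu_max"): 0.2,
            ("nacl_mM", "od_max"): -0.8,
            ("aeration", "acetate"): 5.0,
            ("pH", "formate"): 1.5,
        }
    )
    responsive_sets: dict[str, ResponsiveSpec] = field(
        default_factory=lambda: {
            "temperature_C": ResponsiveSpec(),
            "pH": ResponsiveSpec(overlap={"temperature_C": 15}),
            "nacl_mM": ResponsiveSpec(),
            "aeration": ResponsiveSpec(),
        }
    )
    mumax_signature: SignatureSpec = field(default_factory=SignatureSpec)
    metabolite_assoc: MetaboliteSpec = field(default_factory=MetaboliteSpec)
    noise_sd: float = 0.5  # log2 expression noise
    baseline_mean: float = 8.0  # log2 intensity scale of array data
    baseline_sd: float = 2.0
    phenotype_noise: dict[str, float] = field(
        default_factory=lambda: {
            "mu_max": 0.05,
            "od_max": 0.3,
            "lactate": 15.0,
            "pyruvate": 0.3,
            "acetate": 3.0,
            "formate": 1.0,
            # measurement-scale noise only; acid-specific biological variation
            # is not modelled separately, so the citrate↔succinate
            # anti-correlation comes out stronger than in real fermentations
            "citrate": 0.5,
            "succinate": 0.5,
        }
    )
    phenotype_baseline: dict[str, float] = field(
        default_factory=lambda: {
            "mu_max": 0.45,
            "od_max": 6.0,
            "lactate": 150.0,
            "pyruvate": 2.0,
            "acetate": 20.0,
            "formate": 5.0,
            # both acids sit well above zero so the +/- coupling swing never
            # truncates at the concentration floor
            "citrate": 8.0,
            "succinate": 8.0,
        }
    )
    #: latent citrate→succinate conversion activity: citrate loses and
    #: succinate gains coupling·z(activity); NaCl lowers the activity.
    citsucc_coupling: float = 3.0
    citsucc_nacl_effect: float = -0.8
    citsucc_sd: float = 0.7
    probe_level: bool = False
    probe_spec: ProbeSpec = field(default_factory=ProbeSpec)
    motif: MotifSpec = field(default_factory=MotifSpec)
    promoter_length: int = 300
    make_promoters: bool = True

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.motif.fraction <= 1:
            raise ConfigError("motif fraction must be in [0, 1]")
        if self.promoter_length < len(self.motif.site):
            raise ConfigError("promoter_length shorter than the motif site")
        if self._n_planted() > self.n_genes:
            raise ConfigError(
                f"planted genes ({self._n_planted()}) exceed n_genes ({self.n_genes})"
            )

    def _n_planted(self) -> int:
        n = self.mumax_signature.n_genes + self.metabolite_assoc.n_genes
        for spec in self.responsive_sets.values():
            shared = 2 * sum(spec.overlap.values())
            n += spec.n_up + spec.n_down - shared
        return n


def null_config(n_genes: int = 200, seed: int = 0, **kwargs) -> SimulationConfig:
    """A configuration with every planted effect switched off.

    Used for type-I-error (false-positive rate) simulations: the design and
    noise model are unchanged, only the signal is absent.
    """
    cfg = SimulationConfig(
        n_genes=n_genes,
        seed=seed,
        effect_condition_phenotype={},
        responsive_sets={},
        mumax_signature=SignatureSpec(n_genes=0, strength=0.0),
        metabolite_assoc=MetaboliteSpec(n_genes=0, effect=0.0),
        citsucc_coupling=0.0,
        citsucc_nacl_effect=0.0,
        motif=MotifSpec(fraction=0.0),
        **kwargs,
    )
    return cfg


@dataclass
class SyntheticTruth:
    """Planted structure of one simulated study."""

    genes: list[str]
    responsive: dict[str, dict[str, list[str]]]  # factor -> {"up": [...], "down": [...]}
    signature_genes: list[str]
    metabolite_genes: list[str]
    motif_genes: list[str]
    condition_effects: dict[str, float]  # "factor->phenotype" -> effect

    def structures(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {
            "signature": set(self.signature_genes),
            "metabolite": set(self.metabolite_genes),
            "motif": set(self.motif_genes),
        }
        for factor, sets in self.responsive.items():
            out[f"responsive:{factor}:up"] = set(sets["up"])
            out[f"responsive:{factor}:down"] = set(sets["down"])
            out[f"responsive:{factor}"] = set(sets["up"]) | set(sets["down"])
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "genes": self.genes,
            "responsive": self.responsive,
            "signature_genes": self.signature_genes,
            "metabolite_genes": self.metabolite_genes,
            "motif_genes": self.motif_genes,
            "condition_effects": self.condition_effects,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


@dataclass
class SimulatedStudy:
    study: StudyTable
    expression: pd.DataFrame  # genes x samples, log2
    probes: pd.DataFrame | None
    promoters: dict[str, str]  # gene -> upstream sequence
    truth: SyntheticTruth


def _high_indicator(record: FermentationRecord, factor: str) -> float:
    """Signed factor coding: 0/1 for two-level factors, −1/0/+1 across pH."""
    if factor == "pH":
        return (record.pH - 5.8) / 0.6
    levels = FACTOR_LEVELS[factor]
    return float(getattr(record, factor) == levels[-1])


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic study (see module docstring).

    Fully reproducible: identical config and seed give bit-identical outputs.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(_STREAMS))
    rng = {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}

    design = load_table1() if config.design == "table1" else config.design
    if not isinstance(design, StudyTable):
        raise ConfigError("design must be 'table1' or a StudyTable")

    # --- phenotypes: baseline + planted factor effects + Gaussian noise ---
    prng = rng["phenotypes"]
    pheno_names = list(config.phenotype_baseline)
    conv = {}  # latent citrate->succinate conversion activity per fermentor
    for rec in design:
        conv[rec.ferm_id] = config.citsucc_nacl_effect * _high_indicator(
            rec, "nacl_mM"
        ) + config.citsucc_sd * prng.normal()
    conv_values = np.array([conv[r.ferm_id] for r in design])
    conv_sd = conv_values.std()
    conv_z = (conv_values - conv_values.mean()) / conv_sd if conv_sd > 0 else conv_values * 0.0

    records: list[FermentationRecord] = []
    for i, rec in enumerate(design):
        values: dict[str, float] = {}
        for name in pheno_names:
            v = config.phenotype_baseline[name]
            for (factor, pheno), eff in config.effect_condition_phenotype.items():
                if pheno == name:
                    v += eff * _high_indicator(rec, factor)
            if name == "citrate":
                v -= config.citsucc_coupling * conv_z[i]
            elif name == "succinate":
                v += config.citsucc_coupling * conv_z[i]
            v += prng.normal(0.0, config.phenotype_noise.get(name, 0.0))
            values[name] = v
        acids = {a: max(values[a], 0.0) for a in values if a not in ("mu_max", "od_max")}
        records.append(
            FermentationRecord(
                ferm_id=rec.ferm_id,
                nacl_mM=rec.nacl_mM,
                aa_factor=rec.aa_factor,
                temperature_C=rec.temperature_C,
                pH=rec.pH,
                aeration=rec.aeration,
                od_max=max(values["od_max"], 0.1),
                mu_max=max(values["mu_max"], 0.01),
                organic_acids=acids,
                day=rec.day,
                replicate_group=rec.replicate_group,
                transcriptome=rec.transcriptome,
            )
        )
    study = StudyTable(records)

    # --- gene universe and planted-set assignment ---
    n = config.n_genes
    width = max(4, len(str(n)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    order = rng["assignment"].permutation(n)
    cursor = 0

    def take(count: int) -> list[str]:
        nonlocal cursor
        block = [genes[j] for j in order[cursor : cursor + count]]
        cursor += count
        return block

    responsive: dict[str, dict[str, list[str]]] = {}
    for factor, spec in config.responsive_sets.items():
        up: list[str] = []
        down: list[str] = []
        for other, n_shared in spec.overlap.items():
            if other not in responsive:
                raise ConfigError(
                    f"overlap references {other!r} which is not defined earlier"
                )
            up.extend(responsive[other]["up"][:n_shared])
            down.extend(responsive[other]["down"][:n_shared])
        up.extend(take(spec.n_up - len(up)))
        down.extend(take(spec.n_down - len(down)))
        responsive[factor] = {"up": up, "down": down}
    signature_genes = take(config.mumax_signature.n_genes)
    metabolite_genes = take(config.metabolite_assoc.n_genes)

    # --- expression matrix (log2, genes x transcriptome samples) ---
    samples = [r.ferm_id for r in study.transcriptome_records()]
    baseline = rng["baseline"].normal(config.baseline_mean, config.baseline_sd, size=n)
    expr = np.tile(baseline[:, None], (1, len(samples)))
    expr += rng["expression_noise"].normal(0.0, config.noise_sd, size=expr.shape)

    gene_index = {g: i for i, g in enumerate(genes)}
    sample_recs = [study.get(s) for s in samples]
    for factor, spec in config.responsive_sets.items():
        h = np.array([_high_indicator(r, factor) for r in sample_recs])
        up_idx = [gene_index[g] for g in responsive[factor]["up"]]
        down_idx = [gene_index[g] for g in responsive[factor]["down"]]
        expr[up_idx, :] += spec.log2_effect * h
        expr[down_idx, :] -= spec.log2_effect * h

    mumax = np.array([r.mu_max for r in sample_recs])
    if len(samples) > 1 and mumax.std() > 0 and signature_genes:
        z = (mumax - mumax.mean()) / mumax.std()
        sig_idx = [gene_index[g] for g in signature_genes]
        expr[sig_idx, :] += config.mumax_signature.strength * z

    if metabolite_genes:
        conv_z_samples = np.array(
            [conv_z[[r.ferm_id for r in design].index(s)] for s in samples]
        )
        met_idx = [gene_index[g] for g in metabolite_genes]
        expr[met_idx, :] += config.metabolite_assoc.effect * conv_z_samples

    expression = pd.DataFrame(expr, index=genes, columns=samples)
    expression.index.name = "gene_id"

    # --- promoters and planted motif sites ---
    promoters: dict[str, str] = {}
    motif_genes: list[str] = []
    if config.make_promoters:
        prom_rng = rng["promoters"]
        bases = prom_rng.integers(0, 4, size=(n, config.promoter_length))
        promoters = {g: "".join(DNA[row]) for g, row in zip(genes, bases)}
        o2_up = responsive.get("aeration", {}).get("up", [])
        if o2_up and config.motif.fraction > 0:
            m_rng = rng["motif"]
            n_seed = int(round(config.motif.fraction * len(o2_up)))
            chosen = list(np.array(o2_up)[m_rng.permutation(len(o2_up))[:n_seed]])
            site = config.motif.site
            for g in chosen:
                offset = int(m_rng.integers(0, config.promoter_length - len(site) + 1))
                planted = site if m_rng.random() < 0.5 else _revcomp(site)
                s = promoters[g]
                promoters[g] = s[:offset] + planted + s[offset + len(site) :]
            motif_genes = sorted(chosen)

    # --- optional probe-level two-channel emission ---
    probes = None
    if config.probe_level:
        ps = config.probe_spec
        p_rng = rng["probes"]
        affinity = p_rng.normal(0.0, ps.probe_affinity_sd, size=(n, ps.probes_per_gene))
        rows = []
        for s_i, sample in enumerate(samples):
            x = expr[:, s_i][:, None] + affinity  # true per-probe log2 level
            noise5 = p_rng.normal(0.0, ps.channel_noise_sd, size=x.shape)
            noise3 = p_rng.normal(0.0, ps.channel_noise_sd, size=x.shape)
            log_cy3 = x + noise3
            a = x  # mean intensity drives the dye bias
            log_cy5 = x + noise5 + ps.dye_bias_slope * (a - config.baseline_mean) / 2.0
            for g_i, g in enumerate(genes):
                for p_i in range(ps.probes_per_gene):
                    rows.append(
                        (
                            sample,
                            f"{g}_p{p_i + 1}",
                            g,
                            float(2.0 ** log_cy5[g_i, p_i]),
                            float(2.0 ** log_cy3[g_i, p_i]),
                        )
                    )
        probes = pd.DataFrame(rows, columns=["array_id", "probe_id", "gene_id", "cy5", "cy3"])

    truth = SyntheticTruth(
        genes=genes,
        responsive=responsive,
        signature_genes=signature_genes,
        metabolite_genes=metabolite_genes,
        motif_genes=motif_genes,
        condition_effects={
            f"{factor}->{pheno}": eff
            for (factor, pheno), eff in config.effect_condition_phenotype.items()
        },
    )
    return SimulatedStudy(study, expression, probes, promoters, truth)


def recovery_metrics(truth_set: Iterable[str], recovered: Iterable[str]) -> dict[str, float]:
    """Precision, recall and Jaccard index of one recovered gene set."""
    t, r = set(truth_set), set(recovered)
    inter = len(t & r)
    union = len(t | r)
    return {
        "n_truth": len(t),
        "n_recovered": len(r),
        "n_overlap": inter,
        "precision": inter / len(r) if r else 0.0,
        "recall": inter / len(t) if t else 0.0,
        "jaccard": inter / union if union else 1.0,
    }


def truth_recovery_report(
    truth: SyntheticTruth, results: dict[str, Iterable[str]]
) -> dict[str, dict[str, float]]:
    """Score recovered gene sets against the planted truth.

    ``results`` maps structure names (as in :meth:`SyntheticTruth.structures`,
    e.g. ``"signature"`` or ``"responsive:aeration:up"``) to recovered gene
    collections.  Every recovered gene must belong to the simulated universe.
    """
    universe = set(truth.genes)
    structures = truth.structures()
    report = {}
    for name, recovered in results.items():
        recovered = set(recovered)
        if not recovered <= universe:
            extra = sorted(recovered - universe)[:5]
            raise ValidationError(
                f"{name}: recovered genes outside the simulated universe, e.g. {extra}"
            )
        if name not in structures:
            raise ValidationError(
                f"unknown planted structure {name!r}; known: {sorted(structures)}"
            )
        report[name] = recovery_metrics(structures[name], recovered)
    return report
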