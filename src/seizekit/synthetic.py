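"""Synthetic input bundles with planted ground truth.

Generates every input the pipeline consumes — evidence TSV, gene-based GWAS
table, GMT pathway collection, drug target/metadata tables — from one seeded
configuration, together with the truth labels (which genes are "true"
seizure genes, which pathways were planted, which drugs are antiseizure), so
every stage can be tested for recovery and calibration without downloads.

The generator emulates the statistical structure of a curated cross-species
seizure-gene database: a minority of true genes carry overdispersed,
inflated citation counts spread across species (negative binomial,
zero-truncated so every true gene is in the database); background genes
enter the database only when their un-truncated count exceeds zero; pathways
planted with true genes; GWAS p-values Beta(a, 1) with a <= 1 for true
genes and Uniform(0, 1) for nulls; and antiseizure drugs whose targets are
biased toward top-citation genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .drugs import DrugProfile, write_drug_profiles
from .enrichment import GeneSetCollection, write_gmt
from .evidence import SPECIES, CitationRecord, EvidenceDatabase, write_evidence
from .gwas import GwasGeneResult

__all__ = ["SyntheticConfig", "SyntheticBundle", "ConfigError", "generate", "presets", "get_preset"]

_INDICATIONS = (
    "hypertension", "depression", "pain", "parkinsonism", "asthma",
    "arrhythmia", "migraine", "diabetes", "rheumatoid arthritis", "insomnia",
)

_EVIDENCE_CLASS_PROBS = {"variant_association": 0.6, "direct_manipulation": 0.25, "database_record": 0.15}


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; a bundle is fully determined by one of
    these (including the seed).

    Citation counts are negative binomial parameterized by (mean,
    dispersion): dispersion is the NB size parameter r, so variance =
    mean + mean^2 / r (small r = heavier tail). ``species_probs`` allocates
    each citation to a species (order matches
    :data:`seizekit.evidence.SPECIES`). ``planted_loading`` is the fraction
    of each planted pathway's members drawn from true genes.
    ``gwas_alt_shape`` is the Beta(a, 1) shape for true genes' p-values
    (a = 1 recovers the uniform null). ``target_bias`` is the fraction of
    each antiseizure drug's targets drawn from the top decile of database
    genes by citation count (0 = unbiased background draws).
    """

    n_genes: int = 2000
    frac_true: float = 0.10
    citations_true: tuple[float, float] = (8.0, 0.8)          # (mean, dispersion r)
    citations_background: tuple[float, float] = (0.5, 0.3)
    species_probs: tuple[float, ...] = (0.55, 0.04, 0.25, 0.08, 0.04, 0.02, 0.02)
    frac_human_monogenic_among_true: float = 0.7
    n_pathways: int = 150
    pathway_size: tuple[int, int] = (20, 80)
    planted_pathway_count: int = 15
    planted_loading: float = 0.6
    gwas_alt_shape: float = 0.15
    n_drugs: int = 150
    targets_per_drug: tuple[int, int] = (1, 10)
    n_antiseizure: int = 15
    target_bias: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_true", "frac_human_monogenic_among_true", "planted_loading", "target_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if len(self.species_probs) != len(SPECIES):
            raise ConfigError(f"species_probs needs {len(SPECIES)} entries (order {SPECIES})")
        if abs(sum(self.species_probs) - 1.0) > 1e-9 or min(self.species_probs) < 0:
            raise ConfigError("species_probs must be non-negative and sum to 1")
        for name in ("n_genes", "n_pathways", "n_drugs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.gwas_alt_shape <= 1.0):
            raise ConfigError("gwas_alt_shape must be in (0, 1]")
        lo, hi = self.pathway_size
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError(f"pathway_size {self.pathway_size} infeasible for n_genes={self.n_genes}")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError(f"targets_per_drug {self.targets_per_drug} infeasible")
        if self.planted_pathway_count > self.n_pathways:
            raise ConfigError("planted_pathway_count exceeds n_pathways")
        if self.n_antiseizure > self.n_drugs:
            raise ConfigError("n_antiseizure exceeds n_drugs")
        if self.planted_pathway_count > 0 and self.frac_true == 0.0:
            raise ConfigError("cannot plant pathways with frac_true = 0")
        for pair_name in ("citations_true", "citations_background"):
            mean, disp = getattr(self, pair_name)
            if mean < 0 or disp <= 0:
                raise ConfigError(f"{pair_name}: mean must be >= 0 and dispersion > 0")


@dataclass(frozen=True)
class SyntheticBundle:
    evidence: EvidenceDatabase
    gwas: tuple[GwasGeneResult, ...]
    collection: GeneSetCollection
    drugs: tuple[DrugProfile, ...]
    true_genes: frozenset[str]
    planted_pathways: frozenset[str]
    config: SyntheticConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Serialize to the exact dialects the analysis modules consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "evidence": directory / "evidence.tsv",
            "gwas": directory / "gwas_generalized.tsv",
            "gmt": directory / "pathways.gmt",
            "drug_targets": directory / "drug_targets.tsv",
            "drug_meta": directory / "drug_meta.tsv",
            "truth": directory / "truth.json",
        }
        write_evidence(self.evidence, paths["evidence"])
        with open(paths["gwas"], "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_symbol\tp_value\n")
            for r in self.gwas:
                fh.write(f"{r.gene_symbol}\t{r.p_value!r}\n")
        write_gmt(self.collection, paths["gmt"])
        write_drug_profiles(self.drugs, paths["drug_targets"], paths["drug_meta"])
        truth = {
            "true_genes": sorted(self.true_genes),
            "planted_pathways": sorted(self.planted_pathways),
            "config": asdict(self.config),
        }
        with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _rng(config: SyntheticConfig, component: int) -> np.random.Generator:
    # one root seed; each component gets its own deterministic stream so
    # regenerating one component never perturbs the others
    return np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(component,)))


def _truncated_nb(rng: np.random.Generator, mean: float, disp: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (resampling rejection)."""
    p = disp / (disp + mean)
    out = rng.negative_binomial(disp, p, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(disp, p, int(zero.sum()))


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Build a complete, deterministic input bundle from one configuration."""
    symbols = [f"G{i:05d}" for i in range(config.n_genes)]
    n_true = round(config.n_genes * config.frac_true)

    rng_truth = _rng(config, 0)
    true_idx = np.sort(rng_truth.choice(config.n_genes, size=n_true, replace=False))
    true_genes = frozenset(symbols[i] for i in true_idx)
    is_true = np.zeros(config.n_genes, dtype=bool)
    is_true[true_idx] = True
    human_flag_idx = true_idx[
        rng_truth.random(n_true) < config.frac_human_monogenic_among_true
    ] if n_true else np.array([], dtype=int)
    human_flag = np.zeros(config.n_genes, dtype=bool)
    human_flag[human_flag_idx] = True

    # --- citation counts: true genes always in the database (counts >= 1),
    # background genes only when their NB draw exceeds zero
    rng_cit = _rng(config, 1)
    counts = np.zeros(config.n_genes, dtype=int)
    mean_bg, disp_bg = config.citations_background
    p_bg = disp_bg / (disp_bg + mean_bg) if mean_bg > 0 else 1.0
    if mean_bg > 0:
        counts[~is_true] = rng_cit.negative_binomial(disp_bg, p_bg, int((~is_true).sum()))
    if n_true:
        mean_t, disp_t = config.citations_true
        counts[true_idx] = _truncated_nb(rng_cit, mean_t, disp_t, n_true)

    rng_rec = _rng(config, 2)
    classes = list(_EVIDENCE_CLASS_PROBS)
    class_p = np.array(list(_EVIDENCE_CLASS_PROBS.values()))
    records: list[CitationRecord] = []
    source_counter = 0
    for i in np.flatnonzero(counts):
        c = int(counts[i])
        species = list(rng_rec.choice(SPECIES, size=c, p=np.asarray(config.species_probs)))
        if human_flag[i]:
            species[0] = "human"  # guarantee the human monogenic finding for flagged true genes
        ev_classes = rng_rec.choice(classes, size=c, p=class_p)
        from_db = rng_rec.random(c) < 0.15
        for sp, ec, dbsrc in zip(species, ev_classes, from_db):
            source_counter += 1
            records.append(
                CitationRecord(
                    gene_symbol=symbols[i],
                    species=str(sp),
                    evidence_class=str(ec),
                    source_type="database" if dbsrc else "pmid",
                    source_id=(f"SRC{source_counter}" if dbsrc else f"{source_counter}"),
                )
            )
    evidence = EvidenceDatabase(records)

    # --- GWAS gene-based p-values over the whole universe
    rng_gwas = _rng(config, 3)
    pvals = rng_gwas.uniform(size=config.n_genes)
    if n_true and config.gwas_alt_shape < 1.0:
        pvals[true_idx] = rng_gwas.beta(config.gwas_alt_shape, 1.0, size=n_true)
    gwas = tuple(
        GwasGeneResult(gene_symbol=symbols[i], phenotype="generalized", p_value=float(pvals[i]))
        for i in range(config.n_genes)
    )

    # --- pathways: planted sets load a fixed fraction of members from true
    # genes; background sets are uniform draws from the universe
    rng_path = _rng(config, 4)
    lo, hi = config.pathway_size
    sets: dict[str, list[str]] = {}
    true_list = [symbols[i] for i in true_idx]
    bg_list = [symbols[i] for i in range(config.n_genes) if not is_true[i]]
    for j in range(config.planted_pathway_count):
        size = int(rng_path.integers(lo, hi + 1))
        n_load = min(round(config.planted_loading * size), len(true_list))
        members = list(rng_path.choice(true_list, size=n_load, replace=False))
        members += list(rng_path.choice(bg_list, size=size - n_load, replace=False))
        sets[f"PATH_PLANTED_{j + 1:03d}"] = members
    for j in range(config.n_pathways - config.planted_pathway_count):
        size = int(rng_path.integers(lo, hi + 1))
        sets[f"PATH_RAND_{j + 1:04d}"] = list(rng_path.choice(symbols, size=size, replace=False))
    collection = GeneSetCollection(sets, universe=symbols)
    planted = frozenset(n for n in sets if n.startswith("PATH_PLANTED_"))

    # --- drugs: antiseizure label assigned to a random subset; their targets
    # biased toward the top decile of database genes by citation count
    rng_drug = _rng(config, 5)
    as_idx = set(rng_drug.choice(config.n_drugs, size=config.n_antiseizure, replace=False).tolist())
    db_order = np.argsort(-counts, kind="stable")
    n_top = max(1, int(np.ceil(0.1 * int((counts > 0).sum()))))
    top_genes = [symbols[i] for i in db_order[:n_top]]
    tlo, thi = config.targets_per_drug
    profiles = []
    for d in range(config.n_drugs):
        n_t = int(rng_drug.integers(tlo, thi + 1))
        antiseizure = d in as_idx
        if antiseizure and config.target_bias > 0:
            n_biased = min(round(config.target_bias * n_t), len(top_genes))
            targets = set(rng_drug.choice(top_genes, size=n_biased, replace=False))
            while len(targets) < n_t:
                targets.add(symbols[int(rng_drug.integers(config.n_genes))])
        else:
            targets = set(rng_drug.choice(symbols, size=n_t, replace=False))
        used_in_humans = True if antiseizure else bool(rng_drug.random() < 0.8)
        n_studies = int(rng_drug.poisson(8) + 1) if antiseizure else int(rng_drug.poisson(0.6))
        n_models = min(n_studies, int(rng_drug.integers(1, 7))) if n_studies else 0
        profiles.append(
            DrugProfile(
                drug_name=f"DRUG_{d + 1:04d}",
                targets=frozenset(targets),
                used_in_humans=used_in_humans,
                antiseizure_approved=antiseizure,
                indications=() if antiseizure else (str(rng_drug.choice(_INDICATIONS)),),
                n_animal_studies=n_studies,
                n_animal_models=n_models,
            )
        )

    return SyntheticBundle(
        evidence=evidence,
        gwas=gwas,
        collection=collection,
        drugs=tuple(profiles),
        true_genes=true_genes,
        planted_pathways=planted,
        config=config,
    )


def presets() -> dict[str, SyntheticConfig]:
    """Named study conditions used throughout the test suite.

    * ``strong`` — clearly separated signal: heavily inflated citation
      counts for true genes, 15 planted pathways at 60% true-gene loading,
      GWAS alternative Beta(0.15, 1), antiseizure targets 90% from the top
      citation decile. Planted structure should be recovered.
    * ``moderate`` — attenuated versions of every effect.
    * ``null`` — no true genes, no planted pathways, uniform p-values, and
      unbiased drug targets; 300 background pathways so calibration
      statistics have a usable spread. Everything downstream should be at
      its nominal false-positive level.
    """
    strong = SyntheticConfig()
    moderate = replace(
        strong,
        citations_true=(4.0, 0.8),
        planted_pathway_count=10,
        planted_loading=0.4,
        gwas_alt_shape=0.4,
        target_bias=0.6,
    )
    null = replace(
        strong,
        frac_true=0.0,
        n_pathways=300,
        planted_pathway_count=0,
        planted_loading=0.0,
        gwas_alt_shape=1.0,
        target_bias=0.0,
    )
    return {"strong": strong, "moderate": moderate, "null": null}


def get_preset(name: str, seed: int | None = None) -> SyntheticConfig:
    table = presets()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(table)}")
    config = table[name]
    return config if seed is None else replace(config, seed=seed)
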