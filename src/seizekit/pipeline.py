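"""End-to-end orchestration: inputs -> all analysis artifacts.

``run_all`` executes every stage on one set of inputs (real files or a named
synthetic preset): database summary, polygenic candidate genes,
high-confidence calls, pathway enrichment with its permutation baseline, and
drug ranking/enrichment/repurposing. All artifacts are TSV/JSON in a fixed
layout under the output directory, and a machine-readable ``summary.json``
collects the headline metrics. Every stage is computed before anything is
written, so a failed run leaves no partial artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import confidence as conf
from . import drugs as drugmod
from . import enrichment as enr
from . import evidence as ev
from . import gwas as gwasmod
from . import synthetic

logger = logging.getLogger("seizekit")

__all__ = ["RunConfig", "RunReport", "PipelineError", "load_run_config", "validate", "run_all"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics and exit codes."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Inputs, thresholds, and output layout for one pipeline run.

    Either all input paths are set, or ``preset`` names a synthetic
    configuration (in which case the generated inputs are also written under
    ``<output_dir>/inputs/``).
    """

    output_dir: str | Path = "seizekit_out"
    preset: str | None = None
    evidence_path: str | Path | None = None
    gwas_path: str | Path | None = None
    gwas_phenotype: str = "generalized"
    gmt_path: str | Path | None = None
    drug_targets_path: str | Path | None = None
    drug_meta_path: str | Path | None = None
    known_genes_path: str | Path | None = None
    fdr_threshold: float = 0.05
    min_citations: int = 1
    top_fraction: float = 0.2
    permutations: int = 1000
    keep_duplicates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        paths = (self.evidence_path, self.gwas_path, self.gmt_path,
                 self.drug_targets_path, self.drug_meta_path)
        if self.preset is None and any(p is None for p in paths):
            raise ValueError("either set a synthetic preset or supply all five input paths")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.min_citations < 0:
            raise ValueError("min_citations must be >= 0")


@dataclass(frozen=True)
class RunReport:
    artifacts: Mapping[str, Path]
    metrics: Mapping[str, Any]


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration (keys match :class:`RunConfig` fields)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# validation (findings returned, never raised)

def validate(config: RunConfig) -> list[str]:
    """Schema and invariant checks on all inputs without running analyses."""
    findings: list[str] = []
    if config.preset is not None:
        if config.preset not in synthetic.presets():
            findings.append(f"unknown synthetic preset {config.preset!r}")
        return findings

    def check(path, name):
        if path is None or not Path(path).exists():
            findings.append(f"{name} file missing: {path}")
            return False
        return True

    if check(config.evidence_path, "evidence"):
        try:
            ev.load_evidence(config.evidence_path, keep_duplicates=config.keep_duplicates)
        except ev.EvidenceRowError as exc:
            findings.extend(str(exc).splitlines()[1:])
        except Exception as exc:  # noqa: BLE001 - any parse failure is a finding
            findings.append(f"evidence: {exc}")
    if check(config.gwas_path, "gwas"):
        try:
            frame = pd.read_csv(config.gwas_path, sep="\t")
            if "p_value" not in frame.columns or "gene_symbol" not in frame.columns:
                findings.append(f"gwas: {config.gwas_path} lacks gene_symbol/p_value columns")
            else:
                bad = frame.index[(frame["p_value"] < 0) | (frame["p_value"] > 1) | frame["p_value"].isna()]
                findings.extend(
                    f"gwas line {i + 2}: p_value {frame.loc[i, 'p_value']} outside [0, 1]" for i in bad
                )
        except Exception as exc:  # noqa: BLE001
            findings.append(f"gwas: {exc}")
    if check(config.gmt_path, "gmt"):
        try:
            enr.read_gmt(config.gmt_path)
        except Exception as exc:  # noqa: BLE001
            findings.append(f"gmt: {exc}")
    if check(config.drug_targets_path, "drug targets") and check(config.drug_meta_path, "drug metadata"):
        try:
            drugmod.load_drug_profiles(config.drug_targets_path, config.drug_meta_path)
        except Exception as exc:  # noqa: BLE001
            findings.append(f"drugs: {exc}")
    return findings


# ---------------------------------------------------------------------------
# the run itself

def _load_inputs(config: RunConfig):
    if config.preset is not None:
        cfg = synthetic.get_preset(config.preset, seed=config.seed)
        bundle = synthetic.generate(cfg)
        db = bundle.evidence
        if not config.keep_duplicates:
            db = ev.EvidenceDatabase(ev.deduplicate(db.records))
        gwas = gwasmod.attach_bh_fdr(list(bundle.gwas))
        return db, gwas, bundle.collection, list(bundle.drugs), bundle
    db = ev.load_evidence(config.evidence_path, keep_duplicates=config.keep_duplicates)
    gwas = gwasmod.load_gwas_results(config.gwas_path, config.gwas_phenotype)
    collection = enr.read_gmt(config.gmt_path)
    profiles = drugmod.load_drug_profiles(config.drug_targets_path, config.drug_meta_path)
    return db, gwas, collection, profiles, None


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage and write the full artifact set.

    Returns a report with the artifact paths and the machine-readable
    metrics; each metric equals the value returned by calling the
    corresponding module operation directly on the same inputs.
    """
    out = Path(config.output_dir)

    try:
        db, gwas, collection, profiles, bundle = _load_inputs(config)
    except (FileNotFoundError, ValueError, KeyError) as exc:
        raise PipelineError("load", str(exc)) from exc
    logger.info(
        "inputs: %d genes, %d records (dedup=%s), %d gwas genes, %d pathways, %d drugs",
        db.n_genes, db.n_evidence, not config.keep_duplicates, len(gwas), len(collection), len(profiles),
    )

    try:
        summary = ev.summarize(db)
        candidates = gwasmod.candidate_polygenic_genes(
            db, gwas, fdr_threshold=config.fdr_threshold, min_citations=config.min_citations
        )
        if config.known_genes_path is not None:
            known = {line.strip().upper() for line in Path(config.known_genes_path).read_text().splitlines() if line.strip()}
            candidates = gwasmod.novel_candidates(candidates, known)
        calls = conf.high_confidence_genes(db)
    except (ValueError, KeyError) as exc:
        raise PipelineError("candidates", str(exc)) from exc

    try:
        report = enr.enrich_collection(db.genes.keys(), collection, fdr_threshold=config.fdr_threshold)
        logger.info("enrichment universe %d, query used %d (dropped %d)",
                    len(collection.universe), report.n_query_used, report.n_query_dropped)
        perm = enr.permutation_baseline(
            db_gene_count=report.n_query_used,
            collection=collection,
            observed_count=report.n_significant,
            B=config.permutations,
            seed=config.seed,
            fdr_threshold=config.fdr_threshold,
        )
    except ValueError as exc:
        raise PipelineError("enrichment", str(exc)) from exc

    try:
        ranks = drugmod.drug_scores(db, profiles)
        labels = {p.drug_name: p.antiseizure_approved for p in profiles}
        drug_enr = drugmod.rank_enrichment(ranks, labels, top_fraction=config.top_fraction)
        logger.info("drug enrichment: top bin m=%d of N=%d", drug_enr.m_top_bin, drug_enr.N_drugs)
        repurposing = drugmod.repurposing_candidates(ranks, profiles, db)
    except ValueError as exc:
        raise PipelineError("drugs", str(exc)) from exc

    n_high_conf = sum(c.high_confidence for c in calls)
    metrics: dict[str, Any] = {
        "n_genes": summary.n_genes,
        "n_evidence": summary.n_evidence,
        "n_candidates": len(candidates),
        "n_high_confidence": n_high_conf,
        "n_significant_pathways": report.n_significant,
        "permutation_empirical_p": perm.empirical_p,
        "drug_enrichment_fold": drug_enr.fold,
        "drug_enrichment_p": drug_enr.p_value,
        "settings": {
            "fdr_threshold": config.fdr_threshold,
            "min_citations": config.min_citations,
            "top_fraction": config.top_fraction,
            "top_bin_m": drug_enr.m_top_bin,
            "n_drugs": drug_enr.N_drugs,
            "permutations": config.permutations,
            "universe_size": len(collection.universe),
            "query_used": report.n_query_used,
            "deduplicate": not config.keep_duplicates,
            "seed": config.seed,
            "preset": config.preset,
        },
    }

    # all computation done; write artifacts
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    if bundle is not None:
        for name, path in bundle.write(out / "inputs").items():
            artifacts[f"input_{name}"] = path

    def emit(name: str, filename: str, frame: pd.DataFrame) -> None:
        path = out / filename
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        artifacts[name] = path

    emit("summary", "summary.tsv", summary.to_frame())
    emit("candidates", "candidates.tsv", gwasmod.candidates_frame(candidates))
    emit("confidence", "confidence_calls.tsv", conf.calls_frame(calls))
    emit("enrichment", "enrichment.tsv", report.to_frame())
    emit("drug_ranking", "drug_ranking.tsv", drugmod.ranking_frame(ranks))
    emit("repurposing", "repurposing.tsv", drugmod.repurposing_frame(repurposing))

    perm_payload = {
        "observed_count": perm.observed_count,
        "empirical_p": perm.empirical_p,
        "B": perm.B,
        "threshold": perm.threshold,
        "threshold_on": perm.threshold_on,
        "null_count_max": max(perm.null_counts),
        "null_count_mean": sum(perm.null_counts) / perm.B,
    }
    for name, filename, payload in (
        ("permutation", "permutation.json", perm_payload),
        ("drug_enrichment", "drug_enrichment.json", {
            "N_drugs": drug_enr.N_drugs, "K_labeled": drug_enr.K_labeled,
            "m_top_bin": drug_enr.m_top_bin, "k_labeled_in_bin": drug_enr.k_labeled_in_bin,
            "fold": drug_enr.fold, "p_value": drug_enr.p_value,
        }),
        ("summary_json", "summary.json", metrics),
    ):
        path = out / filename
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        artifacts[name] = path

    (out / "summary.txt").write_text(summary.report() + "\n", encoding="utf-8")
    artifacts["summary_txt"] = out / "summary.txt"

    return RunReport(artifacts=artifacts, metrics=metrics)
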