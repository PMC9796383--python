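"""Polygenic candidate-gene identification from gene-based GWAS results.

A gene found significant in a common-epilepsy GWAS is more credible as a
causal candidate if its disruption is also known to cause seizures/epilepsy
in monogenic cases or animal models. This module converts gene-based GWAS
p-values to Benjamini-Hochberg FDRs and intersects the significant genes
with the monogenic citation evidence in an :class:`~seizekit.evidence.EvidenceDatabase`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .evidence import EvidenceDatabase

__all__ = [
    "PHENOTYPES",
    "GwasGeneResult",
    "CandidateGene",
    "bh_fdr",
    "attach_bh_fdr",
    "load_gwas_results",
    "candidate_polygenic_genes",
    "significant_without_monogenic_support",
    "novel_candidates",
    "candidates_frame",
]

PHENOTYPES: tuple[str, ...] = ("generalized", "focal", "other")


@dataclass(frozen=True)
class GwasGeneResult:
    """Gene-level GWAS association for one phenotype.

    ``fdr`` is normally derived from the p-values of the whole table via
    :func:`attach_bh_fdr`; it may also be supplied directly when only
    published FDRs are available.
    """

    gene_symbol: str
    phenotype: str
    p_value: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        sym = self.gene_symbol.strip().upper()
        object.__setattr__(self, "gene_symbol", sym)
        if not sym:
            raise ValueError("gene_symbol must be non-empty")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class CandidateGene:
    """A polygenic candidate: GWAS-significant with monogenic corroboration."""

    gene_symbol: str
    fdr: float
    monogenic_citations: int
    novel: bool = False


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, order-aligned with input.

    Equivalent to q_(i) = min_{j >= i} p_(j) * m / j over the sorted
    p-values, mapped back to the original order and capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def attach_bh_fdr(results: Sequence[GwasGeneResult]) -> list[GwasGeneResult]:
    """Return results with ``fdr`` filled by BH across the whole table.

    The FDR is computed over every gene in the supplied table, so the table
    must be the full tested universe for the phenotype, not a significant
    subset.
    """
    fdrs = bh_fdr([r.p_value for r in results])
    return [replace(r, fdr=q) for r, q in zip(results, fdrs)]


def load_gwas_results(path: str | Path, phenotype: str, *, compute_fdr: bool = True) -> list[GwasGeneResult]:
    """Read a gene-based GWAS TSV (columns gene_symbol, p_value)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str}, float_precision="round_trip")
    for col in ("gene_symbol", "p_value"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    results = [
        GwasGeneResult(gene_symbol=row.gene_symbol, phenotype=phenotype, p_value=float(row.p_value))
        for row in frame.itertuples(index=False)
    ]
    return attach_bh_fdr(results) if compute_fdr else results


def _require_fdr(results: Iterable[GwasGeneResult]) -> list[GwasGeneResult]:
    out = list(results)
    if any(r.fdr is None for r in out):
        raise ValueError("GWAS results lack FDRs; call attach_bh_fdr first")
    phenos = {r.phenotype for r in out}
    if len(phenos) > 1:
        raise ValueError(f"results mix phenotypes {sorted(phenos)}; supply one phenotype at a time")
    return out


def candidate_polygenic_genes(
    db: EvidenceDatabase,
    gwas: Sequence[GwasGeneResult],
    fdr_threshold: float = 0.05,
    min_citations: int = 1,
) -> list[CandidateGene]:
    """Genes with gene-based FDR < threshold AND monogenic citation support.

    Returns exactly the genes passing both filters, sorted by FDR ascending
    with ties broken by symbol. Genes significant in the GWAS but absent
    from the evidence database are not candidates (see
    :func:`significant_without_monogenic_support`).
    """
    results = _require_fdr(gwas)
    out = [
        CandidateGene(
            gene_symbol=r.gene_symbol,
            fdr=float(r.fdr),  # type: ignore[arg-type]
            monogenic_citations=db.total_citations(r.gene_symbol),
        )
        for r in results
        if r.fdr < fdr_threshold and db.total_citations(r.gene_symbol) >= max(min_citations, 1)
    ]
    out.sort(key=lambda c: (c.fdr, c.gene_symbol))
    return out


def significant_without_monogenic_support(
    db: EvidenceDatabase,
    gwas: Sequence[GwasGeneResult],
    fdr_threshold: float = 0.05,
) -> list[GwasGeneResult]:
    """GWAS-significant genes lacking any monogenic citation — reported
    separately from candidates, never merged into them."""
    results = _require_fdr(gwas)
    out = [r for r in results if r.fdr < fdr_threshold and db.total_citations(r.gene_symbol) == 0]
    out.sort(key=lambda r: (r.fdr, r.gene_symbol))
    return out


def novel_candidates(candidates: Sequence[CandidateGene], known_genes: set[str]) -> list[CandidateGene]:
    """Candidates absent from a supplied known-gene list, with ``novel`` set."""
    known = {g.strip().upper() for g in known_genes}
    return [replace(c, novel=True) for c in candidates if c.gene_symbol not in known]


def candidates_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Tabular view (gene, citations, FDR, novel) for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene_symbol": c.gene_symbol,
                "monogenic_citations": c.monogenic_citations,
                "fdr": c.fdr,
                "novel": c.novel,
            }
            for c in candidates
        ],
        columns=["gene_symbol", "monogenic_citations", "fdr", "novel"],
    )
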