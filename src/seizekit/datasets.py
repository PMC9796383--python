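"""Packaged reference tables and the fixtures built from them.

Two small published reference tables ship with the package:

* ``ge_gwas_candidates.tsv`` — the 16 candidate causal generalized-epilepsy
  genes: GWAS gene-based FDR < .05 for generalized epilepsy together with
  the number of monogenic citations each gene carries in the cross-species
  evidence database (range 1-290; SCN1A dominates with 290).
* ``repurposing_reference.tsv`` — 16 repurposing-triage rows: drugs used in
  humans for non-epilepsy indications, their total target-gene citation
  scores, and their animal-model antiseizure efficacy evidence (study and
  model counts).

Twelve of the sixteen candidate genes had not been reported by the source
GWAS; the remaining four (SCN1A, GABRA2, PCDH7, TTC21B) were previously
reported and serve as the known-gene list for the novelty filter.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .drugs import DrugProfile
from .evidence import CitationRecord, EvidenceDatabase
from .gwas import GwasGeneResult

__all__ = [
    "PREVIOUSLY_REPORTED_GE_GENES",
    "NOVEL_GE_GENES",
    "load_ge_candidate_table",
    "ge_reference_bundle",
    "load_repurposing_reference",
    "repurposing_reference_profiles",
]

#: Generalized-epilepsy candidate genes already reported by the source GWAS.
PREVIOUSLY_REPORTED_GE_GENES = frozenset({"SCN1A", "GABRA2", "PCDH7", "TTC21B"})

#: The 12 newly reported generalized-epilepsy candidate genes.
NOVEL_GE_GENES = frozenset(
    {"AP3D1", "CAMTA1", "DOC2A", "GRM4", "MMP27", "PHACTR1",
     "RAPGEF2", "RBFOX1", "RIMS1", "SETD1A", "STX1B", "UBTF"}
)


def _data(name: str) -> pd.DataFrame:
    with resources.files("seizekit.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_ge_candidate_table() -> pd.DataFrame:
    """Reference candidate table: gene_symbol, monogenic_citations, ge_fdr."""
    return _data("ge_gwas_candidates.tsv")


def ge_reference_bundle() -> tuple[EvidenceDatabase, list[GwasGeneResult]]:
    """Evidence database + GWAS results reconstructed from the reference table.

    Each gene's citation count is expanded into that many synthetic human
    citation records (the reference table reports totals, not per-species
    breakdowns). The published gene-based FDRs are attached directly — the
    underlying p-values are not part of the reference table, so ``p_value``
    is set equal to the FDR as a conservative placeholder; only the FDR
    enters the candidate filter.
    """
    table = load_ge_candidate_table()
    records = []
    source = 0
    for row in table.itertuples(index=False):
        for _ in range(int(row.monogenic_citations)):
            source += 1
            records.append(
                CitationRecord(
                    gene_symbol=row.gene_symbol,
                    species="human",
                    evidence_class="variant_association",
                    source_type="pmid",
                    source_id=str(source),
                )
            )
    gwas = [
        GwasGeneResult(
            gene_symbol=row.gene_symbol,
            phenotype="generalized",
            p_value=float(row.ge_fdr),
            fdr=float(row.ge_fdr),
        )
        for row in table.itertuples(index=False)
    ]
    return EvidenceDatabase(records), gwas


def load_repurposing_reference() -> pd.DataFrame:
    """Reference repurposing rows: drug, indications, citations, studies, models."""
    return _data("repurposing_reference.tsv")


def repurposing_reference_profiles() -> list[DrugProfile]:
    """Drug profiles for the reference repurposing rows (targets unlisted in
    the reference table, so each profile carries an empty target set)."""
    table = load_repurposing_reference()
    return [
        DrugProfile(
            drug_name=row.drug_name,
            targets=frozenset(),
            used_in_humans=True,
            antiseizure_approved=False,
            indications=tuple(row.indications.split(";")),
            n_animal_studies=int(row.studies),
            n_animal_models=int(row.models),
        )
        for row in table.itertuples(index=False)
    ]
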