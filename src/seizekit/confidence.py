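"""High-confidence monogenic epilepsy gene classification.

A human monogenic finding is more credible when mutation or manipulation of
the same gene also causes seizures/epilepsy in a nonhuman species: the
cross-species functional corroboration stands in for the computational
pathogenicity scores used by earlier gene lists. A gene is called
high-confidence here iff it has >= 1 human citation and >= 1 citation in
any other species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .evidence import NONHUMAN_SPECIES, EvidenceDatabase

__all__ = ["ConfidenceCall", "SetComparison", "high_confidence_genes", "compare_sets"]

#: The five named model organisms (excludes the catch-all "other" token).
MODEL_ORGANISMS: tuple[str, ...] = ("dog", "rodent", "zebrafish", "fly", "worm")


@dataclass(frozen=True)
class ConfidenceCall:
    gene_symbol: str
    human_monogenic: bool
    nonhuman_species_with_evidence: tuple[str, ...]
    high_confidence: bool


@dataclass(frozen=True)
class SetComparison:
    """Venn-style partition of two gene sets."""

    n_only_a: int
    n_only_b: int
    n_both: int
    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, members in (("only_a", self.only_a), ("both", self.both), ("only_b", self.only_b)):
            for g in sorted(members):
                rows.append({"region": region, "gene_symbol": g})
        return pd.DataFrame(rows, columns=["region", "gene_symbol"])


def high_confidence_genes(
    db: EvidenceDatabase, *, include_other_species: bool = True
) -> list[ConfidenceCall]:
    """One call per gene with human evidence; high-confidence iff it also has
    evidence in another species.

    ``include_other_species=False`` restricts the corroborating species to
    the five named model organisms, excluding the catch-all ``other`` token.
    Evidence class is not restricted: variant associations and direct gene
    manipulations both count. Genes with only nonhuman evidence are not
    listed (no human monogenic finding to corroborate).
    """
    allowed = NONHUMAN_SPECIES if include_other_species else MODEL_ORGANISMS
    calls = []
    for gene in db.genes.values():
        if gene.citations("human") < 1:
            continue
        nonhuman = tuple(s for s in allowed if gene.citations(s) > 0)
        calls.append(
            ConfidenceCall(
                gene_symbol=gene.gene_symbol,
                human_monogenic=True,
                nonhuman_species_with_evidence=nonhuman,
                high_confidence=bool(nonhuman),
            )
        )
    calls.sort(key=lambda c: c.gene_symbol)
    return calls


def compare_sets(a: Iterable[str], b: Iterable[str]) -> SetComparison:
    """Exact three-region partition of two symbol sets (Venn counts)."""
    sa, sb = set(a), set(b)
    both = frozenset(sa & sb)
    only_a = frozenset(sa - sb)
    only_b = frozenset(sb - sa)
    return SetComparison(
        n_only_a=len(only_a),
        n_only_b=len(only_b),
        n_both=len(both),
        only_a=only_a,
        only_b=only_b,
        both=both,
    )


def calls_frame(calls: Sequence[ConfidenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_symbol": c.gene_symbol,
                "human_monogenic": c.human_monogenic,
                "nonhuman_species": ";".join(c.nonhuman_species_with_evidence),
                "high_confidence": c.high_confidence,
            }
            for c in calls
        ],
        columns=["gene_symbol", "human_monogenic", "nonhuman_species", "high_confidence"],
    )
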