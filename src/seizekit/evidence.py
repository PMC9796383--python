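"""Cross-species seizure/epilepsy gene evidence model.

The central object is :class:`EvidenceDatabase`: a flat list of per-citation
records (one row per publication or database entry linking a gene to a
seizure/epilepsy phenotype in some species) plus per-gene summaries derived
from it. Species are restricted to a fixed seven-token vocabulary in which
``rodent`` aggregates mouse and rat; inputs using finer taxonomy must be
pre-mapped. Gene symbols are human symbols (nonhuman genes are assumed
already mapped to their human orthologs upstream).

Citation counts are the database's measure of the strength of a gene's
association with seizures/epilepsy; they drive the gene filter/sort engine
here and the drug scoring in :mod:`seizekit.drugs`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SPECIES",
    "EVIDENCE_CLASSES",
    "SOURCE_TYPES",
    "CitationRecord",
    "GeneRecord",
    "EvidenceDatabase",
    "FilterSpec",
    "DatabaseSummary",
    "EvidenceFormatError",
    "EvidenceRowError",
    "load_evidence",
    "write_evidence",
    "deduplicate",
    "summarize",
    "filter_genes",
]

#: Fixed species vocabulary. ``rodent`` aggregates mouse and rat; ``other``
#: is a catch-all for species outside the five named model organisms.
SPECIES: tuple[str, ...] = ("human", "dog", "rodent", "zebrafish", "fly", "worm", "other")

NONHUMAN_SPECIES: tuple[str, ...] = tuple(s for s in SPECIES if s != "human")

EVIDENCE_CLASSES: tuple[str, ...] = (
    "variant_association",   # mutation/variant/polymorphism found in affected subjects
    "direct_manipulation",   # knockout, knockin, RNAi, CRISPR, antisense, ...
    "database_record",       # bulk import from a curated gene-disease database
)

SOURCE_TYPES: tuple[str, ...] = ("pmid", "database")

REQUIRED_COLUMNS = ("gene_symbol", "species", "evidence_class", "source_type", "source_id")
OPTIONAL_COLUMNS = ("phenotype_note", "year")


class EvidenceFormatError(ValueError):
    """The evidence table as a whole does not match the expected dialect."""


class EvidenceRowError(ValueError):
    """One or more rows violate a field-level constraint (offending lines listed)."""


@dataclass(frozen=True)
class CitationRecord:
    """A single piece of evidence linking one gene to seizures/epilepsy."""

    gene_symbol: str
    species: str
    evidence_class: str
    source_type: str
    source_id: str
    phenotype_note: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        sym = self.gene_symbol.strip().upper()
        object.__setattr__(self, "gene_symbol", sym)
        if not sym:
            raise ValueError("gene_symbol must be non-empty")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(
                f"unknown evidence_class {self.evidence_class!r}; expected one of {EVIDENCE_CLASSES}"
            )
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}; expected one of {SOURCE_TYPES}")
        if not str(self.source_id).strip():
            raise ValueError("source_id must be non-empty")

    @property
    def dedup_key(self) -> tuple[str, str, str]:
        return (self.gene_symbol, self.source_type, self.source_id)


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene aggregation of citation evidence."""

    gene_symbol: str
    citations_by_species: Mapping[str, int]
    total_citations: int
    syndromes: tuple[str, ...] = ()

    def citations(self, species: str) -> int:
        return int(self.citations_by_species.get(species, 0))

    @property
    def nonhuman_species(self) -> tuple[str, ...]:
        return tuple(s for s in NONHUMAN_SPECIES if self.citations(s) > 0)


@dataclass(frozen=True)
class DatabaseSummary:
    n_genes: int
    n_evidence: int
    genes_per_species: Mapping[str, int]
    citations_per_species: Mapping[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": s,
                "n_genes": self.genes_per_species.get(s, 0),
                "n_citations": self.citations_per_species.get(s, 0),
            }
            for s in SPECIES
        ]
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [
            f"genes: {self.n_genes}",
            f"evidence records: {self.n_evidence}",
        ]
        for s in SPECIES:
            lines.append(
                f"  {s}: {self.genes_per_species.get(s, 0)} genes, "
                f"{self.citations_per_species.get(s, 0)} citations"
            )
        return "\n".join(lines)


def deduplicate(records: Sequence[CitationRecord]) -> list[CitationRecord]:
    """Collapse records citing the same source for the same gene.

    A primary publication and a curated database entry derived from it can
    both appear for one gene; within a source type, repeated (gene,
    source_id) pairs are certainly redundant and are collapsed to the first
    occurrence. Order is otherwise preserved.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[CitationRecord] = []
    for rec in records:
        key = rec.dedup_key
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


class EvidenceDatabase:
    """Citation records plus derived per-gene summaries.

    Invariant: the per-species citation counts over all genes sum to the
    number of retained records, and every gene present has >= 1 citation.
    """

    def __init__(self, records: Iterable[CitationRecord]):
        self.records: list[CitationRecord] = list(records)
        self.genes: dict[str, GeneRecord] = self._derive_genes(self.records)

    @staticmethod
    def _derive_genes(records: Sequence[CitationRecord]) -> dict[str, GeneRecord]:
        by_species: dict[str, Counter] = {}
        syndromes: dict[str, list[str]] = {}
        for rec in records:
            by_species.setdefault(rec.gene_symbol, Counter())[rec.species] += 1
            note = (rec.phenotype_note or "").strip()
            if note:
                notes = syndromes.setdefault(rec.gene_symbol, [])
                if note not in notes:
                    notes.append(note)
        return {
            sym: GeneRecord(
                gene_symbol=sym,
                citations_by_species=dict(counts),
                total_citations=sum(counts.values()),
                syndromes=tuple(syndromes.get(sym, ())),
            )
            for sym, counts in sorted(by_species.items())
        }

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_evidence(self) -> int:
        return len(self.records)

    def total_citations(self, symbol: str) -> int:
        rec = self.genes.get(symbol)
        return rec.total_citations if rec is not None else 0

    def gene_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes.values():
            row = {"gene_symbol": g.gene_symbol, "total_citations": g.total_citations}
            for s in SPECIES:
                row[f"citations_{s}"] = g.citations(s)
            row["syndromes"] = ";".join(g.syndromes)
            rows.append(row)
        cols = ["gene_symbol", "total_citations"] + [f"citations_{s}" for s in SPECIES] + ["syndromes"]
        return pd.DataFrame(rows, columns=cols)


def _parse_year(value) -> int | None:
    if value is None:
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    return int(float(text))


def load_evidence(path: str | Path, *, keep_duplicates: bool = False) -> EvidenceDatabase:
    """Read an evidence TSV into an :class:`EvidenceDatabase`.

    The dialect is UTF-8, tab-separated, header required, with columns
    ``gene_symbol``, ``species``, ``evidence_class``, ``source_type``,
    ``source_id`` and optional ``phenotype_note``, ``year``. Gene symbols
    are uppercased and stripped of surrounding whitespace.

    Deduplication on (gene, source_type, source_id) is ON by default; pass
    ``keep_duplicates=True`` to preserve every row, mirroring published
    totals from databases that count a primary study and a derived database
    entry separately.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise EvidenceFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[CitationRecord] = []
    errors: list[str] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # line 1 is the header
        try:
            records.append(
                CitationRecord(
                    gene_symbol=getattr(row, "gene_symbol"),
                    species=getattr(row, "species").strip(),
                    evidence_class=getattr(row, "evidence_class").strip(),
                    source_type=getattr(row, "source_type").strip(),
                    source_id=getattr(row, "source_id").strip(),
                    phenotype_note=(getattr(row, "phenotype_note", "") or None),
                    year=_parse_year(getattr(row, "year", None)),
                )
            )
        except ValueError as exc:
            errors.append(f"line {idx}: {exc}")
    if errors:
        raise EvidenceRowError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))

    if not keep_duplicates:
        records = deduplicate(records)
    return EvidenceDatabase(records)


def write_evidence(db: EvidenceDatabase, path: str | Path) -> None:
    """Write the database back to the evidence TSV dialect (bit-stable)."""
    rows = [
        {
            "gene_symbol": r.gene_symbol,
            "species": r.species,
            "evidence_class": r.evidence_class,
            "source_type": r.source_type,
            "source_id": r.source_id,
            "phenotype_note": r.phenotype_note or "",
            "year": "" if r.year is None else str(r.year),
        }
        for r in db.records
    ]
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:2]) + list(REQUIRED_COLUMNS[2:]) + list(OPTIONAL_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def summarize(db: EvidenceDatabase) -> DatabaseSummary:
    """Headline counts: genes, evidence records, and per-species breakdowns."""
    genes_per_species: Counter = Counter()
    citations_per_species: Counter = Counter()
    for g in db.genes.values():
        for s, c in g.citations_by_species.items():
            if c > 0:
                genes_per_species[s] += 1
                citations_per_species[s] += c
    return DatabaseSummary(
        n_genes=db.n_genes,
        n_evidence=db.n_evidence,
        genes_per_species=dict(genes_per_species),
        citations_per_species=dict(citations_per_species),
    )


@dataclass(frozen=True)
class FilterSpec:
    """User-defined evidence thresholds for the gene filter/sort engine.

    Every populated criterion must be met (conjunction). Thresholds are
    minimum citation counts; substring matches are case-insensitive.
    """

    min_citations_by_species: Mapping[str, int] = field(default_factory=dict)
    min_total_citations: int = 0
    gene_substring: str | None = None
    syndrome_substring: str | None = None

    def __post_init__(self) -> None:
        for s, v in self.min_citations_by_species.items():
            if s not in SPECIES:
                raise ValueError(f"unknown species {s!r} in filter")
            if v < 0:
                raise ValueError("species citation threshold must be >= 0")
        if self.min_total_citations < 0:
            raise ValueError("min_total_citations must be >= 0")

    def matches(self, gene: GeneRecord) -> bool:
        if gene.total_citations < self.min_total_citations:
            return False
        for s, v in self.min_citations_by_species.items():
            if gene.citations(s) < v:
                return False
        if self.gene_substring is not None:
            if self.gene_substring.strip().upper() not in gene.gene_symbol:
                return False
        if self.syndrome_substring is not None:
            needle = self.syndrome_substring.strip().lower()
            if not any(needle in s.lower() for s in gene.syndromes):
                return False
        return True


def filter_genes(db: EvidenceDatabase, spec: FilterSpec | None = None) -> list[GeneRecord]:
    """Genes meeting every populated criterion, ordered by descending total
    citations with ties broken by symbol (ascending)."""
    spec = spec or FilterSpec()
    hits = [g for g in db.genes.values() if spec.matches(g)]
    hits.sort(key=lambda g: (-g.total_citations, g.gene_symbol))
    return hits
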