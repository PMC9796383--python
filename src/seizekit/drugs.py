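"""Citation-weighted drug prioritization and repurposing triage.

Hypothesis: a drug is more likely to affect seizures if there is more
evidence that the genes it affects are associated with seizures. Each drug
is scored by the total citation count, over all species and evidence
classes, of its target genes in the evidence database; drugs are ranked by
that score and the ranking is validated by testing whether approved
antiseizure drugs are over-represented in the top quantile (hypergeometric
upper tail).

Repurposing triage keeps drugs that (1) are already used in humans for
non-epilepsy indications, (2) affect at least one database gene, and
(3) have antiseizure efficacy evidence in animal models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import hypergeom_overrep
from .evidence import EvidenceDatabase

__all__ = [
    "DrugProfile",
    "DrugRank",
    "RankEnrichment",
    "RepurposingCandidate",
    "load_drug_profiles",
    "write_drug_profiles",
    "drug_scores",
    "rank_enrichment",
    "repurposing_candidates",
    "ranking_frame",
    "repurposing_frame",
]


@dataclass(frozen=True)
class DrugProfile:
    """A drug with its target genes and clinical/preclinical metadata.

    ``n_animal_studies`` counts studies demonstrating antiseizure efficacy
    in animal models; ``n_animal_models`` counts the distinct models.
    """

    drug_name: str
    targets: frozenset[str]
    used_in_humans: bool
    antiseizure_approved: bool
    indications: tuple[str, ...] = ()
    n_animal_studies: int = 0
    n_animal_models: int = 0

    def __post_init__(self) -> None:
        if not self.drug_name.strip():
            raise ValueError("drug_name must be non-empty")
        if self.antiseizure_approved and not self.used_in_humans:
            raise ValueError(f"{self.drug_name}: antiseizure_approved implies used_in_humans")
        if self.n_animal_studies < 0 or self.n_animal_models < 0:
            raise ValueError(f"{self.drug_name}: animal study/model counts must be >= 0")
        object.__setattr__(self, "targets", frozenset(g.strip().upper() for g in self.targets))


@dataclass(frozen=True)
class DrugRank:
    drug_name: str
    score: int
    rank: int
    percentile: float


@dataclass(frozen=True)
class RankEnrichment:
    """Top-quantile enrichment of labeled drugs in a ranking.

    fold = (k/K) / (m/N): the proportion of labeled drugs inside the top bin
    relative to the bin's share of the whole list; 100% of labels in a
    top-20% bin forces fold = 5.
    """

    N_drugs: int
    K_labeled: int
    m_top_bin: int
    k_labeled_in_bin: int
    fold: float
    p_value: float


@dataclass(frozen=True)
class RepurposingCandidate:
    drug_name: str
    indications: tuple[str, ...]
    score: int
    n_targets_in_db: int
    n_animal_studies: int
    n_animal_models: int


def drug_scores(
    db: EvidenceDatabase,
    profiles: Sequence[DrugProfile],
    species_weights: Mapping[str, float] | None = None,
) -> list[DrugRank]:
    """Rank drugs by total target-gene citations.

    Targets absent from the database contribute 0; drugs with no database
    targets are retained with score 0 (they still occupy ranking slots and
    therefore affect enrichment p-values). Descending score, ties broken by
    drug name ascending; percentile = rank / N.

    ``species_weights`` optionally reweights citations per species
    (default: every citation counts 1).
    """
    names = [p.drug_name for p in profiles]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate drug_name(s): {', '.join(dupes)}")

    def gene_score(symbol: str) -> float:
        gene = db.genes.get(symbol)
        if gene is None:
            return 0.0
        if species_weights is None:
            return float(gene.total_citations)
        return sum(species_weights.get(s, 1.0) * c for s, c in gene.citations_by_species.items())

    scored = sorted(
        ((sum(gene_score(t) for t in p.targets), p.drug_name) for p in profiles),
        key=lambda pair: (-pair[0], pair[1]),
    )
    N = len(scored)
    return [
        DrugRank(drug_name=name, score=int(score) if species_weights is None else score,
                 rank=i, percentile=i / N)
        for i, (score, name) in enumerate(scored, start=1)
    ]


def rank_enrichment(
    ranks: Sequence[DrugRank],
    labels: Mapping[str, bool],
    top_fraction: float = 0.2,
) -> RankEnrichment:
    """Hypergeometric enrichment of labeled drugs in the top quantile.

    The top bin holds the first m = ceil(top_fraction * N) ranks (ties at
    the boundary were already resolved by the deterministic name tie-break
    in :func:`drug_scores`). p = P(X >= k) with X ~ Hypergeom(N, K, m).
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must be in (0, 1)")
    missing = [r.drug_name for r in ranks if r.drug_name not in labels]
    if missing:
        raise ValueError(f"labels missing for: {', '.join(missing[:5])}")
    N = len(ranks)
    K = sum(bool(labels[r.drug_name]) for r in ranks)
    if K == 0:
        raise ValueError("no labeled drugs in the ranking")
    m = math.ceil(top_fraction * N)
    k = sum(bool(labels[r.drug_name]) for r in ranks if r.rank <= m)
    fold = (k / K) / (m / N) if m > 0 else float("nan")
    return RankEnrichment(
        N_drugs=N, K_labeled=K, m_top_bin=m, k_labeled_in_bin=k,
        fold=fold, p_value=hypergeom_overrep(k, K, m, N),
    )


def repurposing_candidates(
    ranks: Sequence[DrugRank],
    profiles: Sequence[DrugProfile],
    db: EvidenceDatabase,
) -> list[RepurposingCandidate]:
    """Three-criterion repurposing triage, sorted by score descending.

    Keeps drugs used in humans but not approved for epilepsy, with >= 1
    target in the database and >= 1 animal study of antiseizure efficacy.
    """
    score_of = {r.drug_name: r.score for r in ranks}
    out = []
    for p in profiles:
        n_db_targets = sum(t in db for t in p.targets)
        if (
            p.used_in_humans
            and not p.antiseizure_approved
            and n_db_targets >= 1
            and p.n_animal_studies >= 1
        ):
            out.append(
                RepurposingCandidate(
                    drug_name=p.drug_name,
                    indications=p.indications,
                    score=score_of.get(p.drug_name, 0),
                    n_targets_in_db=n_db_targets,
                    n_animal_studies=p.n_animal_studies,
                    n_animal_models=p.n_animal_models,
                )
            )
    out.sort(key=lambda c: (-c.score, c.drug_name))
    return out


# ---------------------------------------------------------------------------
# TSV I/O: drug->target pairs (drug_name, target_gene) and drug metadata
# (drug_name, used_in_humans, antiseizure_approved, indications,
#  n_animal_studies, n_animal_models).

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(value, context: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL:
        raise ValueError(f"{context}: cannot parse boolean {value!r}")
    return _BOOL[key]


def load_drug_profiles(targets_path: str | Path, meta_path: str | Path) -> list[DrugProfile]:
    targets = pd.read_csv(targets_path, sep="\t", dtype=str, keep_default_na=False)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug_name", "target_gene"):
        if col not in targets.columns:
            raise ValueError(f"{targets_path}: missing column {col!r}")
    needed = ("drug_name", "used_in_humans", "antiseizure_approved",
              "indications", "n_animal_studies", "n_animal_models")
    missing = [c for c in needed if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path}: missing column(s): {', '.join(missing)}")

    target_map: dict[str, set[str]] = {}
    for row in targets.itertuples(index=False):
        target_map.setdefault(row.drug_name.strip(), set()).add(row.target_gene)

    profiles = []
    for row in meta.itertuples(index=False):
        name = row.drug_name.strip()
        profiles.append(
            DrugProfile(
                drug_name=name,
                targets=frozenset(target_map.get(name, set())),
                used_in_humans=_parse_bool(row.used_in_humans, name),
                antiseizure_approved=_parse_bool(row.antiseizure_approved, name),
                indications=tuple(s for s in row.indications.split(";") if s.strip()),
                n_animal_studies=int(row.n_animal_studies),
                n_animal_models=int(row.n_animal_models),
            )
        )
    return profiles


def write_drug_profiles(profiles: Sequence[DrugProfile], targets_path: str | Path, meta_path: str | Path) -> None:
    target_rows = [
        {"drug_name": p.drug_name, "target_gene": t}
        for p in profiles
        for t in sorted(p.targets)
    ]
    pd.DataFrame(target_rows, columns=["drug_name", "target_gene"]).to_csv(
        targets_path, sep="\t", index=False, lineterminator="\n")
    meta_rows = [
        {
            "drug_name": p.drug_name,
            "used_in_humans": str(p.used_in_humans).lower(),
            "antiseizure_approved": str(p.antiseizure_approved).lower(),
            "indications": ";".join(p.indications),
            "n_animal_studies": p.n_animal_studies,
            "n_animal_models": p.n_animal_models,
        }
        for p in profiles
    ]
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False, lineterminator="\n")


def ranking_frame(ranks: Sequence[DrugRank]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"drug_name": r.drug_name, "score": r.score, "rank": r.rank, "percentile": r.percentile}
         for r in ranks],
        columns=["drug_name", "score", "rank", "percentile"],
    )


def repurposing_frame(candidates: Sequence[RepurposingCandidate]) -> pd.DataFrame:
    """Table-shaped view: drug, indications, citations, studies, models."""
    return pd.DataFrame(
        [
            {
                "drug_name": c.drug_name,
                "indications": ";".join(c.indications),
                "citations": c.score,
                "n_targets_in_db": c.n_targets_in_db,
                "studies": c.n_animal_studies,
                "models": c.n_animal_models,
            }
            for c in candidates
        ],
        columns=["drug_name", "indications", "citations", "n_targets_in_db", "studies", "models"],
    )
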