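# seizekit

Toolkit for analyzing curated cross-species seizure/epilepsy gene evidence.
Epilepsy genetics spans rare monogenic syndromes, polygenic common
epilepsies studied by GWAS, and seizure phenotypes elicited in dogs,
rodents, zebrafish, flies, and worms. When all of that literature is
collated into one citation-level database — one row per publication or
database entry linking a gene to seizures in some species — the per-gene
citation counts become a usable measure of evidence strength. `seizekit`
implements the data model for such a database and the four analyses built
on it, for geneticists and pharmacologists prioritizing candidate genes and
candidate antiseizure drugs.

## What it computes

* **Evidence model** (`seizekit.evidence`) — per-citation records with a
  fixed species vocabulary (`human, dog, rodent, zebrafish, fly, worm,
  other`), optional deduplication on (gene, source type, source id),
  per-species citation summaries, and a filter/sort engine
  (`filter_genes`) over user-defined citation thresholds.
* **Polygenic candidates** (`seizekit.gwas`) — gene-based GWAS p-values are
  Benjamini–Hochberg adjusted across the tested universe; genes with
  FDR < .05 *and* ≥ 1 monogenic citation are candidate causal genes, and a
  novelty filter subtracts genes already reported by the source GWAS.
* **High-confidence genes** (`seizekit.confidence`) — a human monogenic
  gene is high-confidence iff it also has seizure evidence in another
  species; `compare_sets` gives Venn-style comparisons against alternative
  definitions.
* **Pathway enrichment** (`seizekit.enrichment`) — hypergeometric
  over-representation P(X ≥ k) for a query of n genes against each pathway
  of size K in a universe of N, BH-adjusted across the GMT collection, plus
  a random-gene permutation baseline for the count of enriched pathways
  with the add-one empirical p-value (1 + #{null ≥ observed}) / (B + 1).
* **Drug prioritization** (`seizekit.drugs`) — each drug scored by the
  total citations of its target genes; ranking validated by hypergeometric
  enrichment of approved antiseizure drugs in the top 20% (fold =
  (k/K)/(m/N)); repurposing triage keeps drugs used in humans for other
  indications, hitting ≥ 1 database gene, with animal-model antiseizure
  efficacy.
* **Synthetic bundles** (`seizekit.synthetic`) — seeded generators for
  complete input sets with planted ground truth (`strong`, `moderate`,
  `null` presets), used by the test suite for recovery and calibration.

## Worked example

The package ships a 16-gene reference table of generalized-epilepsy GWAS
candidates (gene, monogenic citation count, gene-based FDR):

```python
from seizekit.datasets import ge_reference_bundle, PREVIOUSLY_REPORTED_GE_GENES
from seizekit.gwas import candidate_polygenic_genes, novel_candidates

db, gwas = ge_reference_bundle()
found = candidate_polygenic_genes(db, gwas, fdr_threshold=0.05, min_citations=1)
print(len(found))                      # 16  — all pass FDR < .05 with >= 1 citation
novel = novel_candidates(found, set(PREVIOUSLY_REPORTED_GE_GENES))
print(sorted(c.gene_symbol for c in novel))
# ['AP3D1', 'CAMTA1', 'DOC2A', 'GRM4', 'MMP27', 'PHACTR1',
#  'RAPGEF2', 'RBFOX1', 'RIMS1', 'SETD1A', 'STX1B', 'UBTF']   — 12 novel genes
```

End-to-end on a synthetic bundle from the shell:

```
seizekit run-all --preset strong --seed 1 -B 999 --out out/
```

writes every artifact (summary, candidates, confidence calls, enrichment
table, permutation summary, drug ranking/enrichment, repurposing table) and
prints the machine-readable metrics, e.g.

```
"n_genes": 690,                      # genes with >= 1 citation (universe 2000)
"n_significant_pathways": 15,        # all 15 planted pathways at FDR < .05
"permutation_empirical_p": 0.001,    # 1/(B+1): no random gene set matches
"drug_enrichment_fold": 5.0,         # 15/15 antiseizure drugs in the top 20%
"drug_enrichment_p": 9.55e-13
```

A fold of 5.0 is the maximum attainable with a top-20% bin — it means 100%
of the labeled antiseizure drugs rank in the top fifth by citation score.

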