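# Methods

## Evidence model

The unit of evidence is a citation: one publication (`pmid`) or curated
database entry (`database`) linking one gene to a seizure/epilepsy phenotype
in one species. Species use a fixed seven-token vocabulary — `human, dog,
rodent, zebrafish, fly, worm, other` — in which `rodent` aggregates mouse
and rat; finer taxonomy must be pre-mapped upstream, as must nonhuman gene
symbols to their human orthologs. Symbol normalization is uppercase + trim
only; alias resolution would require an external nomenclature service and is
deliberately out of scope.

A primary study and a database entry derived from that same study can both
appear for one gene, inflating its citation count. Deduplication on
(gene, source_type, source_id) is therefore ON by default at load, and a
`keep_duplicates` flag preserves every row to mirror totals published from
raw compilations. Within-`source_type` collapse is the strongest
deduplication possible without cross-referencing databases back to their
primary studies, which the inputs do not support; cross-type duplication
(a pmid and a database entry citing it) is not detectable from the record
alone and survives both modes.

Gene-based GWAS evidence is *not* stored as citation records: degree of
polygenic association and monogenic citation counts are different kinds of
evidence and enter the analyses separately.

## Polygenic candidate genes

Gene-based GWAS p-values (computed upstream by a gene-based association
tool; consumed here as a TSV) are adjusted with the Benjamini–Hochberg
step-up procedure across the full tested table, via
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. BH is the
standard choice where only "FDR" is specified and matches the convention of
the common gene-based pipelines. The universe over which the FDR is taken
materially changes the result, so the whole tested table is a required
input — the package never silently restricts it.

Candidates are genes with FDR strictly < .05 *and* ≥ 1 monogenic citation
(default; both thresholds are parameters). Genes significant in the GWAS
but absent from the evidence database are reported separately and never
merged into the candidate list. The novelty filter is a set subtraction
against a user-supplied known-gene list.

## High-confidence genes

A gene with human monogenic evidence is called high-confidence iff it also
has ≥ 1 citation in another species. Functional corroboration in a second
species is used as the pathogenicity filter in place of computational
variant-effect scores. Both evidence classes (variant association and
direct manipulation) count; the catch-all `other` species token counts as
corroboration by default and can be excluded
(`include_other_species=False`) to restrict to the five named model
organisms. Genes pathogenic in humans only — or simply never studied in
animals — are necessarily missed by this definition; that is a property of
the definition, not of the implementation.

## Pathway over-representation

For a query of n genes (after intersection with the universe; genes outside
the universe are dropped and counted) and a pathway of size K in a universe
of N, the score is the one-sided upper tail P(X ≥ k) of the hypergeometric
distribution (`scipy.stats.hypergeom.sf(k-1, N, K, n)`), with k = 0 mapped
to exactly 1.0. BH adjustment runs across the whole collection; the
significant count uses strict FDR < .05. The default universe is the union
of all collection genes, overridable, and always recorded in the results
because it drives every p-value. No minimum set-size filter is applied by
default.

### Permutation baseline

To ask whether an observed count of enriched pathways could arise by
chance, B random queries of the same size are drawn uniformly without
replacement from the universe, each is scored identically, and the
empirical p-value is (1 + #{null count ≥ observed count}) / (B + 1) — add-one
so the floor is 1/(B+1) and the value is a valid p-value. Permutation b
uses a stream derived deterministically from (seed, b)
(`numpy.random.SeedSequence(entropy=seed, spawn_key=(b,))`), so results are
independent of evaluation order or parallelization. At B = 1000 the
smallest reportable value is ~10⁻³; published analyses of this design that
print "p < 1 × 10³" for the permutation result are read as a typesetting
error for 1 × 10⁻³.

The count statistic defaults to the headline quantity, pathways at
BH FDR < .05. For *calibration* checks a second statistic is exposed
(`threshold_on="p"`): the count of pathways at unadjusted p < .05. Under a
global null the FDR-count is zero in ≳95% of draws, so its empirical
p-value is degenerate at 1 and a uniformity test against it is
uninformative; the raw-p count is spread over many values and its empirical
p-value is approximately uniform under exchangeability. The choice of
calibration statistic and the null-preset sizes were fixed by a prospective
design simulation before the test suite was written.

A second calibration subtlety: the hypergeometric test is discrete, so
P(p < α) under the null is the largest attainable level *below* α, strictly
less than α. The calibration test for raw p-values therefore compares the
observed rejection fraction against that exact attainable level (computed
from the null pmf), not against α itself.

## Drug prioritization

Each drug's score is the sum of total citation counts of its target genes
present in the database (absent targets contribute 0; an optional
per-species weight vector defaults to 1 everywhere). Drugs with zero
database targets stay in the ranking with score 0 — removing them would
change N and hence the enrichment p-value — and ties are broken by drug
name so ranks are a deterministic permutation of 1..N.

Ranking validity is tested by the enrichment of labeled (approved
antiseizure) drugs in the top bin of m = ⌈top_fraction · N⌉ ranks:
fold = (k/K)/(m/N) and p = P(X ≥ k) hypergeometric. The ceiling guarantees
a non-empty bin at small N, and boundary ties were already resolved by the
name tie-break rather than by expanding the bin. When all K labeled drugs
land in a top-20% bin the fold is exactly (K/K)/(1/5) = 5.

Repurposing triage keeps drugs that are (1) used in humans but not approved
for epilepsy, (2) hit ≥ 1 database gene, and (3) have ≥ 1 animal study of
antiseizure efficacy; output is sorted by score with columns drug,
indications, citations, studies, models.

## Synthetic data generator

The generator emulates the statistical structure of a curated cross-species
evidence database; it makes no attempt to fit any real export.

* **Citations.** Counts are negative binomial, parameterized by (mean,
  dispersion r) with variance = mean + mean²/r — citation counts in real
  compilations are heavily overdispersed (observed ranges of 1 to several
  hundred within one gene list). True seizure genes draw from an inflated,
  zero-truncated NB (default mean 8, r 0.8 — median a handful of citations,
  tail into the tens), so every true gene is in the database; background
  genes draw untruncated NB (mean 0.5, r 0.3), entering the database only
  on a positive draw (~25% of them), which makes the database a minority
  subset of the 2000-gene universe, as a real database is of the genome.
* **Species allocation** is i.i.d. multinomial per citation (defaults:
  human .55, rodent .25, zebrafish .08, dog .04, fly .04, worm .02, other
  .02 — human and rodent literature dominate). 70% of true genes are
  flagged human-monogenic and have their first citation forced to human, so
  the high-confidence classifier has known truth.
* **GWAS** p-values are Beta(a, 1) for true genes (a ≤ 1; a = 0.15 in the
  strong preset) and Uniform(0,1) for nulls — the standard one-parameter
  alternative for p-value mixtures.
* **Pathways**: planted sets draw a fixed fraction (strong: 60%) of members
  from true genes, the rest from background; background sets are uniform
  draws. Sizes are uniform on 20–80, the mid-range of curated pathway
  collections.
* **Drugs**: antiseizure labels go to a random subset; their targets are
  drawn with probability `target_bias` (strong: 0.9) from the top decile of
  database genes by citation count, the rest uniformly. Non-antiseizure
  drugs draw targets uniformly, are used in humans with probability 0.8,
  and have Poisson(0.6) animal studies, so some qualify for repurposing.

One root seed drives per-component substreams (truth, citations, records,
GWAS, pathways, drugs) via `SeedSequence(seed, spawn_key=(component,))`, so
a bundle is byte-reproducible and partial regeneration is stable.

Presets: `strong` (all effects clearly separated — the recovery condition),
`moderate` (attenuated), `null` (no true genes, uniform p-values, no
planted pathways, unbiased drug targets, 300 pathways so calibration
statistics have spread). What passing recovery/calibration tests shows is
that the *procedures* detect planted structure and hold their nominal error
rates under this generative model; real evidence databases additionally
have correlated citation counts (hub genes, publication bandwagons),
overlapping pathways, non-multinomial species allocation, and curation
biases that no test here addresses.

## Numerical and design choices

* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, verified in the
  suite against exact integer-binomial enumeration for every universe
  N ≤ 30 at relative tolerance 1e-10.
* BH is verified against the explicit min-over-suffix formula on random
  vectors at 1e-12.
* All orderings are total and deterministic: genes by (−citations, symbol),
  candidates by (FDR, symbol), enrichment by (FDR, p, pathway), drugs by
  (−score, name). Reruns of the pipeline are byte-identical.
* Strict inequalities at every threshold (FDR < .05), matching the stated
  selection rules.
* Pipeline problem sizes used in the shipped tests and acceptance script —
  2000-gene universe, 150–300 pathways, 150 drugs, B = 99–999 permutations,
  100–200 seeds per property — were chosen as the smallest sizes at which
  the design simulations showed the planted effects and calibration
  properties are resolvable with comfortable margins.

## Known limitations

* No literature mining, ortholog mapping, or drug-target compilation: all
  inputs arrive pre-mapped in the documented TSV/GMT dialects.
* Citation counts measure research attention as much as effect size; the
  drug score inherits that bias (drugs targeting well-studied genes score
  high). The enrichment validation quantifies consistency with approved
  drugs, not causal promise.
* The published counts of a specific full-scale database (total genes,
  evidence records, high-confidence genes) are reproducible only from that
  database's export, which is not redistributable here; the package
  reproduces the published desk-scale tables and validates everything else
  by property.
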