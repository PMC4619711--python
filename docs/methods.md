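# Methods

## Annotation model

The unit of knowledge is one row linking a diploid genotype at a dbSNP site
to a qualitative drug-response statement: *(rsid, genotype, drug, aspect ∈
{efficacy, dosage, toxicity}, direction ∈ {increase, decrease}, evidence,
FDA flag)*. A SNP affecting several drugs or aspects occupies several rows,
which keeps the schema at the finest joinable granularity and makes every
downstream computation a plain relational operation.

Matching is **exact at the genotype level** after canonicalization
(uppercase, lexicographically sorted two-base strings). A row curated for
the heterozygote AG says nothing about GG; effects are genotype-specific,
so no dominance model or allele-level fallback is applied. Missing
genotypes never match. The join key is the rsID; a positional (chrom:pos)
fallback fires only for calls that carry no rsID and is logged, because
positional identity across genome builds is not checked.

Evidence levels adopt the PharmGKB six-tier scale (1A, 1B, 2A, 2B, 3, 4;
1A strongest). The optional `min_evidence` filter keeps rows at least as
strong as the threshold; the default is no filter, since the evidence tier
is reported per row and weak evidence is information, not noise.

### Assumptions

- Inputs are biallelic SNVs on autosomes or X/Y/MT; indels, multi-allelic
  records, and symbolic alleles are skipped (and counted).
- All genotypes are reported on the forward strand of the reference, the
  dbSNP convention. A/T and C/G strand-ambiguous genotypes cannot be
  verified from a single file; they are matched as-is and counted in the
  parse log.
- VCF records with a FILTER value other than `PASS` or `.` are treated as
  unreliable and dropped, on the premise that upstream callers emit
  meaningful filters.
- Coordinates are 1-based points throughout; `chr` prefixes are stripped
  and `M`/`MT` unified to `MT`.

## Input formats

The VCF v4.2 subset parser is bespoke and stream-based: it handles exactly
the record shape the annotation model consumes (biallelic SNV, GT field,
multi-sample), resolves `GT` indices through the REF+ALT pool, ignores
phase (`0|1` ≡ `1/0`), and duplicates haploid calls to homozygous diploid
form. The four array dialects share one normalized call model; header
column names of the CSV dialects (deCODEme, FTDNA) can be overridden per
vendor export version via `dialect_config`. No-call tokens (`--`, `00`,
`NN`, empty, indel codes) become the MISSING sentinel, which is retained
(for missingness accounting) but never matchable. Gzip inputs are detected
by magic bytes.

## Group statistics

- **Counting unit.** "Drug-related SNPs per individual" counts *distinct
  matched rsIDs*, not annotation rows: one rsID with three drug rows counts
  once toward the per-sample burden, while contributing one to each drug
  column of the sample×drug table. Row sums of the gene table therefore
  equal distinct (rsid, gene) pairs, and drug-table row sums can exceed the
  distinct-rsID count only through multi-drug SNPs.
- **Dispersion.** SDs use the n−1 sample estimator; a population with fewer
  than two samples reports NaN rather than a misleading zero.
- **Frequencies.** Genotype and allele frequencies are computed per (rsid,
  population) over observed genotypes only; missing calls are excluded from
  the denominator and reported as a separate missing fraction. No
  imputation is performed, and no significance test is attached to
  between-population differences — the output is descriptive.
- **One-vs-group divergence.** `compare_to_group` flags each matched locus
  of an index sample whose genotype has within-group frequency below a
  threshold (default 0.5, i.e. "not the group majority"). Frequencies are
  taken from the cohort's raw genotypes rather than from its match lists,
  because a group member whose genotype matches no knowledge-base row would
  otherwise vanish from the denominator and inflate the index genotype's
  apparent frequency. The index sample itself is excluded from the
  reference group. The majority criterion is one reasonable
  operationalization of "differs from the group"; the threshold is exposed
  as a parameter.

## Network

The gene–drug–category graph is directed: gene→drug edges are witnessed by
at least one annotation row linking the pair (deduplicated; the set of
effect directions rides along as an edge attribute), drug→category edges
come from the drug table's functional classifications. Isolated nodes are
omitted, so a drug's gene in-degree equals the number of distinct genes
with annotations for it. Node colors (gene green, drug blue, category
yellow) are attributes for downstream renderers; no drawing is done here.
GraphML is the round-trip format; JSON node-link and DOT are write-only
conveniences.

## Synthetic cohorts

`simulate_cohort` draws, for every sample, an independent genotype at each
knowledge-base locus from Hardy–Weinberg proportions: with q the planted
frequency of the alphabetically later allele, the count of that allele is
Binomial(2, q), giving p², 2pq, q² genotype probabilities. One seeded
NumPy generator drives the whole cohort, and the seed is recorded in the
output metadata. Sites whose KB rows show only one allele are paired with
the alphabetically first absent base so every locus is biallelic.

The generator emulates population-level allele-frequency structure and
per-genotype matching; it deliberately does **not** model linkage
disequilibrium, relatedness, demographic history, genotyping error, or
structured missingness. Tests passing on these cohorts therefore validate
the bookkeeping — parsing, joining, counting, frequency estimation — not
robustness to real-data artifacts.

Default study conditions used by the acceptance script: five populations
(AFR, AMR, SAS, EAS, EUR) of 500 samples each, planted allele frequencies
drawn uniformly from [0.05, 0.95] per locus (avoiding degenerate fixation
so every genotype class is exercised), annotated against the bundled
knowledge base; oracle-equivalence checks use 20 instances of 200-row
random knowledge bases × 100-sample cohorts. These sizes give 3-binomial-SE
frequency checks real power while keeping a full run in seconds on one
core.

## Bundled mini knowledge base

The built-in fixture covers the documented worked statements: cisplatin
toxicity rows for rs1042522 (CC decrease), rs316019 (CC increase), rs11615
(AG increase, GG decrease), rs3957357; warfarin dosing rows for VKORC1,
CYP2C9, CYP4F2 (FDA-flagged); a phenprocoumon row for CYP4F2; a warfarin
dosage-decrease row for rs2292566; and a clopidogrel efficacy row for
CYP2C19 (FDA-flagged). Three choices are fixture-only and marked as such in
the row descriptions: the placeholder gene symbols GENE_CIS1..4 for the
four cisplatin SNPs, the AA genotype assigned to rs2292566, and
rs2292566's placement under VKORC1 (which keeps warfarin's gene
neighborhood at exactly {VKORC1, CYP2C9, CYP4F2}). Heterozygote rows for
rs1042522 and rs316019 are omitted because no effect direction is curated
for them here.

## Numerical and formatting choices

- Deterministic ordering everywhere: matches sort by (drug, evidence rank,
  rsid, aspect); report sections alphabetically by drug, rows by evidence
  then rsid; count-table columns lexicographically. Reruns are
  byte-identical.
- Frequency normalization is checked to 1e-9; all-missing loci yield an
  empty observed distribution with missing fraction 1 rather than NaN
  frequencies spread across categories.
- Duplicate identical KB rows collapse on load; *conflicting* duplicates
  (same rsid/genotype/drug/aspect, opposite direction) and >2 alleles per
  rsID are surfaced by `validate_kb` as issues, never silently resolved.
- Reports render with plain string templates (HTML escaped); HTML and
  Markdown replace PDF output, keeping the index-link navigation while
  staying text-only and diffable. The default summary table uses compact
  (aspect, direction) columns; `--wide` reproduces the sparse
  efficacy/dosage/toxicity three-column layout.

## Known limitations

- No star-allele/diplotype calling, CNVs, or indels; single-SNP genotype
  rows only.
- No genome-build liftover: rsID matching hides build differences, but
  positional-fallback matching across builds would be wrong.
- Strand ambiguity at A/T and C/G SNPs is flagged, not resolved.
- The divergence rule in `compare_to_group` is a documented approximation;
  other operationalizations (allele-level comparison, exact tests) are out
  of scope.
- Descriptive statistics only; no inferential tests accompany the
  population comparisons.
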