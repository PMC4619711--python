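# pgxkit

An offline pharmacogenomics (PGx) annotation toolkit. Given an individual's
or a cohort's diploid genotypes — from a multi-sample VCF or from consumer
genotyping array exports (23andMe, Affymetrix, deCODEme, Family Tree DNA) —
`pgxkit` matches each observed genotype against a curated drug-response
knowledge base and reports, per drug, the expected qualitative effect on
**efficacy**, **dosage**, or **toxicity** (each labeled *increase* or
*decrease*), together with its PharmGKB-style evidence level (1A strongest …
4 weakest) and whether the drug carries FDA pharmacogenomic biomarker
labeling.

It is aimed at bioinformaticians and PGx researchers who want a scriptable,
server-free pipeline: the knowledge base is a versionable two-file TSV pair
(`kb_annotations.tsv` + `kb_drugs.tsv`), and all outputs are plain text
(TSV, HTML/Markdown reports, GraphML networks).

## The core operation

A knowledge-base row is a tuple *(rsID, genotype g, drug d, aspect a,
direction δ, evidence e)*. All genotypes are reduced to canonical form —
two uppercase bases, lexicographically sorted, so `G/A`, `0|1` and `AG`
compare equal — and a sample's call at rsID *r* with genotype *g* matches a
row exactly when the row has the same *r* and the same *g* (a row for AG
never matches GG; heterozygote and homozygote effects are curated
separately). From the matched rows the toolkit derives:

- **Individual report** — per-drug sections with an index, a flat summary
  table, and FDA-biomarker highlighting (HTML or Markdown).
- **Gene–drug–category network** — a tri-partite directed graph with
  gene→drug edges (a variant of the gene affects the drug's response) and
  drug→category edges; exported as GraphML/JSON/DOT.
- **Group analysis** — sample×gene and sample×drug count tables (distinct
  matched rsIDs), per-population genotype and allele frequency tables, and
  per-population burden summaries: mean ± SD (n−1) of matched-SNP counts per
  individual, overall and restricted to FDA-labeled rows.
- **Cohort simulation** — synthetic cohorts drawn per population under
  Hardy–Weinberg proportions (p², 2pq, q²) at the knowledge-base loci, with
  an exhaustively computed ground-truth match table for validation.

## Worked example

Annotate a sample carrying rs1042522 = CC, rs11615 = GG, and rs9923231 = AA
against the bundled mini knowledge base:

```python
from pgxkit import builtin_mini_kb, annotate_sample
from pgxkit.variant_io import GenotypeCall, SampleGenotypes

kb = builtin_mini_kb()
s = SampleGenotypes("patient1")
for rsid, geno in {"rs1042522": "CC", "rs11615": "GG", "rs9923231": "AA"}.items():
    ann = kb.index_by_rsid[rsid][0]
    s.add(GenotypeCall("patient1", rsid, ann.chrom, ann.position, geno, "23andme"))
for m in annotate_sample(s, kb):
    a = m.annotation
    print(f"{a.rsid}\t{a.gene_symbol}\t{m.observed_genotype}\t{a.drug_name}"
          f"\t{a.aspect}\t{a.direction}\t{a.evidence}\tFDA={a.fda_labeled}")
```

prints

```
rs1042522	GENE_CIS1	CC	cisplatin	toxicity	decrease	2A	FDA=False
rs11615	GENE_CIS3	GG	cisplatin	toxicity	decrease	2B	FDA=False
rs9923231	VKORC1	AA	warfarin	dosage	decrease	1A	FDA=True
```

Both cisplatin genotypes predict *decreased* cisplatin toxicity, and the
VKORC1 promoter homozygote calls for a *lower* warfarin dose with the
strongest evidence tier (1A) and an FDA biomarker flag.

The same flows are available from the shell:

```bash
pgxkit annotate --format 23andme -o matches.tsv genome.txt
pgxkit report  -o report.html matches.tsv
pgxkit network -o net.graphml
pgxkit group   --manifest manifest.tsv --format vcf -o out/ cohort.vcf
pgxkit simulate --spec populations.yaml --seed 42 -o cohort/
```

(`--kb <dir>` points any subcommand at a custom knowledge-base directory;
without it the bundled mini KB is used.)

## Layout

- `src/pgxkit/knowledgebase.py` — KB schema, TSV loader/writer, validation,
  indexing, bundled mini KB
- `src/pgxkit/variant_io.py` — canonical genotypes, VCF v4.2 subset parser,
  four array dialects, writers
- `src/pgxkit/annotation.py` — exact genotype matching, per-sample and
  cohort annotation
- `src/pgxkit/network.py` — tri-partite network build/export
- `src/pgxkit/group_analysis.py` — count tables, frequencies, summaries,
  one-vs-group divergence
- `src/pgxkit/reporting.py` — individual HTML/Markdown reports
- `src/pgxkit/simulate.py` — Hardy–Weinberg cohort and random-KB generators
- `src/pgxkit/cli.py` — the `pgxkit` command-line interface

See `docs/methods.md` for the model, assumptions, and design choices.
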