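"""Cohort-level statistics over matched annotations and raw genotypes.

Provides the batch-analysis outputs: sample × gene and sample × drug count
tables, per-population genotype and allele frequency distributions, per-
population burden summaries (mean and SD of matched-SNP counts, overall and
for the FDA-biomarker subset), and a one-versus-group divergence report.

Counting unit: *distinct matched rsIDs*.  One rsID annotated to three drugs
counts once toward a sample's SNP burden but contributes one to each of the
three drug columns.  Missing genotypes are excluded from frequency
denominators (the missing fraction is reported alongside), and the SD uses
the n−1 sample estimator; groups with fewer than two samples report NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import MatchedAnnotation
from .knowledgebase import KnowledgeBase
from .variant_io import MISSING, SampleGenotypes

__all__ = [
    "sample_gene_counts",
    "sample_drug_counts",
    "genotype_distribution",
    "allele_frequencies",
    "group_summary",
    "compare_to_group",
    "DivergenceReport",
]

MatchMap = dict[str, list[MatchedAnnotation]]


def _count_table(matches: MatchMap, col_of) -> pd.DataFrame:
    """Samples × columns table of distinct matched rsIDs per column."""
    rows = {}
    for sample_id, mlist in matches.items():
        counts: dict[str, set[str]] = {}
        for m in mlist:
            counts.setdefault(col_of(m.annotation), set()).add(m.annotation.rsid)
        rows[sample_id] = {col: len(rs) for col, rs in counts.items()}
    all_cols = sorted({c for r in rows.values() for c in r})
    table = pd.DataFrame(
        [[rows[s].get(c, 0) for c in all_cols] for s in matches],
        index=pd.Index(list(matches), name="sample"),
        columns=all_cols,
        dtype=int,
    )
    return table


def sample_gene_counts(matches: MatchMap) -> pd.DataFrame:
    """Sample × gene table; entry (s, g) counts distinct matched rsIDs of gene g.

    Row order follows cohort order; columns are lexicographic.  The row sum
    equals the number of distinct matched (rsid, gene) pairs of the sample.
    """
    return _count_table(matches, lambda a: a.gene_symbol)


def sample_drug_counts(matches: MatchMap) -> pd.DataFrame:
    """Sample × drug table; entry (s, d) counts distinct matched rsIDs for drug d."""
    return _count_table(matches, lambda a: a.drug_name)


def _check_assignment(samples: list[SampleGenotypes], groups: dict[str, str]) -> None:
    unassigned = [s.sample_id for s in samples if s.sample_id not in groups]
    if unassigned:
        raise ValueError(
            f"sample(s) without a population label: {', '.join(sorted(unassigned))}"
        )


def genotype_distribution(
    samples: list[SampleGenotypes],
    rsids: list[str],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per (rsid, population) genotype frequency table.

    Columns: rsid, population, genotype, count, frequency, missing_fraction.
    Frequencies are normalized over observed (non-missing) genotypes, so they
    sum to 1 per (rsid, population) whenever any genotype was observed; the
    missing fraction is reported in its own column against all group samples.
    """
    _check_assignment(samples, groups)
    records = []
    labels = sorted(set(groups[s.sample_id] for s in samples))
    for rsid in rsids:
        for label in labels:
            members = [s for s in samples if groups[s.sample_id] == label]
            genos = [s.genotype(rsid) for s in members]
            observed = [g for g in genos if g is not MISSING]
            n_missing = len(genos) - len(observed)
            miss_frac = n_missing / len(genos) if genos else 0.0
            counts: dict[str, int] = {}
            for g in observed:
                counts[g] = counts.get(g, 0) + 1
            for g in sorted(counts):
                records.append({
                    "rsid": rsid, "population": label, "genotype": g,
                    "count": counts[g],
                    "frequency": counts[g] / len(observed),
                    "missing_fraction": miss_frac,
                })
            if not counts:
                records.append({
                    "rsid": rsid, "population": label, "genotype": "MISSING",
                    "count": n_missing, "frequency": float("nan"),
                    "missing_fraction": miss_frac,
                })
    return pd.DataFrame.from_records(
        records,
        columns=["rsid", "population", "genotype", "count", "frequency",
                 "missing_fraction"],
    )


def allele_frequencies(
    samples: list[SampleGenotypes],
    rsids: list[str],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per (rsid, population) allele frequency table (columns: rsid,
    population, allele, count, frequency); alleles counted two per observed
    diploid genotype."""
    _check_assignment(samples, groups)
    records = []
    labels = sorted(set(groups[s.sample_id] for s in samples))
    for rsid in rsids:
        for label in labels:
            counts: dict[str, int] = {}
            for s in samples:
                if groups[s.sample_id] != label:
                    continue
                g = s.genotype(rsid)
                if g is MISSING:
                    continue
                for al in g:
                    counts[al] = counts.get(al, 0) + 1
            total = sum(counts.values())
            for al in sorted(counts):
                records.append({
                    "rsid": rsid, "population": label, "allele": al,
                    "count": counts[al], "frequency": counts[al] / total,
                })
    return pd.DataFrame.from_records(
        records, columns=["rsid", "population", "allele", "count", "frequency"]
    )


def _distinct_rsid_count(mlist: list[MatchedAnnotation], fda_only: bool) -> int:
    return len({
        m.annotation.rsid for m in mlist
        if not fda_only or m.annotation.fda_labeled
    })


def group_summary(
    matches: MatchMap,
    groups: dict[str, str],
    kb: KnowledgeBase | None = None,
) -> pd.DataFrame:
    """Per-population burden summary: n, mean and SD of matched-SNP counts.

    Computed twice — over all annotations and over the FDA-biomarker subset.
    Columns: population, n, mean_all, sd_all, mean_fda, sd_fda.  SD uses the
    n−1 estimator and is NaN for groups of fewer than two samples.
    """
    unassigned = sorted(set(matches) - set(groups))
    if unassigned:
        raise ValueError(
            f"sample(s) without a population label: {', '.join(unassigned)}"
        )
    per_label: dict[str, list[tuple[int, int]]] = {}
    for sample_id, mlist in matches.items():
        label = groups[sample_id]
        per_label.setdefault(label, []).append(
            (_distinct_rsid_count(mlist, False), _distinct_rsid_count(mlist, True))
        )
    records = []
    for label in sorted(per_label):
        all_counts = np.array([c for c, _ in per_label[label]], dtype=float)
        fda_counts = np.array([c for _, c in per_label[label]], dtype=float)
        n = len(all_counts)
        records.append({
            "population": label,
            "n": n,
            "mean_all": float(all_counts.mean()),
            "sd_all": float(all_counts.std(ddof=1)) if n > 1 else float("nan"),
            "mean_fda": float(fda_counts.mean()),
            "sd_fda": float(fda_counts.std(ddof=1)) if n > 1 else float("nan"),
        })
    return pd.DataFrame.from_records(
        records, columns=["population", "n", "mean_all", "sd_all", "mean_fda", "sd_fda"]
    )


@dataclass
class DivergenceReport:
    """How one sample's matched genotypes sit within a reference group."""

    sample_id: str
    label: str
    total_matched: int
    flagged: int
    loci: pd.DataFrame  # rsid, genotype, group_frequency, flagged


def compare_to_group(
    sample_matches: list[MatchedAnnotation],
    cohort: list[SampleGenotypes],
    groups: dict[str, str],
    label: str,
    threshold: float = 0.5,
) -> DivergenceReport:
    """Flag matched loci where the index genotype is not the group majority.

    For each distinct (rsid, genotype) among the index sample's matches, the
    within-group frequency of that genotype (over group members with an
    observed genotype at the rsID) is computed; loci with frequency below
    ``threshold`` are flagged as divergent from the group.  Group frequencies
    come from the cohort's raw genotypes, so group members whose genotype
    matches no knowledge-base row still count in the denominator.
    """
    if label not in set(groups.values()):
        raise ValueError(f"population label {label!r} absent from group assignment")
    members = [s for s in cohort if groups.get(s.sample_id) == label]

    index_loci = sorted({(m.annotation.rsid, m.observed_genotype) for m in sample_matches})
    sample_id = sample_matches[0].sample_id if sample_matches else ""
    records = []
    n_flagged = 0
    for rsid, genotype in index_loci:
        observed = [s.genotype(rsid) for s in members
                    if s.genotype(rsid) is not MISSING
                    and s.sample_id != sample_id]
        freq = observed.count(genotype) / len(observed) if observed else 0.0
        flagged = freq < threshold
        n_flagged += flagged
        records.append({
            "rsid": rsid, "genotype": genotype,
            "group_frequency": freq, "flagged": flagged,
        })
    loci = pd.DataFrame.from_records(
        records, columns=["rsid", "genotype", "group_frequency", "flagged"]
    )
    return DivergenceReport(
        sample_id=sample_id,
        label=label,
        total_matched=len(index_loci),
        flagged=int(n_flagged),
        loci=loci,
    )
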