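"""Synthetic cohorts and knowledge bases with known ground truth.

``simulate_cohort`` draws diploid genotypes per sample at every knowledge-
base locus under Hardy–Weinberg proportions (p², 2pq, q² for genotype
counts of the two site alleles), independently across loci and samples, per
population.  It returns the cohort together with a :class:`CohortTruth`
computed by an exhaustive genotype × annotation join — an oracle that every
downstream module can be checked against exactly.  Real-data features such
as linkage disequilibrium, relatedness, genotyping error, and missingness
patterns are deliberately not modeled.

``random_kb`` builds schema-valid random knowledge bases (biallelic sites,
consistent alleles per rsID, no contradictory directions) for fuzzing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .knowledgebase import (
    ASPECTS,
    DIRECTIONS,
    DrugRecord,
    EvidenceLevel,
    KnowledgeBase,
    VariantAnnotation,
)
from .variant_io import GenotypeCall, SampleGenotypes, write_array, write_vcf

__all__ = ["PopulationSpec", "CohortTruth", "simulate_cohort", "random_kb",
           "site_alleles", "hardy_weinberg_expectation"]


@dataclass(frozen=True)
class PopulationSpec:
    """One population to simulate: label, size, and per-rsID allele frequency.

    ``allele_freqs`` maps rsid → frequency of the *alphabetically later* of
    the site's two alleles; loci absent from the map default to 0.5.
    """

    label: str
    n_samples: int
    allele_freqs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        for rsid, f in self.allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency for {rsid} outside [0,1]: {f}")


@dataclass
class CohortTruth:
    """Ground truth planted by the simulator.

    ``genotypes``: sample_id → rsid → canonical genotype.
    ``expected_matches``: sample_id → matched (rsid, genotype, drug, aspect,
    direction) tuples derived by exhaustively joining planted genotypes with
    the generating knowledge base.
    ``expected_genotype_freqs``: (rsid, label) → genotype → Hardy–Weinberg
    expected frequency.
    """

    genotypes: dict[str, dict[str, str]]
    expected_matches: dict[str, list[tuple[str, str, str, str, str]]]
    expected_genotype_freqs: dict[tuple[str, str], dict[str, float]]
    seed: int = 0


def site_alleles(kb: KnowledgeBase, rsid: str) -> tuple[str, str]:
    """The site's (earlier, later) allele pair, read off the KB's genotypes.

    A site whose rows show only one allele is paired with the alphabetically
    first base not present, so homozygous-only KB rows still define a
    biallelic site.
    """
    alleles = sorted(kb.alleles_at(rsid))
    if len(alleles) >= 2:
        return alleles[0], alleles[1]
    if len(alleles) == 1:
        other = next(b for b in "ACGT" if b != alleles[0])
        return tuple(sorted((alleles[0], other)))  # type: ignore[return-value]
    raise ValueError(f"rsid {rsid} absent from knowledge base")


def hardy_weinberg_expectation(a_early: str, a_late: str, q_late: float) -> dict[str, float]:
    """Expected genotype frequencies {early-hom: p², het: 2pq, late-hom: q²}."""
    p = 1.0 - q_late
    het = "".join(sorted(a_early + a_late))
    return {a_early * 2: p * p, het: 2 * p * q_late, a_late * 2: q_late * q_late}


def simulate_cohort(
    kb: KnowledgeBase,
    specs: list[PopulationSpec],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SampleGenotypes], dict[str, str], CohortTruth]:
    """Simulate a multi-population cohort genotyped at every KB locus.

    Returns ``(samples, group_assignment, truth)``.  With ``out_dir`` given,
    also writes a multi-sample VCF (``cohort.vcf``), one 23andMe-dialect
    file per sample, a population manifest, and truth TSVs.  A single seeded
    pseudo-random stream drives the whole cohort, so results are exactly
    reproducible for a given seed.
    """
    if not specs:
        raise ValueError("at least one population spec is required")
    rng = np.random.default_rng(seed)
    rsids = sorted(kb.index_by_rsid)
    sites = {r: site_alleles(kb, r) for r in rsids}
    locus_pos = {r: (kb.index_by_rsid[r][0].chrom, kb.index_by_rsid[r][0].position)
                 for r in rsids}

    samples: list[SampleGenotypes] = []
    groups: dict[str, str] = {}
    genotypes: dict[str, dict[str, str]] = {}
    expected_freqs: dict[tuple[str, str], dict[str, float]] = {}

    for spec in specs:
        for rsid in rsids:
            q = spec.allele_freqs.get(rsid, 0.5)
            a_early, a_late = sites[rsid]
            expected_freqs[(rsid, spec.label)] = hardy_weinberg_expectation(
                a_early, a_late, q)
        for i in range(spec.n_samples):
            sample_id = f"{spec.label}_{i:04d}"
            s = SampleGenotypes(sample_id=sample_id)
            gmap: dict[str, str] = {}
            for rsid in rsids:
                a_early, a_late = sites[rsid]
                q = spec.allele_freqs.get(rsid, 0.5)
                n_late = rng.binomial(2, q)
                geno = "".join(sorted(a_late * n_late + a_early * (2 - n_late)))
                chrom, pos = locus_pos[rsid]
                s.add(GenotypeCall(sample_id=sample_id, rsid=rsid, chrom=chrom,
                                   position=pos, alleles=geno, source_format="vcf"))
                gmap[rsid] = geno
            samples.append(s)
            groups[sample_id] = spec.label
            genotypes[sample_id] = gmap

    # exhaustive join: the truth table every matcher must reproduce
    expected_matches: dict[str, list[tuple[str, str, str, str, str]]] = {}
    for s in samples:
        hits = []
        for rsid, geno in genotypes[s.sample_id].items():
            for ann in kb.annotations:
                if ann.rsid == rsid and ann.genotype == geno:
                    hits.append((rsid, geno, ann.drug_name, ann.aspect, ann.direction))
        hits.sort(key=lambda t: (t[2], t[0], t[3]))
        expected_matches[s.sample_id] = hits

    truth = CohortTruth(
        genotypes=genotypes,
        expected_matches=expected_matches,
        expected_genotype_freqs=expected_freqs,
        seed=seed,
    )

    if out_dir is not None:
        _write_cohort(Path(out_dir), samples, groups, truth)
    return samples, groups, truth


def _write_cohort(out_dir: Path, samples, groups, truth) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "cohort.vcf", "w", encoding="utf-8") as fh:
        write_vcf(samples, fh)
    array_dir = out_dir / "arrays"
    array_dir.mkdir(exist_ok=True)
    for s in samples:
        with open(array_dir / f"{s.sample_id}.23andme.txt", "w", encoding="utf-8") as fh:
            write_array(s, "23andme", fh)
    with open(out_dir / "manifest.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{groups[s.sample_id]}\n")
    with open(out_dir / "truth_matches.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\trsid\tgenotype\tdrug\taspect\tdirection\n")
        for sample_id, hits in truth.expected_matches.items():
            for rsid, geno, drug, aspect, direction in hits:
                fh.write(f"{sample_id}\t{rsid}\t{geno}\t{drug}\t{aspect}\t{direction}\n")
    with open(out_dir / "metadata.txt", "w", encoding="utf-8") as fh:
        fh.write(f"seed={truth.seed}\n")


_GENES = [f"GENE{i:03d}" for i in range(40)]


def random_kb(n_rows: int, n_drugs: int, seed: int) -> KnowledgeBase:
    """Random schema-valid knowledge base for fuzz tests.

    Exactly ``n_rows`` annotation rows and ``n_drugs`` drug records; each
    rsID keeps one fixed biallelic allele pair across its rows and no
    (rsid, genotype, drug, aspect) tuple is duplicated, so the result passes
    validation with zero issues.  Deterministic for a given seed.
    """
    if n_rows < 1 or n_drugs < 1:
        raise ValueError("n_rows and n_drugs must be >= 1")
    rng = np.random.default_rng(seed)
    drug_names = [f"drug{i:03d}" for i in range(n_drugs)]
    categories = ["Anticoagulants", "Antineoplastic Agents", "Analgesics",
                  "Antidepressants", "Beta Blockers"]
    drugs = {
        name: DrugRecord(
            drug_name=name,
            external_id=f"DB{rng.integers(10000, 99999)}",
            categories=tuple(rng.choice(categories,
                                        size=rng.integers(0, 3), replace=False)),
            description=f"synthetic drug record {name}",
        )
        for name in drug_names
    }

    bases = "ACGT"
    # per-rsid fixed site: allele pair, chrom, pos, gene (keeps rows consistent)
    site_pool: dict[str, tuple[str, str, str, int, str]] = {}
    rows: list[VariantAnnotation] = []
    used: set[tuple[str, str, str, str]] = set()
    evidence_codes = EvidenceLevel._CODES
    while len(rows) < n_rows:
        rsid = f"rs{rng.integers(1000, 1000 + max(n_rows, 50))}"
        if rsid not in site_pool:
            pair = rng.choice(4, size=2, replace=False)
            a, b = sorted(bases[i] for i in pair)
            site_pool[rsid] = (a, b, str(int(rng.integers(1, 23))),
                               int(rng.integers(1, 10_000_000)),
                               _GENES[int(rng.integers(len(_GENES)))])
        a1, a2, chrom, pos, gene = site_pool[rsid]
        geno = "".join(sorted(rng.choice([a1, a2], size=2)))
        drug = drug_names[int(rng.integers(n_drugs))]
        aspect = ASPECTS[int(rng.integers(len(ASPECTS)))]
        key = (rsid, geno, drug, aspect)
        if key in used:
            continue  # retry: keep (rsid, genotype, drug, aspect) unique
        used.add(key)
        rows.append(VariantAnnotation(
            rsid=rsid,
            gene_symbol=gene,
            chrom=chrom,
            position=pos,
            genotype=geno,
            drug_name=drug,
            aspect=aspect,
            direction=DIRECTIONS[int(rng.integers(2))],
            evidence=EvidenceLevel(evidence_codes[int(rng.integers(6))]),
            description="synthetic annotation",
            fda_labeled=bool(rng.integers(2)),
        ))
    return KnowledgeBase(annotations=rows, drugs=drugs)
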