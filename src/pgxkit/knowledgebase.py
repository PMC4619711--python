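"""Drug-response knowledge base: schema, loading, validation, indexing.

The knowledge base links an observed diploid genotype at a dbSNP site to a
qualitative drug-response statement: which drug is affected, which aspect of
the response (efficacy, dosage, toxicity), in which direction (increase or
decrease), and with what PharmGKB-style evidence level.  It is stored as a
pair of tab-separated files — an annotations table and a drugs table — so a
curated export can be versioned and diffed like source code.

One annotation row is one ``(rsid, genotype, drug, aspect, direction)``
tuple; a SNP that affects several drugs or aspects occupies several rows.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from functools import total_ordering
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ASPECTS",
    "DIRECTIONS",
    "EvidenceLevel",
    "VariantAnnotation",
    "DrugRecord",
    "KnowledgeBase",
    "KBSchemaError",
    "KBRowError",
    "KBReferentialError",
    "ValidationIssue",
    "load_knowledge_base",
    "write_kb",
    "validate_kb",
    "builtin_mini_kb",
]

ASPECTS = ("efficacy", "dosage", "toxicity")
DIRECTIONS = ("increase", "decrease")

_RSID_RE = re.compile(r"^rs[0-9]+$")
_GENOTYPE_RE = re.compile(r"^[ACGT]{2}$")

ANNOTATION_COLUMNS = (
    "rsid", "gene", "chrom", "pos", "genotype", "drug",
    "aspect", "direction", "evidence", "fda_labeled", "description",
)
DRUG_COLUMNS = ("drug", "external_id", "categories", "description")


class KBSchemaError(ValueError):
    """A required column is missing or a table header is malformed."""


class KBRowError(ValueError):
    """A row carries an unparseable or out-of-vocabulary value."""


class KBReferentialError(ValueError):
    """An annotation references a drug absent from the drugs table."""


@total_ordering
class EvidenceLevel:
    """PharmGKB-style curation tier, 1A (strongest) through 4 (weakest).

    Ordering compares strength: ``EvidenceLevel("1A") > EvidenceLevel("3")``.
    ``rank`` runs 1..6 with 1 strongest, so *stronger* means *smaller rank*.
    """

    _CODES = ("1A", "1B", "2A", "2B", "3", "4")
    _RANK = {c: i + 1 for i, c in enumerate(_CODES)}

    __slots__ = ("code",)

    def __init__(self, code: str):
        code = str(code).strip().upper()
        if code not in self._RANK:
            raise KBRowError(
                f"unknown evidence level {code!r}; expected one of {', '.join(self._CODES)}"
            )
        self.code = code

    @property
    def rank(self) -> int:
        return self._RANK[self.code]

    def __eq__(self, other) -> bool:
        return isinstance(other, EvidenceLevel) and self.code == other.code

    def __lt__(self, other) -> bool:
        # "less" = weaker evidence = larger rank
        if not isinstance(other, EvidenceLevel):
            return NotImplemented
        return self.rank > other.rank

    def __hash__(self) -> int:
        return hash(self.code)

    def __repr__(self) -> str:
        return f"EvidenceLevel({self.code!r})"

    def __str__(self) -> str:
        return self.code


def canonicalize_genotype_string(genotype: str) -> str:
    """Uppercase and sort a two-character diploid genotype string."""
    g = str(genotype).strip().upper()
    g = "".join(sorted(g))
    if not _GENOTYPE_RE.match(g):
        raise KBRowError(f"invalid genotype {genotype!r}: need two bases from A/C/G/T")
    return g


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and unify mitochondrial names to ``MT``."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        return "MT"
    return c.upper() if c.upper() in ("X", "Y") else c


@dataclass(frozen=True)
class VariantAnnotation:
    """One knowledge-base row: a genotype at an rsID tied to a drug response."""

    rsid: str
    gene_symbol: str
    chrom: str
    position: int
    genotype: str          # canonical: two uppercase bases, sorted
    drug_name: str
    aspect: str            # efficacy | dosage | toxicity
    direction: str         # increase | decrease
    evidence: EvidenceLevel
    description: str = ""
    fda_labeled: bool = False

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise KBRowError(f"invalid rsid {self.rsid!r}")
        if self.aspect not in ASPECTS:
            raise KBRowError(f"unknown aspect {self.aspect!r}")
        if self.direction not in DIRECTIONS:
            raise KBRowError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "genotype", canonicalize_genotype_string(self.genotype))
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.position < 1:
            raise KBRowError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class DrugRecord:
    """Descriptive record for one drug, including its functional categories."""

    drug_name: str
    external_id: str = ""
    categories: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self):
        if not self.drug_name:
            raise KBRowError("drug_name must be non-empty")


@dataclass
class KnowledgeBase:
    """Fully indexed collection of annotations plus the drug table."""

    annotations: list[VariantAnnotation]
    drugs: dict[str, DrugRecord]
    index_by_rsid: dict[str, list[VariantAnnotation]] = field(default_factory=dict)
    index_by_gene: dict[str, list[VariantAnnotation]] = field(default_factory=dict)
    index_by_drug: dict[str, list[VariantAnnotation]] = field(default_factory=dict)
    index_by_position: dict[tuple[str, int], list[VariantAnnotation]] = field(default_factory=dict)

    def __post_init__(self):
        for a in self.annotations:
            if a.drug_name not in self.drugs:
                raise KBReferentialError(
                    f"annotation for {a.rsid} references unknown drug {a.drug_name!r}"
                )
        self._reindex()

    def _reindex(self) -> None:
        self.index_by_rsid = {}
        self.index_by_gene = {}
        self.index_by_drug = {}
        self.index_by_position = {}
        for a in self.annotations:
            self.index_by_rsid.setdefault(a.rsid, []).append(a)
            self.index_by_gene.setdefault(a.gene_symbol, []).append(a)
            self.index_by_drug.setdefault(a.drug_name, []).append(a)
            self.index_by_position.setdefault((a.chrom, a.position), []).append(a)

    def query(self, rsid: str, genotype: str | None = None) -> list[VariantAnnotation]:
        """Annotations at ``rsid``, optionally restricted to one genotype."""
        rows = self.index_by_rsid.get(rsid, [])
        if genotype is None:
            return list(rows)
        g = canonicalize_genotype_string(genotype)
        return [a for a in rows if a.genotype == g]

    def genes_for_drug(self, drug_name: str) -> set[str]:
        return {a.gene_symbol for a in self.index_by_drug.get(drug_name, [])}

    def alleles_at(self, rsid: str) -> set[str]:
        """Distinct alleles appearing in any genotype row of ``rsid``."""
        return {al for a in self.index_by_rsid.get(rsid, []) for al in a.genotype}

    def __len__(self) -> int:
        return len(self.annotations)


def _parse_bool(token: str, line_no: int) -> bool:
    t = token.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise KBRowError(f"line {line_no}: cannot parse boolean {token!r}")


def _read_tsv(path: Path, required: Iterable[str]) -> list[tuple[int, dict[str, str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise KBSchemaError(f"{path.name}: missing required column {col!r}")
        return [(i, row) for i, row in enumerate(reader, start=2)]


def load_knowledge_base(kb_path: str | Path) -> KnowledgeBase:
    """Load a knowledge base from a directory holding the two-table TSV pair.

    ``kb_path`` is a directory containing ``kb_annotations.tsv`` and
    ``kb_drugs.tsv``.  Genotypes are canonicalized (uppercased, sorted) on
    load and byte-identical duplicate rows are collapsed to one.

    Raises
    ------
    KBSchemaError
        A required column is missing from either table.
    KBRowError
        An aspect/direction/evidence token is out of vocabulary (the message
        carries the line number).
    KBReferentialError
        An annotation names a drug absent from the drugs table.
    """
    kb_path = Path(kb_path)
    ann_path = kb_path / "kb_annotations.tsv"
    drug_path = kb_path / "kb_drugs.tsv"

    drugs: dict[str, DrugRecord] = {}
    for line_no, row in _read_tsv(drug_path, DRUG_COLUMNS):
        name = row["drug"].strip()
        if not name:
            raise KBRowError(f"{drug_path.name} line {line_no}: empty drug name")
        cats = tuple(c.strip() for c in row["categories"].split(";") if c.strip())
        drugs[name] = DrugRecord(
            drug_name=name,
            external_id=row["external_id"].strip(),
            categories=cats,
            description=row["description"].strip(),
        )

    annotations: list[VariantAnnotation] = []
    seen: set[VariantAnnotation] = set()
    for line_no, row in _read_tsv(ann_path, ANNOTATION_COLUMNS):
        try:
            ann = VariantAnnotation(
                rsid=row["rsid"].strip(),
                gene_symbol=row["gene"].strip(),
                chrom=row["chrom"].strip(),
                position=int(row["pos"]),
                genotype=row["genotype"],
                drug_name=row["drug"].strip(),
                aspect=row["aspect"].strip().lower(),
                direction=row["direction"].strip().lower(),
                evidence=EvidenceLevel(row["evidence"]),
                description=row["description"].strip(),
                fda_labeled=_parse_bool(row["fda_labeled"], line_no),
            )
        except (KBRowError, ValueError) as exc:
            raise KBRowError(f"{ann_path.name} line {line_no}: {exc}") from exc
        if ann.drug_name not in drugs:
            raise KBReferentialError(
                f"{ann_path.name} line {line_no}: annotation references unknown drug "
                f"{ann.drug_name!r}"
            )
        if ann not in seen:
            seen.add(ann)
            annotations.append(ann)

    return KnowledgeBase(annotations=annotations, drugs=drugs)


def write_kb(kb: KnowledgeBase, out_dir: str | Path) -> None:
    """Serialize a knowledge base back to the two-table TSV pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "kb_annotations.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in kb.annotations:
            w.writerow([
                a.rsid, a.gene_symbol, a.chrom, a.position, a.genotype, a.drug_name,
                a.aspect, a.direction, a.evidence.code,
                "true" if a.fda_labeled else "false", a.description,
            ])
    with open(out_dir / "kb_drugs.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DRUG_COLUMNS)
        for d in kb.drugs.values():
            w.writerow([d.drug_name, d.external_id, ";".join(d.categories), d.description])


@dataclass(frozen=True)
class ValidationIssue:
    """One consistency problem found by :func:`validate_kb`."""

    kind: str      # "conflicting_direction" | "multi_allelic_rsid"
    rsid: str
    detail: str


def validate_kb(kb: KnowledgeBase) -> list[ValidationIssue]:
    """Report internal inconsistencies; an empty list means clean.

    Two checks: rows sharing (rsid, genotype, drug, aspect) but disagreeing
    on direction, and rsIDs whose rows use more than two distinct alleles.
    Validation reports, it never raises.
    """
    issues: list[ValidationIssue] = []

    by_key: dict[tuple[str, str, str, str], set[str]] = {}
    for a in kb.annotations:
        by_key.setdefault((a.rsid, a.genotype, a.drug_name, a.aspect), set()).add(a.direction)
    for (rsid, genotype, drug, aspect), dirs in sorted(by_key.items()):
        if len(dirs) > 1:
            issues.append(ValidationIssue(
                kind="conflicting_direction",
                rsid=rsid,
                detail=(f"genotype {genotype}, drug {drug}, aspect {aspect}: "
                        f"directions {sorted(dirs)}"),
            ))

    for rsid in sorted(kb.index_by_rsid):
        alleles = kb.alleles_at(rsid)
        if len(alleles) > 2:
            issues.append(ValidationIssue(
                kind="multi_allelic_rsid",
                rsid=rsid,
                detail=f"alleles {sorted(alleles)} exceed a biallelic site",
            ))

    return issues


def builtin_mini_kb() -> KnowledgeBase:
    """The bundled miniature knowledge base used in examples and tests.

    Covers cisplatin toxicity SNPs (rs1042522, rs316019, rs11615, rs3957357),
    the warfarin dosing genes VKORC1/CYP2C9/CYP4F2, phenprocoumon via CYP4F2,
    a warfarin dosage-decrease row for rs2292566, and a clopidogrel efficacy
    row; FDA biomarker flags are set on the warfarin and clopidogrel entries.
    Genes for the cisplatin SNPs use placeholder symbols GENE_CIS1..4.
    """
    with resources.as_file(resources.files("pgxkit").joinpath("data/mini_kb")) as p:
        return load_knowledge_base(p)


def copy_with(ann: VariantAnnotation, **changes) -> VariantAnnotation:
    """Field-replaced copy of an annotation (convenience for fixtures)."""
    return replace(ann, **changes)
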