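"""Genotype input parsing: VCF v4.2 subset and four consumer-array dialects.

Every input route normalizes to the same per-sample model: a
:class:`GenotypeCall` holds one canonical diploid genotype (two uppercase
bases, lexicographically sorted) or the missing sentinel, keyed by rsID.
Canonical form makes genotypes from unordered VCF ``GT`` fields and vendor
allele strings directly comparable, and makes matching phase-blind by
construction.

Only biallelic SNVs are handled: records with indels, symbolic alleles, or
more than one ALT are skipped and counted.  VCF records whose FILTER column
is neither ``PASS`` nor ``.`` are treated as unreliable and skipped too.
All genotypes are assumed reported on the forward strand of the reference
(the dbSNP convention); A/T and C/G strand-ambiguous sites are matched as-is
but counted in the parse log.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from .knowledgebase import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "DIALECTS",
    "GenotypeCall",
    "SampleGenotypes",
    "AlleleError",
    "VcfFormatError",
    "ArrayFormatError",
    "canonical_genotype",
    "resolve_vcf_genotype",
    "parse_vcf",
    "parse_array",
    "write_vcf",
    "write_array",
    "open_genotype_file",
]

#: Sentinel for a no-call genotype.  Distinct from any canonical string.
MISSING = None

DIALECTS = ("23andme", "affymetrix", "decodeme", "ftdna")

_BASES = frozenset("ACGT")
_NOCALL_TOKENS = frozenset({"--", "00", "NN", "", "II", "DD", "DI", "ID"})
_AMBIGUOUS = frozenset({"AT", "CG"})  # same genotype on both strands
_HAPLOID_CHROMS = frozenset({"X", "Y", "MT"})


class AlleleError(ValueError):
    """An allele character outside A/C/G/T."""


class VcfFormatError(ValueError):
    """Structural problem in a VCF stream (header or record level)."""


class ArrayFormatError(ValueError):
    """Structural problem in a consumer-array genotype file."""


def canonical_genotype(a1: str, a2: str) -> str:
    """Canonical diploid genotype: uppercase, lexicographically sorted.

    Commutative: ``canonical_genotype("G", "A") == canonical_genotype("A", "G")
    == "AG"``.
    """
    a1, a2 = str(a1).upper(), str(a2).upper()
    for a in (a1, a2):
        if len(a) != 1 or a not in _BASES:
            raise AlleleError(f"invalid allele {a!r}: expected one of A, C, G, T")
    return a1 + a2 if a1 <= a2 else a2 + a1


@dataclass(frozen=True)
class GenotypeCall:
    """One observed diploid genotype for one sample at one site."""

    sample_id: str
    rsid: str                      # dbSNP id, or "" when unknown
    chrom: str
    position: int
    alleles: str | None            # canonical 2-char string, or MISSING
    source_format: str = "vcf"

    def __post_init__(self):
        if self.alleles is not MISSING:
            if len(self.alleles) != 2 or set(self.alleles) - _BASES:
                raise AlleleError(f"non-canonical alleles {self.alleles!r}")
            if "".join(sorted(self.alleles)) != self.alleles:
                raise AlleleError(f"unsorted alleles {self.alleles!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> str:
        """rsID when present, else ``chrom:pos``."""
        return self.rsid if self.rsid else f"{self.chrom}:{self.position}"


@dataclass
class SampleGenotypes:
    """All calls for one sample, keyed by rsID (or chrom:pos)."""

    sample_id: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def add(self, call: GenotypeCall) -> None:
        if call.sample_id != self.sample_id:
            raise ValueError(
                f"call for sample {call.sample_id!r} added to {self.sample_id!r}"
            )
        self.calls[call.key] = call

    def genotype(self, rsid: str) -> str | None:
        call = self.calls.get(rsid)
        return call.alleles if call else MISSING

    def __len__(self) -> int:
        return len(self.calls)


def resolve_vcf_genotype(ref: str, alts: list[str], gt_field: str) -> str | None:
    """Map a VCF ``GT`` value onto REF/ALT alleles; phase separators ignored.

    ``./.``, ``.`` (and half-calls like ``./1``) give :data:`MISSING`; a
    haploid GT is duplicated to a homozygous diploid genotype.
    """
    gt = gt_field.strip().replace("|", "/")
    parts = gt.split("/")
    if any(p in ("", ".") for p in parts) or not parts:
        return MISSING
    if len(parts) == 1:
        parts = parts * 2
    if len(parts) != 2:
        raise VcfFormatError(f"GT field {gt_field!r} is not haploid or diploid")
    pool = [ref] + list(alts)
    try:
        indices = [int(p) for p in parts]
    except ValueError as exc:
        raise VcfFormatError(f"unparseable GT field {gt_field!r}") from exc
    for i in indices:
        if not 0 <= i < len(pool):
            raise VcfFormatError(
                f"GT index {i} out of range for {len(pool)} alleles in {gt_field!r}"
            )
    return canonical_genotype(pool[indices[0]], pool[indices[1]])


def _is_snv(ref: str, alts: list[str]) -> bool:
    return (
        len(ref) == 1 and ref.upper() in _BASES
        and all(len(a) == 1 and a.upper() in _BASES for a in alts)
    )


def parse_vcf(stream: IO[str]) -> list[SampleGenotypes]:
    """Parse a multi-sample VCF v4.2 stream into per-sample genotype sets.

    One :class:`SampleGenotypes` per sample column, in header order.
    Biallelic SNV records with FILTER ``PASS`` or ``.`` are kept; multi-allelic,
    non-SNV, and filtered records are skipped with counts reported at DEBUG
    level.  Raises :class:`VcfFormatError` when the ``#CHROM`` header line is
    absent or a GT index exceeds the record's allele count.
    """
    samples: list[SampleGenotypes] = []
    sample_names: list[str] = []
    n_skipped_filter = n_skipped_nonsnv = n_skipped_multi = n_ambiguous = 0
    saw_header = False

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) < 10:
                raise VcfFormatError("#CHROM header lists no sample columns")
            sample_names = cols[9:]
            samples = [SampleGenotypes(sample_id=s) for s in sample_names]
            saw_header = True
            continue
        if not saw_header:
            raise VcfFormatError("missing #CHROM header line before records")

        cols = line.split("\t")
        if len(cols) < 9 + len(sample_names):
            raise VcfFormatError(f"line {line_no}: too few columns")
        chrom, pos, vid, ref, alt, _qual, filt = cols[:7]
        fmt = cols[8]
        if filt not in ("PASS", "."):
            n_skipped_filter += 1
            continue
        alts = alt.split(",")
        if len(alts) > 1:
            n_skipped_multi += 1
            continue
        if alt == "." or not _is_snv(ref, alts):
            n_skipped_nonsnv += 1
            continue

        fmt_keys = fmt.split(":")
        try:
            gt_idx = fmt_keys.index("GT")
        except ValueError:
            raise VcfFormatError(f"line {line_no}: FORMAT lacks GT") from None

        rsid = vid if vid.startswith("rs") else ""
        chrom_n = normalize_chrom(chrom)
        position = int(pos)
        for sample, cell in zip(samples, cols[9:]):
            gt_field = cell.split(":")[gt_idx] if cell != "." else "."
            try:
                alleles = resolve_vcf_genotype(ref.upper(), [a.upper() for a in alts], gt_field)
            except VcfFormatError as exc:
                raise VcfFormatError(f"line {line_no}: {exc}") from exc
            if alleles is not MISSING and alleles in _AMBIGUOUS:
                n_ambiguous += 1
            sample.add(GenotypeCall(
                sample_id=sample.sample_id,
                rsid=rsid,
                chrom=chrom_n,
                position=position,
                alleles=alleles,
                source_format="vcf",
            ))

    if not saw_header:
        raise VcfFormatError("missing #CHROM header line")
    logger.debug(
        "parse_vcf: skipped %d filtered, %d non-SNV, %d multi-allelic records; "
        "%d strand-ambiguous genotypes",
        n_skipped_filter, n_skipped_nonsnv, n_skipped_multi, n_ambiguous,
    )
    return samples


def _array_genotype(token: str, chrom: str) -> str | None:
    token = token.strip().upper()
    if token in _NOCALL_TOKENS or set(token) - _BASES:
        return MISSING
    if len(token) == 1:
        # hemizygous call on X/Y/MT reported as a single base
        if normalize_chrom(chrom) in _HAPLOID_CHROMS:
            return canonical_genotype(token, token)
        return canonical_genotype(token, token)
    if len(token) == 2:
        return canonical_genotype(token[0], token[1])
    return MISSING


# Dialect layouts: (delimiter, has_header, field order).  Header strings can
# be overridden through ``dialect_config`` in :func:`parse_array` for vendor
# export versions with different column names.
_DIALECT_LAYOUT = {
    "23andme": {"delim": "\t", "header": False,
                "fields": ("rsid", "chrom", "pos", "genotype")},
    "affymetrix": {"delim": "\t", "header": False,
                   "fields": ("rsid", "chrom", "pos", "genotype")},
    "decodeme": {"delim": ",", "header": True,
                 "columns": {"rsid": "Name", "chrom": "Chromosome",
                             "pos": "Position", "genotype": "YourCode"}},
    "ftdna": {"delim": ",", "header": True,
              "columns": {"rsid": "RSID", "chrom": "CHROMOSOME",
                          "pos": "POSITION", "genotype": "RESULT"}},
}


def parse_array(
    stream: IO[str],
    dialect: str,
    sample_id: str = "sample",
    dialect_config: dict | None = None,
) -> SampleGenotypes:
    """Parse one consumer-array genotype file into a :class:`SampleGenotypes`.

    ``dialect`` is one of ``23andme``, ``affymetrix``, ``decodeme``,
    ``ftdna``.  No-call tokens (``--``, ``00``, ``NN``, empty) become
    :data:`MISSING`; a single-character genotype on X/Y/MT is duplicated to a
    homozygous diploid representation.  ``dialect_config`` may override the
    CSV column names of the header-carrying dialects.
    """
    if dialect not in DIALECTS:
        raise ArrayFormatError(
            f"unknown dialect {dialect!r}; expected one of {', '.join(DIALECTS)}"
        )
    layout = dict(_DIALECT_LAYOUT[dialect])
    if dialect_config:
        layout.update(dialect_config)

    sample = SampleGenotypes(sample_id=sample_id)

    if layout["header"]:
        reader = csv.DictReader(stream, delimiter=layout["delim"])
        cols = layout["columns"]
        missing_cols = set(cols.values()) - set(reader.fieldnames or [])
        if missing_cols:
            raise ArrayFormatError(
                f"{dialect} file lacks expected column(s) {sorted(missing_cols)}"
            )
        for line_no, row in enumerate(reader, start=2):
            _add_array_call(sample, dialect, line_no,
                            row[cols["rsid"]], row[cols["chrom"]],
                            row[cols["pos"]], row[cols["genotype"]])
    else:
        for line_no, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split(layout["delim"])
            if len(parts) < 4:
                raise ArrayFormatError(f"{dialect} line {line_no}: expected 4 fields")
            _add_array_call(sample, dialect, line_no, *parts[:4])

    return sample


def _add_array_call(sample, dialect, line_no, rsid, chrom, pos, genotype) -> None:
    rsid = rsid.strip()
    try:
        position = int(str(pos).strip())
    except ValueError as exc:
        raise ArrayFormatError(
            f"{dialect} line {line_no}: unparseable position {pos!r}"
        ) from exc
    sample.add(GenotypeCall(
        sample_id=sample.sample_id,
        rsid=rsid if rsid.startswith("rs") else "",
        chrom=normalize_chrom(chrom),
        position=position,
        alleles=_array_genotype(genotype, chrom),
        source_format=dialect,
    ))


def write_vcf(samples: list[SampleGenotypes], stream: IO[str]) -> None:
    """Write samples sharing a common site set as a minimal multi-sample VCF.

    REF is the alphabetically earlier allele observed at the site and ALT the
    later; missing genotypes are emitted as ``./.``.  The union of sites
    across samples is used, ordered by (chrom, position).
    """
    site_info: dict[str, tuple[str, int]] = {}
    site_alleles: dict[str, set[str]] = {}
    for s in samples:
        for call in s.calls.values():
            site_info.setdefault(call.key, (call.chrom, call.position))
            if call.alleles is not MISSING:
                site_alleles.setdefault(call.key, set()).update(call.alleles)

    stream.write("##fileformat=VCFv4.2\n")
    stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.sample_id for s in samples) + "\n")
    for key in sorted(site_info, key=lambda k: (site_info[k][0], site_info[k][1], k)):
        chrom, pos = site_info[key]
        alleles = sorted(site_alleles.get(key, set()))
        if not alleles:
            continue  # a site missing in every sample carries no allele info
        ref = alleles[0]
        alt = alleles[1] if len(alleles) > 1 else next(b for b in "ACGT" if b != ref)
        pool = {ref: "0", alt: "1"}
        cells = []
        for s in samples:
            call = s.calls.get(key)
            if call is None or call.alleles is MISSING:
                cells.append("./.")
            else:
                cells.append("/".join(sorted(pool[a] for a in call.alleles)))
        rsid = key if key.startswith("rs") else "."
        stream.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def write_array(sample: SampleGenotypes, dialect: str, stream: IO[str]) -> None:
    """Write one sample's calls in a consumer-array dialect."""
    if dialect not in DIALECTS:
        raise ArrayFormatError(f"unknown dialect {dialect!r}")
    calls = sorted(sample.calls.values(), key=lambda c: (c.chrom, c.position, c.key))
    if dialect in ("23andme", "affymetrix"):
        if dialect == "23andme":
            stream.write("# rsid\tchromosome\tposition\tgenotype\n")
        for c in calls:
            g = c.alleles if c.alleles is not MISSING else "--"
            stream.write(f"{c.key}\t{c.chrom}\t{c.position}\t{g}\n")
    elif dialect == "decodeme":
        stream.write("Name,Variation,Chromosome,Position,Strand,YourCode\n")
        for c in calls:
            g = c.alleles if c.alleles is not MISSING else "--"
            stream.write(f"{c.key},,{c.chrom},{c.position},+,{g}\n")
    else:  # ftdna
        stream.write("RSID,CHROMOSOME,POSITION,RESULT\n")
        for c in calls:
            g = c.alleles if c.alleles is not MISSING else "--"
            stream.write(f"{c.key},{c.chrom},{c.position},{g}\n")


def open_genotype_file(path: str | Path) -> IO[str]:
    """Open a genotype file as text, transparently handling gzip by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")
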