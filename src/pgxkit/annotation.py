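"""Clinical annotation: join observed genotypes against the knowledge base.

Matching is exact at the genotype level — a knowledge-base row for AG never
matches an observed GG, because drug-response phenotypes are curated per
genotype.  The primary join key is the rsID; a positional fallback
(chrom:pos) is used only for calls that carry no rsID, with a warning.
Missing genotypes never match anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .knowledgebase import EvidenceLevel, KnowledgeBase, VariantAnnotation
from .variant_io import MISSING, SampleGenotypes

logger = logging.getLogger(__name__)

__all__ = ["MatchedAnnotation", "match_genotype", "annotate_sample", "annotate_cohort"]

_CANONICAL = frozenset(
    a + b for i, a in enumerate("ACGT") for b in "ACGT"[i:]
)


@dataclass(frozen=True)
class MatchedAnnotation:
    """A knowledge-base row that an observed sample genotype hit exactly."""

    sample_id: str
    annotation: VariantAnnotation
    observed_genotype: str

    def __post_init__(self):
        if self.observed_genotype != self.annotation.genotype:
            raise ValueError(
                f"observed genotype {self.observed_genotype} differs from "
                f"annotation genotype {self.annotation.genotype}"
            )


def match_genotype(observed: str | None, kb_genotype: str) -> bool:
    """True iff the canonical genotype strings are equal; MISSING never matches."""
    if observed is MISSING:
        return False
    for g in (observed, kb_genotype):
        if g not in _CANONICAL:
            raise ValueError(f"non-canonical genotype {g!r}")
    return observed == kb_genotype


def _sort_key(m: MatchedAnnotation):
    a = m.annotation
    return (a.drug_name, a.evidence.rank, a.rsid, a.aspect)


def annotate_sample(
    sample: SampleGenotypes,
    kb: KnowledgeBase,
    min_evidence: EvidenceLevel | str | None = None,
) -> list[MatchedAnnotation]:
    """All knowledge-base rows matched exactly by one sample's genotypes.

    For each call with a non-missing genotype, every KB row with the same
    rsID and the same canonical genotype is emitted, optionally restricted to
    evidence at least as strong as ``min_evidence``.  Output is sorted by
    (drug, evidence rank, rsid, aspect) and is deterministic.
    """
    if isinstance(min_evidence, str):
        min_evidence = EvidenceLevel(min_evidence)

    out: list[MatchedAnnotation] = []
    for call in sample.calls.values():
        if call.alleles is MISSING:
            continue
        if call.rsid:
            rows = kb.index_by_rsid.get(call.rsid, [])
        else:
            rows = kb.index_by_position.get((call.chrom, call.position), [])
            if rows:
                logger.warning(
                    "sample %s: positional fallback match at %s:%d (no rsID on call)",
                    sample.sample_id, call.chrom, call.position,
                )
        for ann in rows:
            if not match_genotype(call.alleles, ann.genotype):
                continue
            if min_evidence is not None and ann.evidence < min_evidence:
                continue
            out.append(MatchedAnnotation(
                sample_id=sample.sample_id,
                annotation=ann,
                observed_genotype=call.alleles,
            ))
    out.sort(key=_sort_key)
    return out


def annotate_cohort(
    samples: list[SampleGenotypes],
    kb: KnowledgeBase,
    min_evidence: EvidenceLevel | str | None = None,
) -> dict[str, list[MatchedAnnotation]]:
    """Per-sample annotation for a cohort; sample order is preserved.

    Raises ``ValueError`` on duplicate sample ids.  Samples without any
    knowledge-base overlap map to an empty list but stay present.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample id(s): {', '.join(dupes)}")
    return {s.sample_id: annotate_sample(s, kb, min_evidence) for s in samples}
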