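"""Shared fixtures: the bundled mini knowledge base and sample builders."""

from __future__ import annotations

import pytest

from pgxkit import builtin_mini_kb
from pgxkit.variant_io import GenotypeCall, SampleGenotypes


@pytest.fixture(scope="session")
def mini_kb():
    return builtin_mini_kb()


def make_sample(sample_id: str, genotypes: dict[str, str | None],
                kb=None, source="23andme") -> SampleGenotypes:
    """Build a SampleGenotypes from {rsid: genotype}; positions come from the
    KB when given, else are synthesized deterministically."""
    s = SampleGenotypes(sample_id=sample_id)
    for i, (rsid, geno) in enumerate(genotypes.items(), start=1):
        if kb is not None and rsid in kb.index_by_rsid:
            ann = kb.index_by_rsid[rsid][0]
            chrom, pos = ann.chrom, ann.position
        else:
            chrom, pos = "1", 1000 + i
        s.add(GenotypeCall(sample_id=sample_id, rsid=rsid, chrom=chrom,
                           position=pos, alleles=geno, source_format=source))
    return s


@pytest.fixture
def worked_sample(mini_kb):
    """The worked-example individual: rs1042522=CC and rs11615=GG."""
    return make_sample("patient1", {"rs1042522": "CC", "rs11615": "GG"}, kb=mini_kb)
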