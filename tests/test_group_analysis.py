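"""Cohort statistics: count tables, frequencies, summaries, divergence."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pgxkit.annotation import annotate_cohort
from pgxkit.group_analysis import (
    allele_frequencies,
    compare_to_group,
    genotype_distribution,
    group_summary,
    sample_drug_counts,
    sample_gene_counts,
)
from pgxkit.simulate import PopulationSpec, random_kb, simulate_cohort
from pgxkit.variant_io import GenotypeCall, SampleGenotypes

from conftest import make_sample


@pytest.fixture(scope="module")
def synthetic_cohort():
    kb = random_kb(n_rows=120, n_drugs=8, seed=9)
    specs = [PopulationSpec("AFR", 20), PopulationSpec("EUR", 20),
             PopulationSpec("EAS", 10)]
    samples, groups, truth = simulate_cohort(kb, specs, seed=77)
    matches = annotate_cohort(samples, kb)
    return kb, samples, groups, truth, matches


def groupby_oracle(matches, col):
    """Independent pandas group-by recount from a flat match dataframe."""
    rows = [(s, m.annotation.rsid,
             m.annotation.gene_symbol if col == "gene" else m.annotation.drug_name)
            for s, ml in matches.items() for m in ml]
    df = pd.DataFrame(rows, columns=["sample", "rsid", col])
    return df.drop_duplicates().groupby(["sample", col]).size()


class TestCountTables:
    def test_one_sample_direct_counts(self, mini_kb):
        s = make_sample("s", {"rs1042522": "CC", "rs11615": "GG"}, kb=mini_kb)
        matches = annotate_cohort([s], mini_kb)
        genes = sample_gene_counts(matches)
        assert genes.loc["s", "GENE_CIS1"] == 1 and genes.loc["s", "GENE_CIS3"] == 1
        drugs = sample_drug_counts(matches)
        assert drugs.loc["s", "cisplatin"] == 2

    def test_empty_cohort_gives_empty_table(self):
        assert sample_gene_counts({}).shape == (0, 0)

    def test_multi_drug_rsid_counts_once_per_drug(self, mini_kb):
        s = make_sample("s", {"rs2108622": "TT"}, kb=mini_kb)
        matches = annotate_cohort([s], mini_kb)
        drugs = sample_drug_counts(matches)
        assert drugs.loc["s", "warfarin"] == 1
        assert drugs.loc["s", "phenprocoumon"] == 1

    def test_tables_equal_groupby_oracle(self, synthetic_cohort):
        _, _, _, _, matches = synthetic_cohort
        for fn, col in ((sample_gene_counts, "gene"), (sample_drug_counts, "drug")):
            table = fn(matches)
            oracle = groupby_oracle(matches, col)
            for (s, c), n in oracle.items():
                assert table.loc[s, c] == n
            assert int(table.to_numpy().sum()) == int(oracle.sum())

    def test_row_sum_equals_distinct_pairs(self, synthetic_cohort):
        _, _, _, _, matches = synthetic_cohort
        genes = sample_gene_counts(matches)
        for s, ml in matches.items():
            pairs = {(m.annotation.rsid, m.annotation.gene_symbol) for m in ml}
            assert genes.loc[s].sum() == len(pairs)
            rsids = {m.annotation.rsid for m in ml}
            assert sample_drug_counts(matches).loc[s].sum() >= len(rsids)

    def test_permuting_samples_permutes_rows(self, synthetic_cohort):
        _, _, _, _, matches = synthetic_cohort
        reversed_matches = dict(reversed(list(matches.items())))
        a = sample_gene_counts(matches)
        b = sample_gene_counts(reversed_matches)
        assert list(b.index) == list(reversed(a.index))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestGenotypeDistribution:
    def test_direct_fraction(self):
        samples = [make_sample(f"s{i}", {"rs11615": g})
                   for i, g in enumerate(["AG", "AG", "GG", "GG"])]
        groups = {s.sample_id: "EUR" for s in samples}
        dist = genotype_distribution(samples, ["rs11615"], groups)
        freqs = dict(zip(dist["genotype"], dist["frequency"]))
        assert freqs == {"AG": 0.5, "GG": 0.5}

    def test_all_missing_locus(self):
        samples = [make_sample(f"s{i}", {"rs1": None}) for i in range(3)]
        groups = {s.sample_id: "G" for s in samples}
        dist = genotype_distribution(samples, ["rs1"], groups)
        assert list(dist["genotype"]) == ["MISSING"]
        assert dist["missing_fraction"].iloc[0] == 1.0

    def test_unassigned_sample_named_in_error(self):
        samples = [make_sample("orphan", {"rs1": "AA"})]
        with pytest.raises(ValueError, match="orphan"):
            genotype_distribution(samples, ["rs1"], {})

    def test_frequencies_normalize_per_cell(self, synthetic_cohort):
        kb, samples, groups, _, _ = synthetic_cohort
        dist = genotype_distribution(samples, sorted(kb.index_by_rsid), groups)
        observed = dist[dist["genotype"] != "MISSING"]
        sums = observed.groupby(["rsid", "population"])["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_allele_frequencies_normalize(self, synthetic_cohort):
        kb, samples, groups, _, _ = synthetic_cohort
        af = allele_frequencies(samples, sorted(kb.index_by_rsid), groups)
        sums = af.groupby(["rsid", "population"])["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_recovers_hardy_weinberg_within_three_se(self, mini_kb):
        specs = [PopulationSpec(lbl, 500, {"rs11615": q})
                 for lbl, q in (("AFR", 0.2), ("EUR", 0.7))]
        samples, groups, truth = simulate_cohort(mini_kb, specs, seed=13)
        dist = genotype_distribution(samples, ["rs11615"], groups)
        ok = total = 0
        for _, row in dist.iterrows():
            expect = truth.expected_genotype_freqs[("rs11615", row["population"])]
            p = expect.get(row["genotype"], 0.0)
            se = math.sqrt(max(p * (1 - p), 1e-12) / 500)
            total += 1
            ok += abs(row["frequency"] - p) <= 3 * se
        assert ok / total >= 0.95


class TestGroupSummary:
    def test_hand_arithmetic(self, mini_kb):
        # per-sample distinct matched rsid counts {2, 4} -> mean 3, SD sqrt(2)
        s1 = make_sample("a", {"rs1042522": "CC", "rs11615": "GG"}, kb=mini_kb)
        s2 = make_sample("b", {"rs1042522": "CC", "rs11615": "GG",
                               "rs316019": "CC", "rs2292566": "AA"}, kb=mini_kb)
        matches = annotate_cohort([s1, s2], mini_kb)
        out = group_summary(matches, {"a": "EUR", "b": "EUR"}, mini_kb)
        row = out.set_index("population").loc["EUR"]
        assert row["n"] == 2
        assert row["mean_all"] == pytest.approx(3.0)
        assert row["sd_all"] == pytest.approx(math.sqrt(2))

    def test_identical_samples_have_zero_sd(self, mini_kb):
        samples = [make_sample(f"s{i}", {"rs1042522": "CC"}, kb=mini_kb)
                   for i in range(3)]
        matches = annotate_cohort(samples, mini_kb)
        out = group_summary(matches, {s.sample_id: "G" for s in samples}, mini_kb)
        assert out["sd_all"].iloc[0] == 0.0

    def test_singleton_group_sd_is_nan(self, mini_kb):
        matches = annotate_cohort([make_sample("solo", {"rs11615": "GG"}, kb=mini_kb)],
                                  mini_kb)
        out = group_summary(matches, {"solo": "G"}, mini_kb)
        assert math.isnan(out["sd_all"].iloc[0])

    def test_fda_mean_bounded_by_overall_mean(self, synthetic_cohort):
        kb, _, groups, _, matches = synthetic_cohort
        out = group_summary(matches, groups, kb)
        assert (out["mean_fda"] <= out["mean_all"] + 1e-12).all()

    def test_equals_independent_recomputation(self, synthetic_cohort):
        kb, _, groups, _, matches = synthetic_cohort
        out = group_summary(matches, groups, kb).set_index("population")
        # spreadsheet-style recount from flat (sample, rsid, fda) triples
        rows = [(s, m.annotation.rsid, m.annotation.fda_labeled)
                for s, ml in matches.items() for m in ml]
        df = pd.DataFrame(rows, columns=["sample", "rsid", "fda"]).drop_duplicates()
        df["population"] = df["sample"].map(groups)
        for label, sub in df.groupby("population"):
            group_sample_ids = [s for s, g in groups.items() if g == label]
            per_all = [sub[sub["sample"] == s]["rsid"].nunique() for s in group_sample_ids]
            per_fda = [sub[(sub["sample"] == s) & sub["fda"]]["rsid"].nunique()
                       for s in group_sample_ids]
            assert out.loc[label, "mean_all"] == pytest.approx(np.mean(per_all))
            assert out.loc[label, "sd_all"] == pytest.approx(np.std(per_all, ddof=1))
            assert out.loc[label, "mean_fda"] == pytest.approx(np.mean(per_fda))
            assert out.loc[label, "sd_fda"] == pytest.approx(np.std(per_fda, ddof=1))


class TestCompareToGroup:
    def _cohort(self, mini_kb, index_geno, group_genos):
        index = make_sample("index", {"rs11615": index_geno}, kb=mini_kb)
        members = [make_sample(f"m{i}", {"rs11615": g}, kb=mini_kb)
                   for i, g in enumerate(group_genos)]
        cohort = [index] + members
        groups = {s.sample_id: "EUR" for s in cohort}
        matches = annotate_cohort([index], mini_kb)["index"]
        return matches, cohort, groups

    def test_majority_genotype_not_flagged(self, mini_kb):
        matches, cohort, groups = self._cohort(mini_kb, "GG", ["GG"] * 5)
        rep = compare_to_group(matches, cohort, groups, "EUR")
        assert (rep.total_matched, rep.flagged) == (1, 0)

    def test_genotype_absent_from_group_flagged(self, mini_kb):
        matches, cohort, groups = self._cohort(mini_kb, "GG", ["AG"] * 5)
        rep = compare_to_group(matches, cohort, groups, "EUR")
        assert rep.flagged == 1
        assert rep.loci["group_frequency"].iloc[0] == 0.0

    def test_unknown_label_rejected(self, mini_kb):
        matches, cohort, groups = self._cohort(mini_kb, "GG", ["GG"])
        with pytest.raises(ValueError, match="MARS"):
            compare_to_group(matches, cohort, groups, "MARS")

    def test_planted_rare_genotypes_all_flagged(self, mini_kb):
        # index sample carries the minor homozygote at two loci where the
        # group is fixed for the other homozygote
        index = make_sample("index", {"rs11615": "AA", "rs1042522": "CC",
                                      "rs316019": "CC"}, kb=mini_kb)
        members = [make_sample(f"m{i}", {"rs11615": "AA", "rs1042522": "GG",
                                         "rs316019": "GG"}, kb=mini_kb)
                   for i in range(8)]
        cohort = [index] + members
        groups = {s.sample_id: "EUR" for s in cohort}
        from pgxkit.annotation import annotate_sample
        matches = annotate_sample(index, mini_kb)
        rep = compare_to_group(matches, cohort, groups, "EUR")
        # planted: rs1042522 CC and rs316019 CC are absent from the group;
        # rs11615 AA matches no KB row so contributes nothing
        assert rep.total_matched == 2
        assert rep.flagged == 2
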