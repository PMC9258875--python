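"""Gene-evidence prioritization, oligogenic pairs and summary statistics."""

import io
import random

import pytest
from hypothesis import given, strategies as st

from famvar.annotation import PopulationFrequencies, VariantAnnotation
from famvar.evaluation import (
    CandidateReport,
    EvaluationError,
    GeneEvidence,
    allele_fraction,
    cooccurrence_probability,
    cosegregating_pairs,
    deviation_in_sd,
    diagnostic_yield,
    evidence_class,
    rank_candidates,
    read_candidates,
    write_candidates,
)
from famvar.segregation import AUTOSOMAL_DOMINANT, SegregationResult
from famvar.variants import VariantSite


class TestEvidenceClass:
    def test_human_chd_gene_is_strong(self, study_knowledge):
        assert evidence_class("NOTCH1", study_knowledge) == "strong"

    def test_model_only_gene_is_supported(self, study_knowledge):
        # HEY1 has mouse-model support but no human CHD report
        assert evidence_class("HEY1", study_knowledge) == "supported"

    def test_absent_gene_is_unsupported(self, study_knowledge):
        assert evidence_class("NOT_A_GENE", study_knowledge) == "unsupported"

    def test_priority_of_flags(self):
        k = {
            "A": GeneEvidence("A", human_chd_reported=True, mouse_model_chd=True),
            "B": GeneEvidence("B", cardiac_development_role=True),
            "C": GeneEvidence("C"),
        }
        assert [evidence_class(g, k) for g in "ABC"] == [
            "strong", "supported", "unsupported"]


def seg_result(site):
    return SegregationResult(variant=site, model=AUTOSOMAL_DOMINANT, passed=True)


def make_ann(site, gene, maf, cadd, nhom=None):
    return VariantAnnotation(
        site.chrom, site.pos, site.ref, site.alt, gene_symbol=gene,
        frequencies=(
            PopulationFrequencies("exomes", (("all", maf),), homozygote_count=nhom),
        ),
        cadd_phred=cadd,
    )


class TestRanking:
    def test_family_16_like_pair_orders_casz1_first_and_flags_eln(self):
        casz1 = VariantSite("1", 1000, "C", "T")
        eln = VariantSite("7", 2000, "G", "A")
        anns = {
            casz1.key: make_ann(casz1, "CASZ1", 0.0007, 32.0),
            eln.key: make_ann(eln, "ELN", 0.006, 23.0, nhom=2),
        }
        knowledge = {
            "CASZ1": GeneEvidence("CASZ1", human_chd_reported=True),
            "ELN": GeneEvidence("ELN", human_chd_reported=True,
                                gnomad_homozygote_count=2),
        }
        ranked = rank_candidates(
            [seg_result(casz1), seg_result(eln)], knowledge, anns, family_id="16")
        assert [r.gene for r in ranked] == ["CASZ1", "ELN"]
        assert ranked[0].rank == 1 and ranked[0].demotion_flags == ()
        assert "gnomad_homozygotes" in ranked[1].demotion_flags

    def test_single_candidate_gets_rank_one(self):
        s = VariantSite("1", 10, "A", "G")
        ranked = rank_candidates(
            [seg_result(s)], {}, {s.key: make_ann(s, "G1", 0.001, 25.0)})
        assert [r.rank for r in ranked] == [1]

    def test_matches_brute_force_comparator(self):
        rng = random.Random(5)
        sites, anns, results, knowledge = [], {}, [], {}
        for i in range(40):
            s = VariantSite("1", 100 + i, "A", "G")
            gene = f"G{i}"
            cls = rng.choice(["strong", "supported", "unsupported"])
            knowledge[gene] = GeneEvidence(
                gene,
                human_chd_reported=cls == "strong",
                mouse_model_chd=cls == "supported",
            )
            cadd = rng.choice([None, rng.uniform(0, 45)])
            anns[s.key] = make_ann(s, gene, rng.choice([0.0, 1e-4, 5e-3, 2e-2]), cadd)
            results.append(seg_result(s))
        ranked = rank_candidates(results, knowledge, anns)
        # independent comparator over the stated key
        cls_order = {"strong": 0, "supported": 1, "unsupported": 2}
        tier_order = {"I": 0, "II": 1, "unscored": 2, "III": 3}
        expected = sorted(
            ranked,
            key=lambda r: (
                cls_order[r.evidence_class],
                tier_order[r.tier],
                -(r.cadd_phred if r.cadd_phred is not None else float("-inf")),
                r.max_maf,
                r.variant_label,
            ),
        )
        assert [r.variant_label for r in ranked] == [r.variant_label for r in expected]
        assert [r.rank for r in ranked] == list(range(1, len(ranked) + 1))


class TestCooccurrence:
    def test_published_pair_value(self):
        assert cooccurrence_probability(0.014, 0.012) == pytest.approx(
            0.000168, abs=1e-12)

    def test_zero_frequency_gives_zero(self):
        assert cooccurrence_probability(0.3, 0.0) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetric_and_bounded(self, a, b):
        p = cooccurrence_probability(a, b)
        assert p == cooccurrence_probability(b, a)
        assert 0.0 <= p <= min(a, b) + 1e-12

    def test_carrier_model_alternative(self):
        p, q = 0.014, 0.012
        assert cooccurrence_probability(p, q, carrier_model=True) == pytest.approx(
            (2 * p * (1 - p)) * (2 * q * (1 - q)))

    def test_out_of_range_rejected(self):
        with pytest.raises(EvaluationError):
            cooccurrence_probability(-0.1, 0.5)


def report(gene, maf, family="154"):
    return CandidateReport(
        family_id=family,
        variant_label=f"1:{hash(gene) % 10_000}:A>G",
        gene=gene,
        hgvs="",
        max_maf=maf,
        cadd_phred=30.0,
        tier="I",
        models_passed=(AUTOSOMAL_DOMINANT,),
        evidence_class="strong",
    )


class TestCosegregatingPairs:
    def test_family_154_like_two_genes_one_pair(self):
        pairs = cosegregating_pairs([report("ROCK1", 0.0), report("MCTP2", 0.0005)])
        assert len(pairs) == 1
        (a, b), p = pairs[0]
        assert {a.gene, b.gene} == {"ROCK1", "MCTP2"}
        assert p == 0.0

    def test_single_candidate_no_pairs(self):
        assert cosegregating_pairs([report("ROCK1", 0.0)]) == []

    def test_three_candidates_three_pairs(self):
        pairs = cosegregating_pairs(
            [report("A", 0.01), report("B", 0.02), report("C", 0.03)])
        assert len(pairs) == 3
        assert {frozenset((a.gene, b.gene)) for (a, b), _ in pairs} == {
            frozenset("AB"), frozenset("AC"), frozenset("BC")}

    def test_same_gene_candidates_not_paired(self):
        assert cosegregating_pairs([report("A", 0.01), report("A", 0.02)]) == []


class TestSummaryStatistics:
    def test_study_outcomes_give_42_percent(self):
        from famvar.fixtures import load_study_outcomes

        num, den, pct = diagnostic_yield(load_study_outcomes())
        assert (num, den, pct) == (8, 19, 42)

    def test_zero_of_n(self):
        assert diagnostic_yield({"a": "none", "b": "candidate_only"})[2] == 0

    def test_one_of_three_rounds_to_33(self):
        assert diagnostic_yield(
            {"a": "causative", "b": "none", "c": "none"}) == (1, 3, 33)

    def test_empty_map_is_error(self):
        with pytest.raises(EvaluationError):
            diagnostic_yield({})

    def test_rna_seq_allele_fraction(self):
        frac, pct = allele_fraction(38, 227)
        assert pct == 17
        assert frac == pytest.approx(38 / 227)

    def test_allele_fraction_edges(self):
        assert allele_fraction(0, 50) == (0.0, 0)
        assert allele_fraction(227, 227) == (1.0, 100)
        with pytest.raises(EvaluationError):
            allele_fraction(1, 0)

    def test_western_blot_deviation(self):
        z = deviation_in_sd(0.23, 0.53, 0.08)
        assert z == pytest.approx(3.75)
        assert z >= 3

    def test_deviation_edges(self):
        assert deviation_in_sd(0.5, 0.5, 1.0) == 0.0
        with pytest.raises(EvaluationError):
            deviation_in_sd(1.0, 0.0, 0.0)

    @given(st.dictionaries(st.text(min_size=1, max_size=3),
                           st.sampled_from(["causative", "candidate_only", "none"]),
                           min_size=1, max_size=30))
    def test_yield_percent_consistent_with_counts(self, outcomes):
        num, den, pct = diagnostic_yield(outcomes)
        assert 0 <= pct <= 100
        assert abs(pct - 100.0 * num / den) <= 0.5


class TestCandidateIO:
    def test_empty_list_header_only(self):
        buf = io.StringIO()
        write_candidates([], buf)
        assert buf.getvalue().count("\n") == 1
        assert buf.getvalue().startswith("rank\t")

    def test_roundtrip_recovers_fields(self):
        reps = [report("ROCK1", 0.0), report("MCTP2", 0.0005)]
        for i, r in enumerate(reps, 1):
            r.rank = i
        buf = io.StringIO()
        write_candidates(reps, buf)
        back = read_candidates(io.StringIO(buf.getvalue()))
        assert [(r.gene, r.max_maf, r.rank) for r in back] == [
            (r.gene, r.max_maf, r.rank) for r in reps]
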