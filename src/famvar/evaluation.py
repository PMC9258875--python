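"""Candidate prioritization, oligogenic pair detection and summary statistics.

Gene-level evidence drives the primary ranking: a gene previously reported
as causing congenital heart disease (CHD) in humans is *strong*; a gene
with a CHD mouse model or a demonstrated role in cardiac development is
*supported*; anything else is *unsupported*.  Within an evidence class,
candidates sort by CADD tier (I > II > unscored > III), then raw CADD,
then rarity.  Soft counter-evidence — homozygotes in the population
database, or a frequency unusually high for a family-private disease
allele — attaches a demotion flag without changing the rank order, since
the corresponding judgment in practice is partly clinical.

For families segregating two plausible variants in different genes, the
co-occurrence probability of the pair is the product of the two population
allele frequencies — the probability that one individual drawn from the
population carries both alleles, as printed in the source analyses.  A
carrier-based alternative, (2p(1-p)) * (2q(1-q)), is available via
``carrier_model=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import pandas as pd

from .annotation import VariantAnnotation, cadd_tier, max_population_maf
from .segregation import SegregationResult

__all__ = [
    "GeneEvidence",
    "CandidateReport",
    "EvaluationError",
    "load_gene_evidence",
    "evidence_class",
    "rank_candidates",
    "cooccurrence_probability",
    "cosegregating_pairs",
    "diagnostic_yield",
    "allele_fraction",
    "deviation_in_sd",
    "write_candidates",
    "read_candidates",
]

STRONG = "strong"
SUPPORTED = "supported"
UNSUPPORTED = "unsupported"

# a family-private disease allele is typically well below 1e-3 in gnomAD;
# 10x that triggers the frequency demotion flag
TYPICAL_FAMILY_RARE_MAF = 1e-3


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneEvidence:
    gene_symbol: str
    human_chd_reported: bool = False
    mouse_model_chd: bool = False
    cardiac_development_role: bool = False
    gnomad_homozygote_count: int | None = None
    references: tuple[str, ...] = ()


def load_gene_evidence(tsv: IO[str] | str) -> dict[str, GeneEvidence]:
    """Load a gene-evidence knowledge table.

    Columns: gene, human_chd_reported, mouse_model_chd,
    cardiac_development_role, nhomalt, refs (semicolon separated).
    """
    df = pd.read_csv(tsv, sep="\t", dtype=str)
    out: dict[str, GeneEvidence] = {}
    truthy = {"1", "true", "yes", "y"}
    for _, row in df.iterrows():

        def flag(col: str) -> bool:
            v = row.get(col)
            return isinstance(v, str) and v.strip().lower() in truthy

        nhom = row.get("nhomalt")
        refs = row.get("refs")
        out[row["gene"]] = GeneEvidence(
            gene_symbol=row["gene"],
            human_chd_reported=flag("human_chd_reported"),
            mouse_model_chd=flag("mouse_model_chd"),
            cardiac_development_role=flag("cardiac_development_role"),
            gnomad_homozygote_count=(
                None if pd.isna(nhom) or nhom in ("", None) else int(float(nhom))
            ),
            references=tuple(str(refs).split(";")) if isinstance(refs, str) and refs else (),
        )
    return out


def evidence_class(gene: str, knowledge: Mapping[str, GeneEvidence]) -> str:
    """strong | supported | unsupported for a gene symbol."""
    ev = knowledge.get(gene)
    if ev is None:
        return UNSUPPORTED
    if ev.human_chd_reported:
        return STRONG
    if ev.mouse_model_chd or ev.cardiac_development_role:
        return SUPPORTED
    return UNSUPPORTED


@dataclass
class CandidateReport:
    family_id: str
    variant_label: str  # chrom:pos:ref>alt, "|"-joined for pairs
    gene: str
    hgvs: str
    max_maf: float
    cadd_phred: float | None
    tier: str
    models_passed: tuple[str, ...]
    evidence_class: str
    demotion_flags: tuple[str, ...] = ()
    rank: int = 0


_CLASS_ORDER = {STRONG: 0, SUPPORTED: 1, UNSUPPORTED: 2}
_TIER_ORDER = {"I": 0, "II": 1, "unscored": 2, "III": 3}


def _sort_key(rep: CandidateReport):
    return (
        _CLASS_ORDER[rep.evidence_class],
        _TIER_ORDER[rep.tier],
        -(rep.cadd_phred if rep.cadd_phred is not None else -math.inf),
        rep.max_maf,
        rep.variant_label,
    )


def rank_candidates(
    results: Sequence[SegregationResult],
    knowledge: Mapping[str, GeneEvidence],
    annotations: Mapping[tuple[str, int, str, str], VariantAnnotation],
    family_id: str = "",
) -> list[CandidateReport]:
    """Total ordering of passing candidates; ranks are 1-based and contiguous.

    Pairs (compound het) are ranked by their better member's annotation.
    """
    reports: list[CandidateReport] = []
    for r in results:
        if not r.passed:
            continue
        anns = [annotations.get(s.key) for s in r.sites]
        anns = [a for a in anns if a is not None]
        if not anns:
            continue
        best = max(anns, key=lambda a: (a.cadd_phred if a.cadd_phred is not None else -1.0))
        gene = best.gene_symbol
        maf = max(max_population_maf(a) for a in anns)
        flags: list[str] = []
        ev = knowledge.get(gene)
        nhom = best.nhomalt
        if ev is not None and ev.gnomad_homozygote_count:
            nhom = ev.gnomad_homozygote_count
        if nhom is not None and nhom >= 1:
            flags.append("gnomad_homozygotes")
        if maf > 10 * TYPICAL_FAMILY_RARE_MAF:
            flags.append("high_maf_for_private_allele")
        reports.append(
            CandidateReport(
                family_id=family_id,
                variant_label="|".join(
                    f"{s.chrom}:{s.pos}:{s.ref}>{s.alt}" for s in r.sites
                ),
                gene=gene,
                hgvs="|".join(a.hgvs_c or "" for a in anns),
                max_maf=maf,
                cadd_phred=best.cadd_phred,
                tier=cadd_tier(best.cadd_phred),
                models_passed=(r.model,),
                evidence_class=evidence_class(gene, knowledge),
                demotion_flags=tuple(flags),
            )
        )
    # merge duplicate variants passing under several models
    merged: dict[str, CandidateReport] = {}
    for rep in reports:
        if rep.variant_label in merged:
            prev = merged[rep.variant_label]
            prev.models_passed = tuple(
                sorted(set(prev.models_passed) | set(rep.models_passed))
            )
        else:
            merged[rep.variant_label] = rep
    ordered = sorted(merged.values(), key=_sort_key)
    for i, rep in enumerate(ordered, start=1):
        rep.rank = i
    return ordered


def cooccurrence_probability(
    maf_a: float, maf_b: float, carrier_model: bool = False
) -> float:
    """Probability of one individual carrying both population alleles.

    Default is the direct product of the two allele frequencies; with
    ``carrier_model`` the product of the two Hardy-Weinberg carrier
    frequencies, (2p(1-p)) * (2q(1-q)).
    """
    for f in (maf_a, maf_b):
        if not 0.0 <= f <= 1.0:
            raise EvaluationError(f"frequency {f} outside [0,1]")
    if carrier_model:
        return (2 * maf_a * (1 - maf_a)) * (2 * maf_b * (1 - maf_b))
    return maf_a * maf_b


def cosegregating_pairs(
    candidates: Sequence[CandidateReport],
) -> list[tuple[tuple[CandidateReport, CandidateReport], float]]:
    """Distinct-gene candidate pairs that each co-segregate in one family.

    Input candidates must already have passed segregation in every
    sequenced affected member (they are filter+segregation survivors); each
    unordered pair of candidates in different genes is annotated with the
    co-occurrence probability of their maximum population frequencies.
    """
    pairs = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            if a.gene and b.gene and a.gene != b.gene:
                pairs.append(((a, b), cooccurrence_probability(a.max_maf, b.max_maf)))
    return pairs


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def diagnostic_yield(
    family_outcomes: Mapping[str, str],
) -> tuple[int, int, int]:
    """(n causative families, n families, percent) over per-family outcomes.

    Outcomes are 'causative', 'candidate_only' or 'none'; percent is
    rounded half-up to the nearest integer.
    """
    if not family_outcomes:
        raise EvaluationError("family_outcomes is empty")
    bad = set(family_outcomes.values()) - {"causative", "candidate_only", "none"}
    if bad:
        raise EvaluationError(f"unknown outcomes: {sorted(bad)}")
    num = sum(1 for v in family_outcomes.values() if v == "causative")
    den = len(family_outcomes)
    return num, den, _round_half_up(100.0 * num / den)


def allele_fraction(variant_reads: int, total_reads: int) -> tuple[float, int]:
    """(fraction, percent half-up) of reads supporting the variant allele."""
    if total_reads <= 0:
        raise EvaluationError("total_reads must be positive")
    if not 0 <= variant_reads <= total_reads:
        raise EvaluationError("variant_reads must be in [0, total_reads]")
    frac = variant_reads / total_reads
    return frac, _round_half_up(100.0 * frac)


def deviation_in_sd(value: float, control_mean: float, control_sd: float) -> float:
    """Absolute deviation of ``value`` from a control mean, in control SDs."""
    if control_sd <= 0:
        raise EvaluationError("control_sd must be positive")
    return abs(control_mean - value) / control_sd


_CANDIDATE_COLS = [
    "rank", "family", "variant", "gene", "hgvs", "max_maf", "cadd_phred",
    "tier", "models_passed", "evidence_class", "demotion_flags",
]


def write_candidates(candidates: Sequence[CandidateReport], out: IO[str]) -> None:
    """Write ranked candidates as TSV with a deterministic column order."""
    out.write("\t".join(_CANDIDATE_COLS) + "\n")
    for rep in candidates:
        out.write(
            "\t".join(
                [
                    str(rep.rank),
                    rep.family_id,
                    rep.variant_label,
                    rep.gene,
                    rep.hgvs,
                    repr(rep.max_maf),
                    "" if rep.cadd_phred is None else repr(rep.cadd_phred),
                    rep.tier,
                    ",".join(rep.models_passed),
                    rep.evidence_class,
                    ",".join(rep.demotion_flags),
                ]
            )
            + "\n"
        )


def read_candidates(stream: IO[str] | str) -> list[CandidateReport]:
    """Parse a candidate TSV back into reports (round-trip of write_candidates)."""
    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            CandidateReport(
                family_id=row["family"],
                variant_label=row["variant"],
                gene=row["gene"],
                hgvs=row["hgvs"],
                max_maf=float(row["max_maf"]),
                cadd_phred=float(row["cadd_phred"]) if row["cadd_phred"] else None,
                tier=row["tier"],
                models_passed=tuple(row["models_passed"].split(",")) if row["models_passed"] else (),
                evidence_class=row["evidence_class"],
                demotion_flags=tuple(row["demotion_flags"].split(",")) if row["demotion_flags"] else (),
                rank=int(row["rank"]),
            )
        )
    return out
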