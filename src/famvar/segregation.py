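"""Co-segregation of candidate variants with disease through a pedigree.

Three inheritance models are evaluated against per-sample genotypes:

* **autosomal dominant** — every sequenced affected member carries at least
  one alternate allele; sequenced unaffected members carry none, unless
  reduced penetrance is allowed, in which case unaffected carriers are
  tolerated but recorded.
* **autosomal recessive (homozygous)** — every sequenced affected member is
  homozygous alternate; no sequenced unaffected member is; sequenced
  unaffected parents of affected members must be heterozygous carriers.
* **compound heterozygous** — two distinct variants in one gene, each
  heterozygous in every sequenced affected member, with phase assessed from
  parental transmission only: a pair is *trans-confirmed* when the two
  alternates demonstrably arrive from different parents, *cis* (excluded)
  when both demonstrably arrive through the same parent, and *unknown*
  otherwise (retained, flagged).

A missing genotype in an affected member fails segregation; the only
re-entry path is the low-coverage rescue flag from the filter engine, under
which an affected member's missing/low-coverage genotype backed by at least
one variant-supporting read is accepted as a carrier call pending
orthogonal confirmation.

X-linked/hemizygous logic is not modeled; sites on X are processed as
autosomal with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .pedigree import Pedigree, affected_members
from .variants import GenotypeCall, VariantSite

__all__ = [
    "AUTOSOMAL_DOMINANT",
    "AUTOSOMAL_RECESSIVE_HOM",
    "COMPOUND_HETEROZYGOUS",
    "MODELS",
    "SegregationError",
    "SegregationResult",
    "segregates_dominant",
    "segregates_recessive_hom",
    "compound_het_candidates",
    "family_candidates",
    "confirmation_manifest",
]

AUTOSOMAL_DOMINANT = "autosomal_dominant"
AUTOSOMAL_RECESSIVE_HOM = "autosomal_recessive_hom"
COMPOUND_HETEROZYGOUS = "compound_heterozygous"
MODELS = (AUTOSOMAL_DOMINANT, AUTOSOMAL_RECESSIVE_HOM, COMPOUND_HETEROZYGOUS)

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
MISSING = "missing"
CARRIER_UNAFFECTED = "carrier_unaffected"

TRANS_CONFIRMED = "trans_confirmed"
CIS = "cis"
PHASE_UNKNOWN = "unknown"


class SegregationError(ValueError):
    pass


@dataclass
class SegregationResult:
    variant: VariantSite | tuple[VariantSite, VariantSite]
    model: str
    per_member_status: dict[str, str] = field(default_factory=dict)
    passed: bool = False
    reduced_penetrance_used: bool = False
    phase_support: str | None = None  # pairs only

    @property
    def is_pair(self) -> bool:
        return isinstance(self.variant, tuple)

    @property
    def sites(self) -> tuple[VariantSite, ...]:
        return self.variant if self.is_pair else (self.variant,)


def _warn_if_x(site: VariantSite) -> None:
    if site.chrom.removeprefix("chr").upper() == "X":
        warnings.warn(
            f"site {site.chrom}:{site.pos} on X treated as autosomal "
            "(hemizygous logic not modeled)",
            stacklevel=3,
        )


def _sequenced(pedigree: Pedigree):
    return [m for m in pedigree if m.sequenced]


def segregates_dominant(
    site: VariantSite,
    calls: Mapping[str, GenotypeCall],
    pedigree: Pedigree,
    allow_unaffected_carriers: bool = False,
    rescued: bool = False,
) -> SegregationResult:
    """Dominant model: alt in all sequenced affected, absent from unaffected.

    ``allow_unaffected_carriers`` encodes suspected reduced penetrance;
    carriers among the unaffected are then recorded rather than failing the
    variant.  ``rescued`` marks a low-coverage rescued variant: an affected
    member with a missing genotype but >= 1 alt-supporting read counts as a
    carrier (pending confirmation).
    """
    _warn_if_x(site)
    affected = affected_members(pedigree, require_sequenced=True)
    if not affected:
        raise SegregationError(
            f"family {pedigree.family_id!r} has no sequenced affected members"
        )
    result = SegregationResult(variant=site, model=AUTOSOMAL_DOMINANT)
    ok = True
    for m in _sequenced(pedigree):
        call = calls.get(m.individual_id)
        n_alt = None if call is None else call.n_alt
        if m.affection == "affected":
            if n_alt is None:
                if rescued and call is not None and (call.alt_reads or 0) >= 1:
                    result.per_member_status[m.individual_id] = CONSISTENT
                else:
                    result.per_member_status[m.individual_id] = MISSING
                    ok = False
            elif n_alt >= 1:
                result.per_member_status[m.individual_id] = CONSISTENT
            else:
                result.per_member_status[m.individual_id] = INCONSISTENT
                ok = False
        elif m.affection == "unaffected":
            if n_alt is None:
                result.per_member_status[m.individual_id] = MISSING
            elif n_alt == 0:
                result.per_member_status[m.individual_id] = CONSISTENT
            elif allow_unaffected_carriers:
                result.per_member_status[m.individual_id] = CARRIER_UNAFFECTED
                result.reduced_penetrance_used = True
            else:
                result.per_member_status[m.individual_id] = INCONSISTENT
                ok = False
        else:  # unknown affection constrains nothing
            result.per_member_status[m.individual_id] = (
                MISSING if n_alt is None else CONSISTENT
            )
    result.passed = ok
    return result


def segregates_recessive_hom(
    site: VariantSite,
    calls: Mapping[str, GenotypeCall],
    pedigree: Pedigree,
) -> SegregationResult:
    """Recessive model: hom-alt in all sequenced affected, carriers elsewhere."""
    _warn_if_x(site)
    affected = affected_members(pedigree, require_sequenced=True)
    if not affected:
        raise SegregationError(
            f"family {pedigree.family_id!r} has no sequenced affected members"
        )
    result = SegregationResult(variant=site, model=AUTOSOMAL_RECESSIVE_HOM)
    ok = True

    def dosage(iid: str) -> int | None:
        call = calls.get(iid)
        return None if call is None else call.n_alt

    for m in _sequenced(pedigree):
        n_alt = dosage(m.individual_id)
        if m.affection == "affected":
            if n_alt is None:
                result.per_member_status[m.individual_id] = MISSING
                ok = False
            elif n_alt == 2:
                result.per_member_status[m.individual_id] = CONSISTENT
            else:
                result.per_member_status[m.individual_id] = INCONSISTENT
                ok = False
        elif m.affection == "unaffected":
            if n_alt is None:
                result.per_member_status[m.individual_id] = MISSING
            elif n_alt == 2:
                result.per_member_status[m.individual_id] = INCONSISTENT
                ok = False
            else:
                result.per_member_status[m.individual_id] = CONSISTENT
        else:
            result.per_member_status[m.individual_id] = (
                MISSING if n_alt is None else CONSISTENT
            )
    # sequenced non-affected parents of affected members must be carriers
    for m in affected:
        for pid in (m.father_id, m.mother_id):
            if pid and pid in pedigree.members and pedigree.members[pid].sequenced:
                if pedigree.members[pid].affection == "affected":
                    continue  # governed by the affected rule above
                n_alt = dosage(pid)
                if n_alt is not None and n_alt != 1:
                    result.per_member_status[pid] = INCONSISTENT
                    ok = False
    result.passed = ok
    return result


def _transmitting_parents(
    site_calls: Mapping[str, GenotypeCall],
    child_id: str,
    pedigree: Pedigree,
) -> set[str] | None:
    """Which sequenced parents could have transmitted the alt to ``child_id``.

    Returns None when transmission cannot be constrained (a parent
    unsequenced or missing genotype).
    """
    ind = pedigree.members[child_id]
    carriers: set[str] = set()
    for pid in (ind.father_id, ind.mother_id):
        if not pid or pid not in pedigree.members or not pedigree.members[pid].sequenced:
            return None
        call = site_calls.get(pid)
        if call is None or call.n_alt is None:
            return None
        if call.n_alt >= 1:
            carriers.add(pid)
    return carriers


def compound_het_candidates(
    gene_variants: Sequence[tuple[VariantSite, Mapping[str, GenotypeCall]]],
    pedigree: Pedigree,
    genes: Sequence[str] | None = None,
) -> list[SegregationResult]:
    """Compound-het pairs among variants of a single gene.

    Returns one result per unordered pair in which every sequenced affected
    member is heterozygous for both variants.  Provably cis pairs are
    excluded; trans-confirmed and phase-unknown pairs are returned with
    ``phase_support`` set accordingly.  A trans-confirmed pair fails if a
    sequenced unaffected member also carries both variants.
    """
    if genes is not None and len(set(genes)) > 1:
        raise SegregationError(f"compound-het variants span genes {sorted(set(genes))}")
    affected = affected_members(pedigree, require_sequenced=True)
    if not affected:
        raise SegregationError(
            f"family {pedigree.family_id!r} has no sequenced affected members"
        )
    out: list[SegregationResult] = []
    for (site_a, calls_a), (site_b, calls_b) in combinations(gene_variants, 2):
        result = SegregationResult(
            variant=(site_a, site_b), model=COMPOUND_HETEROZYGOUS
        )
        ok = True
        for m in affected:
            na = calls_a.get(m.individual_id)
            nb = calls_b.get(m.individual_id)
            da = None if na is None else na.n_alt
            db = None if nb is None else nb.n_alt
            if da is None or db is None:
                result.per_member_status[m.individual_id] = MISSING
                ok = False
            elif da == 1 and db == 1:
                result.per_member_status[m.individual_id] = CONSISTENT
            else:
                result.per_member_status[m.individual_id] = INCONSISTENT
                ok = False
        if not ok:
            continue
        # phase from parental transmission, per affected member
        phase = PHASE_UNKNOWN
        cis_proven = False
        for m in affected:
            pa = _transmitting_parents(calls_a, m.individual_id, pedigree)
            pb = _transmitting_parents(calls_b, m.individual_id, pedigree)
            if pa is None or pb is None:
                continue
            # the child is het for each variant, so the alt came from a carrier parent
            if len(pa) == 1 and len(pb) == 1:
                if pa == pb:
                    cis_proven = True
                else:
                    phase = TRANS_CONFIRMED
        if cis_proven:
            continue  # both alts ride one transmitted haplotype
        result.phase_support = phase
        # a trans-confirmed pathogenic pair must not appear intact in unaffecteds
        if phase == TRANS_CONFIRMED:
            for m in _sequenced(pedigree):
                if m.affection != "unaffected":
                    continue
                da = calls_a.get(m.individual_id)
                db = calls_b.get(m.individual_id)
                if (
                    da is not None and (da.n_alt or 0) >= 1
                    and db is not None and (db.n_alt or 0) >= 1
                ):
                    result.per_member_status[m.individual_id] = INCONSISTENT
                    ok = False
        result.passed = ok
        if ok:
            out.append(result)
    return out


def family_candidates(
    variants: Sequence,  # FilteredVariant-like: .site, .calls, .annotation, .rescued
    pedigree: Pedigree,
    models: Sequence[str] = (AUTOSOMAL_DOMINANT,),
    allow_unaffected_carriers: bool = False,
) -> list[SegregationResult]:
    """Passing segregation results across the requested inheritance models.

    Input is the filter-engine survivor list; which models apply to a family
    is configuration (e.g. recessive/compound-het only for consanguineous or
    multi-sib structures), not inference.  Output order is deterministic:
    model, then genomic position.
    """
    unknown = set(models) - set(MODELS)
    if unknown:
        raise SegregationError(f"unknown inheritance models: {sorted(unknown)}")
    results: list[SegregationResult] = []
    for model in MODELS:
        if model not in models:
            continue
        if model == AUTOSOMAL_DOMINANT:
            for fv in variants:
                r = segregates_dominant(
                    fv.site,
                    fv.calls,
                    pedigree,
                    allow_unaffected_carriers=allow_unaffected_carriers,
                    rescued=getattr(fv, "rescued", False),
                )
                if r.passed:
                    results.append(r)
        elif model == AUTOSOMAL_RECESSIVE_HOM:
            for fv in variants:
                r = segregates_recessive_hom(fv.site, fv.calls, pedigree)
                if r.passed:
                    results.append(r)
        elif model == COMPOUND_HETEROZYGOUS:
            by_gene: dict[str, list] = {}
            for fv in variants:
                gene = fv.annotation.gene_symbol
                if gene:
                    by_gene.setdefault(gene, []).append(fv)
            for gene in sorted(by_gene):
                group = by_gene[gene]
                if len(group) < 2:
                    continue
                pairs = compound_het_candidates(
                    [(fv.site, fv.calls) for fv in group], pedigree
                )
                results.extend(p for p in pairs if p.passed)
    order = {m: i for i, m in enumerate(MODELS)}
    results.sort(
        key=lambda r: (order[r.model], [(s.chrom, s.pos, s.alt) for s in r.sites])
    )
    return results


def confirmation_manifest(
    results: Sequence[SegregationResult],
    pedigree: Pedigree,
) -> list[tuple[str, str]]:
    """(individual, variant) rows for orthogonal (Sanger) confirmation.

    Every available family member — affected and unaffected — is paired
    with every candidate variant, deduplicated, in stable sorted order.
    """
    rows: set[tuple[str, str]] = set()
    for r in results:
        if not r.passed:
            continue
        for site in r.sites:
            label = f"{site.chrom}:{site.pos}:{site.ref}>{site.alt}"
            for m in pedigree:
                rows.add((m.individual_id, label))
    return sorted(rows)
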