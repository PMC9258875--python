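"""Frequency / impact / region filters with low-coverage rescue.

The filter chain mirrors a family-exome prioritization workflow: restrict to
the mutually covered capture targets, keep variants with maximum population
allele frequency <= ``maf_max``, keep predicted-damaging variants
(CADD >= ``cadd_min``; unscored variants are retained flagged by default,
since real candidate indels can lack CADD).  A per-step funnel records
in/out counts.

Rescue: a variant in a configured gene of interest whose calls in affected
members are low coverage (depth <= ``rescue_depth_max``) is re-admitted if
every sequenced affected member still shows at least one variant-supporting
read.  This is a deterministic, auditable stand-in for manual review of the
alignments; rescued variants are flagged as needing orthogonal confirmation
(e.g. Sanger).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import VariantAnnotation, cadd_tier, max_population_maf
from .intervals import IntervalSet, contains_site
from .pedigree import Pedigree, affected_members
from .variants import GenotypeCall, VariantSite

__all__ = [
    "FilterConfig",
    "FilterFunnel",
    "FilterError",
    "passes_frequency",
    "passes_impact",
    "rescue_low_coverage",
    "run_filters",
]

PASS = "pass"
PASS_FLAGGED_UNSCORED = "pass_flagged_unscored"
FAIL = "fail"

NOT_APPLICABLE = "not_applicable"
RESCUED = "rescued"
REJECTED = "rejected"

DEFAULT_STEP_ORDER = ("region", "frequency", "impact")


class FilterError(ValueError):
    pass


@dataclass
class FilterConfig:
    maf_max: float = 0.01
    cadd_min: float = 20.0
    target_regions: IntervalSet | None = None
    rescue_depth_max: int = 10
    genes_of_interest: frozenset[str] = frozenset()
    unscored_policy: str = "retain_flagged"  # or "drop"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_max <= 1.0:
            raise FilterError(f"maf_max {self.maf_max} outside [0,1]")
        if self.cadd_min < 0:
            raise FilterError("cadd_min must be >= 0")
        if self.rescue_depth_max < 0:
            raise FilterError("rescue_depth_max must be >= 0")
        if self.unscored_policy not in ("retain_flagged", "drop"):
            raise FilterError(f"unknown unscored_policy {self.unscored_policy!r}")
        self.genes_of_interest = frozenset(self.genes_of_interest)


@dataclass
class FilterFunnel:
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (name, in, out)
    rescued: int = 0  # re-admissions, tracked outside the monotone funnel

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise FilterError(f"funnel step {name!r}: out {n_out} > in {n_in}")
        if self.steps and self.steps[-1][2] != n_in:
            raise FilterError(f"funnel step {name!r}: input {n_in} != previous output")
        self.steps.append((name, n_in, n_out))

    def to_tsv(self) -> str:
        lines = ["step\tvariants_in\tvariants_out"]
        lines += [f"{s}\t{i}\t{o}" for s, i, o in self.steps]
        lines.append(f"# rescued_low_coverage\t{self.rescued}")
        return "\n".join(lines) + "\n"


def passes_frequency(ann: VariantAnnotation, config: FilterConfig) -> bool:
    """True iff the max population allele frequency is <= maf_max (inclusive)."""
    return max_population_maf(ann) <= config.maf_max


def passes_impact(ann: VariantAnnotation, config: FilterConfig) -> str:
    """'pass' | 'pass_flagged_unscored' | 'fail' under the CADD threshold."""
    if ann.cadd_phred is None:
        if config.unscored_policy == "retain_flagged":
            return PASS_FLAGGED_UNSCORED
        return FAIL
    if ann.cadd_phred >= config.cadd_min:
        return PASS
    return FAIL


def rescue_low_coverage(
    site: VariantSite,
    calls: Mapping[str, GenotypeCall],
    ann: VariantAnnotation,
    config: FilterConfig,
    pedigree: Pedigree,
) -> str:
    """'not_applicable' | 'rescued' | 'rejected' for a low-coverage call set.

    Applicable only when some sequenced affected member's call has
    total_depth <= rescue_depth_max.  Rescued requires the gene to be a
    configured gene of interest and every sequenced affected member to carry
    at least one variant-supporting read.
    """
    affected = affected_members(pedigree, require_sequenced=True)
    low = [
        m
        for m in affected
        if m.individual_id in calls
        and calls[m.individual_id].total_depth is not None
        and calls[m.individual_id].total_depth <= config.rescue_depth_max
    ]
    if not low:
        return NOT_APPLICABLE
    if ann.gene_symbol not in config.genes_of_interest:
        return REJECTED
    for m in affected:
        call = calls.get(m.individual_id)
        if call is None or call.alt_reads is None or call.alt_reads < 1:
            return REJECTED
    return RESCUED


@dataclass
class FilteredVariant:
    site: VariantSite
    calls: dict[str, GenotypeCall]
    annotation: VariantAnnotation
    flags: list[str] = field(default_factory=list)

    @property
    def needs_orthogonal_confirmation(self) -> bool:
        return "rescued_low_coverage" in self.flags

    @property
    def rescued(self) -> bool:
        return "rescued_low_coverage" in self.flags


def run_filters(
    records: Sequence[tuple[VariantSite, Mapping[str, GenotypeCall], VariantAnnotation]],
    config: FilterConfig,
    pedigree: Pedigree | None = None,
    step_order: Sequence[str] = DEFAULT_STEP_ORDER,
) -> tuple[list[FilteredVariant], FilterFunnel]:
    """Apply region -> frequency -> impact filters; rescue re-admits.

    The three predicates are independent, so permuting ``step_order``
    changes the funnel counts but never the surviving set.  When a pedigree
    is supplied, variants dropped by any step that qualify for low-coverage
    rescue are re-admitted (flagged) in a final ``rescue`` funnel step.
    """
    predicates = {
        "region": lambda s, c, a: (
            config.target_regions is None or contains_site(config.target_regions, s)
        ),
        "frequency": lambda s, c, a: passes_frequency(a, config),
        "impact": lambda s, c, a: passes_impact(a, config) != FAIL,
    }
    unknown = set(step_order) - set(predicates)
    if unknown:
        raise FilterError(f"unknown filter steps: {sorted(unknown)}")

    funnel = FilterFunnel()
    current = list(records)
    dropped: list[tuple[VariantSite, Mapping[str, GenotypeCall], VariantAnnotation]] = []
    for step in step_order:
        pred = predicates[step]
        kept = [r for r in current if pred(*r)]
        dropped += [r for r in current if not pred(*r)]
        funnel.record(step, len(current), len(kept))
        current = kept

    survivors = [
        FilteredVariant(site=s, calls=dict(c), annotation=a, flags=_impact_flags(a, config))
        for s, c, a in current
    ]
    if pedigree is not None and config.genes_of_interest:
        # low-coverage survivors also carry the rescue/confirmation flag,
        # which is segregation's re-entry path for missing affected genotypes
        for fv in survivors:
            if rescue_low_coverage(fv.site, fv.calls, fv.annotation, config, pedigree) == RESCUED:
                fv.flags.append("rescued_low_coverage")
        readmitted = []
        for s, c, a in dropped:
            if rescue_low_coverage(s, c, a, config, pedigree) == RESCUED:
                fv = FilteredVariant(site=s, calls=dict(c), annotation=a,
                                     flags=_impact_flags(a, config))
                fv.flags.append("rescued_low_coverage")
                readmitted.append(fv)
        readmitted.sort(key=lambda fv: (fv.site.chrom, fv.site.pos, fv.site.alt))
        funnel.rescued = len(readmitted)
        survivors += readmitted
    return survivors, funnel


def _impact_flags(ann: VariantAnnotation, config: FilterConfig) -> list[str]:
    flags = []
    if passes_impact(ann, config) == PASS_FLAGGED_UNSCORED:
        flags.append("unscored_cadd")
    return flags
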