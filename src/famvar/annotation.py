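"""Per-variant annotations: population allele frequencies and CADD.

Annotations are consumed from a sidecar TSV rather than queried live, so a
run is reproducible against a pinned table version.  Frequency columns are
named ``af_<cohort>_<population>`` (cohort ``exomes`` or ``genomes``); the
schema is population-agnostic and unknown populations are preserved.

"MAF" here is the alternate-allele frequency — at the rare-variant
thresholds this pipeline uses the two notions coincide; a frequency above
0.5 is folded to ``1 - f`` with a warning.

CADD Phred scores are binned into impact tiers: tier I (>= 30, roughly the
top 0.1% most deleterious possible substitutions), tier II (20-30, top 1%),
tier III (< 20).  Variants without a score (e.g. some indels) are
``unscored`` rather than silently assigned a tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO

import pandas as pd

__all__ = [
    "PopulationFrequencies",
    "VariantAnnotation",
    "AnnotationError",
    "load_annotation_table",
    "max_population_maf",
    "cadd_tier",
]

SiteKey = tuple[str, int, str, str]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationFrequencies:
    cohort: str  # "exomes" | "genomes"
    frequencies: tuple[tuple[str, float], ...]  # (population, allele frequency)
    homozygote_count: int | None = None

    def __post_init__(self) -> None:
        for pop, f in self.frequencies:
            if not 0.0 <= f <= 1.0:
                raise AnnotationError(f"frequency {f} for {self.cohort}/{pop} outside [0,1]")


@dataclass(frozen=True)
class VariantAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str = ""
    transcript: str = ""
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    consequence: str = ""
    frequencies: tuple[PopulationFrequencies, ...] = ()
    cadd_phred: float | None = None
    extra: tuple[tuple[str, str], ...] = ()

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def nhomalt(self) -> int | None:
        counts = [f.homozygote_count for f in self.frequencies if f.homozygote_count is not None]
        return sum(counts) if counts else None


_FIXED_COLS = {
    "chrom", "pos", "ref", "alt", "gene", "transcript",
    "hgvs_c", "hgvs_p", "consequence", "nhomalt", "cadd_phred",
}


def load_annotation_table(tsv: IO[str] | str) -> dict[SiteKey, VariantAnnotation]:
    """Load an annotation TSV keyed by (chrom, pos, ref, alt).

    Frequency columns follow ``af_<cohort>_<population>``; blank cells mean
    "no record".  Duplicate site keys are a hard error.  Columns outside the
    schema are preserved in ``extra``.
    """
    df = pd.read_csv(tsv, sep="\t", dtype=str, comment=None)
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    extra_cols = [c for c in df.columns if c not in _FIXED_COLS and c not in af_cols]
    out: dict[SiteKey, VariantAnnotation] = {}
    for _, row in df.iterrows():
        key: SiteKey = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            raise AnnotationError(f"duplicate annotation key {key}")
        per_cohort: dict[str, list[tuple[str, float]]] = {}
        for col in af_cols:
            val = row.get(col)
            if pd.isna(val) or val == "":
                continue
            _, cohort, pop = col.split("_", 2)
            f = float(val)
            if f > 0.5:
                warnings.warn(
                    f"allele frequency {f} > 0.5 at {key}; folding to minor allele",
                    stacklevel=2,
                )
                f = 1.0 - f
            per_cohort.setdefault(cohort, []).append((pop, f))
        nhom = row.get("nhomalt")
        nhom_i = None if pd.isna(nhom) or nhom in ("", None) else int(float(nhom))
        freqs = tuple(
            PopulationFrequencies(
                cohort=c,
                frequencies=tuple(pops),
                # attach the (cohort-agnostic) homozygote count once
                homozygote_count=nhom_i if i == 0 else None,
            )
            for i, (c, pops) in enumerate(sorted(per_cohort.items()))
        )
        if not freqs and nhom_i is not None:
            freqs = (PopulationFrequencies("exomes", (), homozygote_count=nhom_i),)
        cadd_raw = row.get("cadd_phred")
        cadd = None if pd.isna(cadd_raw) or cadd_raw == "" else float(cadd_raw)
        out[key] = VariantAnnotation(
            chrom=key[0],
            pos=key[1],
            ref=key[2],
            alt=key[3],
            gene_symbol="" if pd.isna(row.get("gene")) else str(row.get("gene", "")),
            transcript="" if pd.isna(row.get("transcript")) else str(row.get("transcript", "")),
            hgvs_c=None if pd.isna(row.get("hgvs_c")) else row.get("hgvs_c"),
            hgvs_p=None if pd.isna(row.get("hgvs_p")) else row.get("hgvs_p"),
            consequence="" if pd.isna(row.get("consequence")) else str(row.get("consequence", "")),
            frequencies=freqs,
            cadd_phred=cadd,
            extra=tuple(
                (c, "" if pd.isna(row[c]) else str(row[c])) for c in extra_cols
            ),
        )
    return out


def max_population_maf(ann: VariantAnnotation) -> float:
    """Maximum allele frequency over all populations of all cohorts (0 if none)."""
    best = 0.0
    for cohort in ann.frequencies:
        for _, f in cohort.frequencies:
            best = max(best, f)
    return best


def cadd_tier(cadd_phred: float | None) -> str:
    """Impact tier for a Phred-scaled CADD score: I (>=30), II ([20,30)), III (<20)."""
    if cadd_phred is None:
        return "unscored"
    if cadd_phred < 0:
        raise AnnotationError(f"negative CADD score {cadd_phred}")
    if cadd_phred >= 30:
        return "I"
    if cadd_phred >= 20:
        return "II"
    return "III"
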