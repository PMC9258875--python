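"""Packaged study fixtures.

Three small tables transcribed from the published study of 19 multiplex
left-sided CHD families, plus a per-family outcome table:

* ``chd_families.ped`` — the sequenced subjects and their phenotypes, one
  pedigree per family.
* ``chd_candidates.tsv`` — the reported candidate variants with their
  maximum population allele frequency and CADD Phred score.  Genomic
  coordinates in this table are synthetic placeholders (the study reports
  transcript-level HGVS only); variant identity is carried by
  gene/transcript/HGVS.
* ``gene_evidence.tsv`` — gene-level evidence (human CHD reports, mouse
  models, cardiac-development roles) backing the prioritization classes.
* ``family_outcomes.tsv`` — per-family classification (causative variant
  established / candidate only / none) used for the diagnostic yield.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation import VariantAnnotation, load_annotation_table
from .evaluation import GeneEvidence, load_gene_evidence
from .pedigree import Pedigree, parse_pedigrees

__all__ = [
    "load_study_pedigrees",
    "load_study_candidates",
    "load_study_gene_evidence",
    "load_study_outcomes",
]


def _read_text(name: str) -> str:
    return (resources.files("famvar") / "data" / name).read_text()


def load_study_pedigrees() -> dict[str, Pedigree]:
    """The 19 family pedigrees (47 sequenced subjects)."""
    return parse_pedigrees(_read_text("chd_families.ped"))


def load_study_candidates() -> dict[tuple[str, int, str, str], VariantAnnotation]:
    """The 11 reported candidate variants as an annotation table."""
    import io

    return load_annotation_table(io.StringIO(_read_text("chd_candidates.tsv")))


def load_study_candidates_df() -> pd.DataFrame:
    """Raw candidate table (keeps the family and causative columns)."""
    import io

    return pd.read_csv(io.StringIO(_read_text("chd_candidates.tsv")), sep="\t", dtype=str)


def load_study_gene_evidence() -> dict[str, GeneEvidence]:
    import io

    return load_gene_evidence(io.StringIO(_read_text("gene_evidence.tsv")))


def study_callset() -> list:
    """Reconstruct per-family genotype calls for the candidate variants.

    Each reported candidate was heterozygous in every sequenced affected
    member of its family; members of other families are homozygous
    reference.  Depths are nominal (50x).  This yields a callset on which
    the whole pipeline can run against the packaged tables.
    """
    from .variants import GenotypeCall, VariantSite

    peds = load_study_pedigrees()
    df = load_study_candidates_df()
    records = []
    for _, row in df.iterrows():
        site = VariantSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        fam = row["family"]
        calls = {}
        for ped in peds.values():
            for m in ped:
                if not m.sequenced:
                    continue
                if ped.family_id == fam and m.affection == "affected":
                    alleles, ad = ("ref", "alt"), (25, 25)
                else:
                    alleles, ad = ("ref", "ref"), (50, 0)
                calls[m.individual_id] = GenotypeCall(
                    sample_id=m.individual_id, alleles=alleles,
                    total_depth=50, allele_depths=ad,
                )
        records.append((site, calls))
    return records


def load_study_outcomes() -> dict[str, str]:
    """Per-family outcome: causative / candidate_only / none."""
    import io

    df = pd.read_csv(io.StringIO(_read_text("family_outcomes.tsv")), sep="\t", dtype=str)
    return dict(zip(df["family"], df["outcome"]))
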