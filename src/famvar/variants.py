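"""Variant callset model: normalized biallelic sites with per-sample calls.

Reading goes through :mod:`cyvcf2`; multi-allelic records are split into one
site per alternate allele, with genotypes recoded against that alternate
(an allele matching a *different* alternate is recoded as ref for the split
site — the haplotype's identity is preserved jointly across the split
records, see tests).  Inputs are assumed caller-normalized; no left
alignment or trimming is performed beyond the split.  Half-calls such as
``0/.`` are treated as fully missing.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from cyvcf2 import VCF

__all__ = ["VariantSite", "GenotypeCall", "CallsetError", "read_callset", "write_vcf"]

REF = "ref"
ALT = "alt"
MISSING = "missing"


class CallsetError(ValueError):
    """Raised for malformed variant input."""


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CallsetError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CallsetError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    alleles: tuple[str, str]  # values from {ref, alt, missing}, GT slot order
    total_depth: int | None = None
    allele_depths: tuple[int, int] | None = None  # (ref reads, alt reads)

    def __post_init__(self) -> None:
        for a in self.alleles:
            if a not in (REF, ALT, MISSING):
                raise CallsetError(f"invalid allele state {a!r}")
        if self.allele_depths is not None and self.total_depth is not None:
            if sum(self.allele_depths) > self.total_depth:
                raise CallsetError(
                    f"allele depths {self.allele_depths} exceed total depth "
                    f"{self.total_depth} for {self.sample_id}"
                )

    @property
    def is_missing(self) -> bool:
        return MISSING in self.alleles

    @property
    def n_alt(self) -> int | None:
        """Alternate-allele dosage, or None for missing/half calls."""
        if self.is_missing:
            return None
        return self.alleles.count(ALT)

    @property
    def alt_reads(self) -> int | None:
        return None if self.allele_depths is None else self.allele_depths[1]


def _recode(gt_idx: int | None, alt_index: int) -> str:
    if gt_idx is None or gt_idx < 0:
        return MISSING
    if gt_idx == alt_index:
        return ALT
    return REF


def read_callset(
    vcf_source: str | os.PathLike | IO[str],
) -> list[tuple[VariantSite, dict[str, GenotypeCall]]]:
    """Read a VCF into (site, sample -> call) records, splitting multi-allelics.

    ``vcf_source`` is a path to an uncompressed or bgzipped VCF, or an open
    text handle (spooled to a temporary file for the htslib-backed reader).
    Records are returned in input order; a multi-allelic record yields one
    entry per alternate, consecutively.  A missing GT field is a hard error.
    """
    tmp_path: str | None = None
    if hasattr(vcf_source, "read"):
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(vcf_source.read())
        path = tmp_path
    else:
        path = os.fspath(vcf_source)
    try:
        vcf = VCF(path, gts012=False)
        if "GT" not in {f for f in _format_ids(vcf)}:
            raise CallsetError("VCF has no GT FORMAT field")
        samples = list(vcf.samples)
        out: list[tuple[VariantSite, dict[str, GenotypeCall]]] = []
        for rec in vcf:
            depths = rec.format("DP")
            ads = rec.format("AD")
            for alt_index, alt in enumerate(rec.ALT, start=1):
                site = VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    site_id=None if rec.ID in (None, ".") else rec.ID,
                )
                calls: dict[str, GenotypeCall] = {}
                for si, sample in enumerate(samples):
                    gt = rec.genotypes[si]  # [allele1, allele2, phased]
                    a = (_recode(gt[0], alt_index), _recode(gt[1], alt_index))
                    if MISSING in a:  # half-calls collapse to missing
                        a = (MISSING, MISSING)
                    dp = None
                    if depths is not None and int(depths[si][0]) >= 0:
                        dp = int(depths[si][0])
                    ad = None
                    if ads is not None:
                        row = ads[si]
                        if int(row[0]) >= 0 and len(row) > alt_index and int(row[alt_index]) >= 0:
                            ad = (int(row[0]), int(row[alt_index]))
                    calls[sample] = GenotypeCall(
                        sample_id=sample, alleles=a, total_depth=dp, allele_depths=ad
                    )
                out.append((site, calls))
        return out
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


def _format_ids(vcf: VCF) -> Iterable[str]:
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            yield line[len("##FORMAT=<ID=") :].split(",", 1)[0]


_GT_OUT = {REF: "0", ALT: "1", MISSING: "."}


def write_vcf(
    records: Iterable[tuple[VariantSite, Mapping[str, GenotypeCall]]],
    samples: list[str],
    out: IO[str],
) -> None:
    """Write biallelic records as minimal, deterministic VCF 4.2 text."""
    contigs: list[str] = []
    buffered = list(records)
    for site, _ in buffered:
        if site.chrom not in contigs:
            contigs.append(site.chrom)
    out.write("##fileformat=VCFv4.2\n")
    for c in contigs:
        out.write(f"##contig=<ID={c}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    out.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    )
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    for site, calls in buffered:
        cols = [
            site.chrom,
            str(site.pos),
            site.site_id or ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for s in samples:
            call = calls[s]
            gt = "/".join(_GT_OUT[a] for a in call.alleles)
            dp = "." if call.total_depth is None else str(call.total_depth)
            ad = (
                "."
                if call.allele_depths is None
                else f"{call.allele_depths[0]},{call.allele_depths[1]}"
            )
            cols.append(f"{gt}:{dp}:{ad}")
        out.write("\t".join(cols) + "\n")
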