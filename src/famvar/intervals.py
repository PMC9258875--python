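"""Interval algebra for capture-kit harmonization and coverage breadth.

Coordinates follow BED convention: 0-based, half-open.  VCF positions are
1-based; the conversion happens in exactly one place
(:func:`contains_site`).  An :class:`IntervalSet` is canonical — per
chromosome, intervals are sorted, pairwise disjoint and non-adjacent
(abutting intervals are merged) — so set algebra is a linear sweep.

When several exome capture kits were used across a cohort, variants are
restricted to the bases targeted by *every* kit (:func:`intersect_sets`)
to avoid batch artifacts at kit-specific targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .variants import VariantSite

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "IntervalError",
    "canonicalize",
    "intersect_sets",
    "contains_site",
    "breadth_at_threshold",
    "read_bed",
    "write_bed",
]


class IntervalError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """Canonical per-chromosome interval lists."""

    by_chrom: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def intervals(self) -> Iterable[GenomicInterval]:
        for chrom in sorted(self.by_chrom):
            yield from self.by_chrom[chrom]

    def total_bases(self) -> int:
        return sum(len(iv) for ivs in self.by_chrom.values() for iv in ivs)

    def is_empty(self) -> bool:
        return self.total_bases() == 0

    def pad(self, pad: int) -> "IntervalSet":
        """Symmetrically extend every interval by ``pad`` bp and re-canonicalize."""
        return canonicalize(
            GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad)
            for iv in self.intervals()
        )


def canonicalize(intervals: Iterable[GenomicInterval]) -> IntervalSet:
    """Sort and merge intervals (overlapping or abutting) per chromosome."""
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append(iv)
    out: dict[str, list[GenomicInterval]] = {}
    for chrom, ivs in grouped.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        merged: list[list[int]] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1][1]:  # overlap or abut
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        out[chrom] = [GenomicInterval(chrom, s, e) for s, e in merged]
    return IntervalSet(by_chrom=out)


def _intersect_two(a: list[GenomicInterval], b: list[GenomicInterval], chrom: str) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(GenomicInterval(chrom, lo, hi))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return out


def intersect_sets(sets: list[IntervalSet]) -> IntervalSet:
    """Bases present in *all* input sets (the mutually covered regions)."""
    if not sets:
        raise IntervalError("intersect_sets requires at least one IntervalSet")
    result = {c: list(ivs) for c, ivs in sets[0].by_chrom.items()}
    for other in sets[1:]:
        nxt: dict[str, list[GenomicInterval]] = {}
        for chrom in result:
            if chrom in other.by_chrom:
                hits = _intersect_two(result[chrom], other.by_chrom[chrom], chrom)
                if hits:
                    nxt[chrom] = hits
        result = nxt
    return IntervalSet(by_chrom=result)


def contains_site(regions: IntervalSet, site: VariantSite) -> bool:
    """Whether the site's anchor base (VCF POS, 1-based) lies in the regions.

    Membership is a point test on ``pos - 1``; the REF span of an indel is
    not required to be fully contained.
    """
    import bisect

    ivs = regions.by_chrom.get(site.chrom)
    if not ivs:
        return False
    coord = site.pos - 1
    idx = bisect.bisect_right([iv.start for iv in ivs], coord) - 1
    return idx >= 0 and ivs[idx].start <= coord < ivs[idx].end


def breadth_at_threshold(
    depth_track: Iterable[tuple[GenomicInterval, int]],
    targets: IntervalSet,
    min_depth: int,
) -> float:
    """Fraction of target bases with depth >= ``min_depth``.

    ``depth_track`` gives piecewise-constant depth over disjoint intervals;
    bases absent from the track have depth 0.
    """
    if targets.is_empty():
        raise IntervalError("breadth_at_threshold requires nonempty targets")
    covered = canonicalize(iv for iv, d in depth_track if d >= min_depth)
    if min_depth <= 0:
        return 1.0
    hit = intersect_sets([targets, covered]) if not covered.is_empty() else IntervalSet()
    return hit.total_bases() / targets.total_bases()


def read_bed(stream: IO[str] | str) -> IntervalSet:
    """Read BED3 (track/browser/comment lines ignored) into a canonical set."""
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    ivs = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise IntervalError(f"BED line {lineno}: expected >= 3 columns")
        try:
            ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise IntervalError(f"BED line {lineno}: {exc}") from exc
    return canonicalize(ivs)


def write_bed(regions: IntervalSet, out: IO[str]) -> None:
    for iv in regions.intervals():
        out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
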