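"""Genomic interval algebra.

All intervals here are 0-based half-open ``(start, end)`` on a named
chromosome, the internal convention of the whole package (BED-like).
External formats that are 1-based inclusive (VCF positions, GFF3) are
converted at the I/O boundary, see :mod:`ecodiff.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class Region:
    """A called genomic interval with provenance.

    ``source`` records which scan statistics supported the region
    (e.g. ``{"fst"}``, ``{"fst", "xpclr"}``, ``{"clr_pop1"}``).
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    source: frozenset = frozenset()
    member_snps: list = field(default_factory=list)
    member_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval {self.start}..{self.end}")
        self.source = frozenset(self.source)

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def merge_regions(regions: list[Region], max_gap: int = 0) -> list[Region]:
    """Merge overlapping, book-ended, or nearby intervals.

    Two intervals on the same chromosome are merged when the gap between
    them is at most ``max_gap`` base pairs (gap 0 = overlapping or
    book-ended).  Sources are unioned; member lists concatenated.
    """
    out: list[Region] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == r.chrom and r.start - out[-1].end <= max_gap:
            prev = out[-1]
            out[-1] = replace(
                prev,
                end=max(prev.end, r.end),
                source=prev.source | r.source,
                member_snps=prev.member_snps + r.member_snps,
                member_genes=prev.member_genes + r.member_genes,
            )
        else:
            out.append(replace(r))
    return out


def intersect_regions(a: list[Region], b: list[Region]) -> list[Region]:
    """Pairwise interval intersection of two merged region sets.

    Empty intersections are dropped.  The resulting regions carry the
    union of both parents' sources.
    """
    out: list[Region] = []
    for ra in a:
        for rb in b:
            if ra.overlaps(rb):
                out.append(
                    Region(
                        chrom=ra.chrom,
                        start=max(ra.start, rb.start),
                        end=min(ra.end, rb.end),
                        source=ra.source | rb.source,
                    )
                )
    return sorted(out, key=lambda r: (r.chrom, r.start, r.end))


def point_in_regions(chrom: str, pos0: int, regions: list[Region]) -> bool:
    """Whether a 0-based point falls inside any region."""
    return any(r.chrom == chrom and r.start <= pos0 < r.end for r in regions)


def point_interval_distance(pos0: int, start: int, end: int) -> int:
    """bp distance between a 0-based point and a half-open interval (0 if inside)."""
    if pos0 < start:
        return start - pos0
    if pos0 >= end:
        return pos0 - (end - 1)
    return 0
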