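"""Exact genome mapping of sRNA tags, repeat-locus filtering, and excision of
candidate precursor windows.

Mapping is exact and full-length on both strands — a miRNA candidate must
have a perfect genomic origin.  Tags hitting more genomic loci than
``max_loci`` (default 50) are set aside as likely repeat-associated siRNAs.
Coordinates are 1-based inclusive externally (``scaffold:start.end`` style)
and 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import revcomp
from .preprocess import UniqueTag

logger = logging.getLogger(__name__)

DEFAULT_MAX_LOCI = 50
#: Far-flank lengths tried on each side of a mapped tag; chosen to cover
#: plant pre-miRNA lengths up to the high end of the ~85-283 nt range.
DEFAULT_FLANKS = (100, 170, 250)
#: Near-side pad, so a window brackets a precursor whose mature arm lies
#: within this many nt of the precursor end.
DEFAULT_NEAR_FLANK = 60


@dataclass(frozen=True)
class GenomeHit:
    """One exact, full-length genomic occurrence of a tag."""

    tag: UniqueTag
    scaffold: str
    start: int  # 1-based inclusive, forward axis
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    @property
    def location(self) -> str:
        return f"{self.scaffold}:{self.start}.{self.end}"


@dataclass(frozen=True)
class LocusSet:
    tag: UniqueTag
    hits: tuple[GenomeHit, ...]

    @property
    def n_loci(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class PrecursorWindow:
    """A genomic window excised around a hit, oriented so that the tag
    occurs verbatim (reverse-strand windows are reverse-complemented)."""

    seq: str
    scaffold: str
    start: int  # 1-based inclusive, forward axis
    end: int
    strand: str
    tag_offset: int  # 0-based offset of the tag within ``seq``


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def map_tags(
    tags: Sequence[UniqueTag], genome: Mapping[str, str]
) -> list[LocusSet]:
    """Report every exact occurrence of each tag on both genome strands.

    Reverse-strand hits carry forward-axis coordinates (the interval the
    tag's reverse complement occupies on the plus strand).
    """
    out = []
    for tag in tags:
        hits: list[GenomeHit] = []
        for name, seq in genome.items():
            for pos in _find_all(seq, tag.seq):
                hits.append(GenomeHit(tag, name, pos + 1, pos + tag.length, "+"))
            rc = revcomp(tag.seq)
            for pos in _find_all(seq, rc):
                if rc == tag.seq and any(
                    h.scaffold == name and h.start == pos + 1 and h.strand == "+"
                    for h in hits
                ):
                    continue  # palindromic tag: same locus, count once
                hits.append(GenomeHit(tag, name, pos + 1, pos + tag.length, "-"))
        out.append(LocusSet(tag, tuple(sorted(
            hits, key=lambda h: (h.scaffold, h.start, h.strand)
        ))))
    return out


def filter_repeats(
    locus_sets: Sequence[LocusSet], max_loci: int = DEFAULT_MAX_LOCI
) -> tuple[list[LocusSet], list[LocusSet]]:
    """Partition locus sets into (kept, excluded) by the repeat-locus rule:
    a tag hitting more than ``max_loci`` genomic loci is excluded."""
    kept = [ls for ls in locus_sets if ls.n_loci <= max_loci]
    excluded = [ls for ls in locus_sets if ls.n_loci > max_loci]
    if excluded:
        logger.info(
            "repeat filter: excluded %d of %d tags (> %d loci)",
            len(excluded), len(locus_sets), max_loci,
        )
    return kept, excluded


def excise_windows(
    hit: GenomeHit,
    genome: Mapping[str, str],
    flank_lengths: Sequence[int] = DEFAULT_FLANKS,
    near_flank: int = DEFAULT_NEAR_FLANK,
) -> list[PrecursorWindow]:
    """Excise candidate precursor windows around a genomic hit.

    For each far-flank length F two asymmetric windows are produced,
    [start - F, end + near] and [start - near, end + F], so the mature arm
    may sit near either precursor end.  Windows are clipped to scaffold
    bounds; reverse-strand windows are reverse-complemented so the tag reads
    verbatim.  Windows shorter than the tag are skipped.
    """
    if any(f <= 0 for f in flank_lengths):
        raise ValueError("flank lengths must be positive")
    scaffold = genome[hit.scaffold]
    s0, e0 = hit.start - 1, hit.end  # 0-based half-open
    windows = []
    seen = set()
    for f in flank_lengths:
        for up, down in ((f, near_flank), (near_flank, f)):
            lo = max(0, s0 - up)
            hi = min(len(scaffold), e0 + down)
            if hi - lo < e0 - s0:
                logger.debug("window at %s too short; skipped", hit.location)
                continue
            if (lo, hi) in seen:
                continue
            seen.add((lo, hi))
            seq = scaffold[lo:hi]
            if hit.strand == "-":
                seq = revcomp(seq)
                offset = hi - e0
            else:
                offset = s0 - lo
            windows.append(
                PrecursorWindow(seq, hit.scaffold, lo + 1, hi, hit.strand, offset)
            )
    return windows
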