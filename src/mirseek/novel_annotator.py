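"""Class A/B/C annotation of novel miRNA candidates.

Candidates surviving the repeat filter and hairpin/duplex validation are
tiered by the strength of their evidence: Class A candidates have their star
(passenger) strand sequenced in the same library — the expression/biogenesis
gold standard; Class B candidates lack a star but were sequenced at least
``min_reads_b`` times (default 5); Class C candidates are rare tags with
neither form of support and are retained but flagged non-reportable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .known_profiler import KnownMatch, _align
from .preprocess import UniqueTag

DEFAULT_MIN_READS_B = 5
STAR_END_SHIFT = 2

TABLE_COLUMNS = [
    "csa-MIR",
    "Location",
    "Orientation",
    "Abundance",
    "Sequence",
    "Length (nt)",
    "Hairpin Length (nt)",
    "Minimum Free Energy",
    "Class",
    "miRNA*",
]


@dataclass(frozen=True)
class NovelAnnotation:
    """One Table-style row describing a novel miRNA candidate locus."""

    candidate_id: str
    scaffold: str
    start: int  # 1-based inclusive, mature arm on the forward axis
    end: int
    orientation: str
    abundance: int
    mature_seq: str
    hairpin_len: int
    energy: float
    class_label: str
    star_seq: str | None = None
    star_count: int = 0

    @property
    def location(self) -> str:
        return f"{self.scaffold}:{self.start}.{self.end}"

    @property
    def mature_len(self) -> int:
        return len(self.mature_seq)


def assign_class(abundance: int, star_count: int, min_reads_b: int = DEFAULT_MIN_READS_B) -> str:
    """Tier a candidate: A if the star strand was sequenced, else B when the
    mature tag reached ``min_reads_b`` reads, else C.  Star evidence dominates
    abundance."""
    if abundance < 1:
        raise ValueError("abundance must be at least 1")
    if star_count >= 1:
        return "A"
    return "B" if abundance >= min_reads_b else "C"


def find_star_reads(
    star_seq: str,
    tags: Sequence[UniqueTag],
    end_shift: int = STAR_END_SHIFT,
) -> int:
    """Summed counts of tags matching the predicted star sequence within
    +/- ``end_shift`` nt end variation (no internal mismatches)."""
    total = 0
    for tag in tags:
        if _align(tag.seq, star_seq, end_shift, max_mismatch=0) is not None:
            total += tag.count
    return total


def exclude_known(
    candidates: Sequence[NovelAnnotation], known_matches: Sequence[KnownMatch]
) -> list[NovelAnnotation]:
    """Drop candidates whose mature tag matched any known miRNA family."""
    known_seqs = {m.tag.seq for m in known_matches}
    return [c for c in candidates if c.mature_seq not in known_seqs]


def name_candidates(
    annotations: Sequence[NovelAnnotation], prefix: str = "cand"
) -> list[NovelAnnotation]:
    """Assign deterministic ids; loci sharing a mature sequence share a stem
    id with ``_1``, ``_2`` locus suffixes."""
    ordered = sorted(annotations, key=lambda a: (a.scaffold, a.start))
    stems: dict[str, int] = {}
    for ann in ordered:
        if ann.mature_seq not in stems:
            stems[ann.mature_seq] = len(stems) + 1
    n_loci = {seq: sum(1 for a in ordered if a.mature_seq == seq) for seq in stems}
    seen: dict[str, int] = {}
    out = []
    for ann in ordered:
        stem = f"{prefix}-{stems[ann.mature_seq]}"
        if n_loci[ann.mature_seq] > 1:
            seen[ann.mature_seq] = seen.get(ann.mature_seq, 0) + 1
            stem = f"{stem}_{seen[ann.mature_seq]}"
        out.append(replace(ann, candidate_id=stem))
    return out


def report_table(
    annotations: Sequence[NovelAnnotation], include_class_c: bool = False
) -> pd.DataFrame:
    """Novel-candidate report with deterministic (scaffold, start) row order.

    Class C rows are withheld by default: only A and B candidates carry
    enough evidence to report, though all remain available upstream.
    """
    rows = []
    for ann in sorted(annotations, key=lambda a: (a.scaffold, a.start)):
        if ann.class_label == "C" and not include_class_c:
            continue
        star = f"{ann.star_seq}({ann.star_count})" if ann.star_count else "NO"
        rows.append(
            {
                "csa-MIR": ann.candidate_id,
                "Location": ann.location,
                "Orientation": ann.orientation,
                "Abundance": ann.abundance,
                "Sequence": ann.mature_seq,
                "Length (nt)": ann.mature_len,
                "Hairpin Length (nt)": ann.hairpin_len,
                "Minimum Free Energy": round(ann.energy, 2),
                "Class": ann.class_label,
                "miRNA*": star,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
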