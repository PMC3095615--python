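"""Identification of known miRNA families among unique tags.

A tag is credited to a reference mature miRNA when, under ungapped anchoring,
each of its ends extends or recedes at most ``end_shift`` nt (default 2,
the canonical-length +/- 2 rule) relative to the reference and the
overlapping core carries at most ``max_mismatch`` mismatches (default 0).
A tag matching several families is credited to every one and flagged
ambiguous — near-identical families (the miR165/miR166 situation) are never
silently arbitrated.  Conservation status is reference metadata, not a
computed quantity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import normalize_seq, read_fasta
from .preprocess import UniqueTag

DEFAULT_END_SHIFT = 2


@dataclass(frozen=True)
class MatureRef:
    """A reference mature miRNA with family/species/conservation metadata."""

    family: str
    species: str
    seq: str
    conserved: bool


@dataclass(frozen=True)
class KnownMatch:
    tag: UniqueTag
    family: str
    ref_seq: str
    end_shift_5p: int  # tag 5' end relative to reference 5' end (+ = extends)
    end_shift_3p: int
    mismatches: int
    ambiguous: bool = False


def read_reference(path: str | Path) -> list[MatureRef]:
    """Load a mature-miRNA reference FASTA.

    Header convention: ``>family|species|conserved={0,1}``; missing fields
    default to species ``?`` and conserved.
    """
    refs = []
    for name, seq in read_fasta(path):
        parts = name.split("|")
        family = parts[0]
        species = parts[1] if len(parts) > 1 else "?"
        conserved = True
        for part in parts[2:]:
            if part.startswith("conserved="):
                conserved = part.split("=", 1)[1] not in ("0", "false", "False")
        refs.append(MatureRef(family, species, seq, conserved))
    return refs


def _align(tag_seq: str, ref_seq: str, end_shift: int, max_mismatch: int):
    """Best (fewest-mismatch) admissible ungapped anchoring, or None.

    Anchorings place the tag 5' end at offset d in [-end_shift, end_shift]
    relative to the reference 5' end; the 3' shift follows from the lengths
    and must also be within +/- end_shift.
    """
    best = None
    for d in range(-end_shift, end_shift + 1):
        shift_3p = len(tag_seq) + d - len(ref_seq)
        if abs(shift_3p) > end_shift:
            continue
        # overlap of tag positions i with ref positions i + d
        lo = max(0, -d)
        hi = min(len(tag_seq), len(ref_seq) - d)
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if tag_seq[i] != ref_seq[i + d])
        if mm <= max_mismatch and (best is None or mm < best[2]):
            best = (-d, shift_3p, mm)
    return best


def match_known(
    tags: Sequence[UniqueTag],
    refs: Sequence[MatureRef],
    max_mismatch: int = 0,
    end_shift: int = DEFAULT_END_SHIFT,
) -> list[KnownMatch]:
    """Match tags against reference mature miRNAs under the +/- 2-nt rule."""
    if not refs:
        raise ValueError("reference set must be non-empty")
    norm_refs = [(r, normalize_seq(r.seq)) for r in refs]
    matches: list[KnownMatch] = []
    for tag in tags:
        per_tag: dict[str, KnownMatch] = {}
        for ref, ref_seq in norm_refs:
            hit = _align(tag.seq, ref_seq, end_shift, max_mismatch)
            if hit is None:
                continue
            s5, s3, mm = hit
            prev = per_tag.get(ref.family)
            if prev is None or mm < prev.mismatches:
                per_tag[ref.family] = KnownMatch(tag, ref.family, ref_seq, s5, s3, mm)
        ambiguous = len(per_tag) > 1
        for m in per_tag.values():
            matches.append(
                KnownMatch(m.tag, m.family, m.ref_seq, m.end_shift_5p,
                           m.end_shift_3p, m.mismatches, ambiguous)
            )
    return matches


@dataclass(frozen=True)
class FamilySummary:
    family: str
    conserved: bool
    size_range: tuple[int, int]
    five_prime_mode: str  # e.g. "U (68%)" or "A/G (50%)"
    total_reads: int
    n_tags: int


def _five_prime_mode(tags: Sequence[UniqueTag]) -> str:
    weights: dict[str, int] = defaultdict(int)
    for tag in tags:
        first = tag.seq[0].replace("T", "U")
        weights[first] += tag.count
    top = max(weights.values())
    winners = sorted(nt for nt, w in weights.items() if w == top)
    pct = round(100 * top / sum(weights.values()))
    return f"{'/'.join(winners)} ({pct}%)"


def summarize_families(
    matches: Sequence[KnownMatch], refs: Sequence[MatureRef]
) -> list[FamilySummary]:
    """Per-family size range, count-weighted 5'-nucleotide mode, total reads."""
    conserved_by_family = {r.family: r.conserved for r in refs}
    by_family: dict[str, dict[str, UniqueTag]] = defaultdict(dict)
    for m in matches:
        by_family[m.family][m.tag.seq] = m.tag
    out = []
    for family in sorted(by_family):
        tags = list(by_family[family].values())
        lengths = [t.length for t in tags]
        out.append(
            FamilySummary(
                family=family,
                conserved=conserved_by_family.get(family, True),
                size_range=(min(lengths), max(lengths)),
                five_prime_mode=_five_prime_mode(tags),
                total_reads=sum(t.count for t in tags),
                n_tags=len(tags),
            )
        )
    return out


def count_family_classes(summaries: Sequence[FamilySummary]) -> tuple[int, int]:
    """(number of conserved, number of non-conserved) families."""
    n_cons = sum(1 for s in summaries if s.conserved)
    return n_cons, len(summaries) - n_cons


def summaries_to_frame(summaries: Sequence[FamilySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [s.family for s in summaries],
            "conserved": [int(s.conserved) for s in summaries],
            "size_range": [f"{s.size_range[0]}-{s.size_range[1]}" for s in summaries],
            "five_prime_end": [s.five_prime_mode for s in summaries],
            "total_reads": [s.total_reads for s in summaries],
            "n_tags": [s.n_tags for s in summaries],
        }
    )
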