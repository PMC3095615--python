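"""Read cleaning, collapsing, and library profiling.

A raw 454-style sRNA library is adapter-trimmed, purged of structural-RNA
fragments (rRNA/tRNA/snRNA/snoRNA), length-filtered to the analysis window
(18-30 nt by default), and collapsed to unique tags with read counts.  The
size/redundancy profile summarises, per read length, how many distinct
sequences (non-redundant) and how many total reads (redundant) were seen;
their ratio is the redundancy at that length — high values mean few, highly
expressed species.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import normalize_seq, revcomp

logger = logging.getLogger(__name__)

MIN_LEN = 18
MAX_LEN = 30


@dataclass(frozen=True, order=True)
class UniqueTag:
    """A distinct sRNA sequence with its library read count."""

    seq: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("tag count must be positive")

    @property
    def length(self) -> int:
        return len(self.seq)


def trim_adapters(
    reads: Iterable[str], adapter_3p: str, min_overlap: int = 6
) -> list[str]:
    """Trim a 3' adapter by its leftmost suffix-prefix match.

    Each read is truncated at the leftmost position where its suffix matches
    a prefix of the adapter over at least ``min_overlap`` bases; reads with
    no such match are returned untouched.  Reads left empty are dropped.
    """
    if not adapter_3p:
        raise ValueError("adapter sequence must be non-empty when trimming")
    adapter = normalize_seq(adapter_3p)
    out = []
    n_dropped = 0
    for read in reads:
        read = normalize_seq(read)
        trimmed = read
        for pos in range(len(read) - min_overlap + 1):
            k = min(len(read) - pos, len(adapter))
            if k >= min_overlap and read[pos : pos + k] == adapter[:k]:
                trimmed = read[:pos]
                break
        if trimmed:
            out.append(trimmed)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("adapter trimming dropped %d empty reads", n_dropped)
    return out


def filter_structural_rna(
    tags: Sequence[UniqueTag], exclusion_db: Mapping[str, str] | None
) -> list[UniqueTag]:
    """Remove tags contained (either strand) in any exclusion-db sequence.

    The database holds rRNA/tRNA/snRNA/snoRNA reference sequences; matching
    is exact substring containment of the tag.
    """
    if not exclusion_db:
        return list(tags)
    db = [normalize_seq(s) for s in exclusion_db.values()]
    kept = []
    n_removed = 0
    for tag in tags:
        rc = revcomp(tag.seq)
        if any(tag.seq in ref or rc in ref for ref in db):
            n_removed += 1
        else:
            kept.append(tag)
    logger.info("structural-RNA filter removed %d of %d tags", n_removed, len(tags))
    return kept


def length_filter(
    tags: Sequence[UniqueTag], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> list[UniqueTag]:
    return [t for t in tags if min_len <= t.length <= max_len]


def collapse(reads: Iterable[str | tuple[str, int]]) -> list[UniqueTag]:
    """Collapse reads (or pre-counted (seq, count) pairs) into unique tags.

    Output is sorted by count descending, then sequence ascending; counts
    sum to the number of input reads.
    """
    counter: Counter[str] = Counter()
    for item in reads:
        if isinstance(item, tuple):
            seq, count = item
            counter[normalize_seq(seq)] += count
        else:
            counter[normalize_seq(item)] += 1
    return [
        UniqueTag(seq, count)
        for seq, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def size_profile(
    tags: Sequence[UniqueTag], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> pd.DataFrame:
    """Per-length unique/redundant counts and redundancy ratios.

    Returns a DataFrame indexed by length with columns ``unique``,
    ``redundant`` and ``ratio`` (redundant/unique, NaN where no tags).
    """
    lengths = range(min_len, max_len + 1)
    unique = {length: 0 for length in lengths}
    redundant = {length: 0 for length in lengths}
    for tag in tags:
        if min_len <= tag.length <= max_len:
            unique[tag.length] += 1
            redundant[tag.length] += tag.count
    df = pd.DataFrame(
        {"unique": pd.Series(unique), "redundant": pd.Series(redundant)}
    )
    df.index.name = "length"
    df["ratio"] = df["redundant"] / df["unique"]
    return df


def plot_size_profile(profile: pd.DataFrame, path: str) -> None:
    """Bar chart of unique vs redundant counts per length, plus the ratio."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    x = profile.index.to_numpy()
    ax1.bar(x - 0.2, profile["redundant"], width=0.4, color="firebrick",
            label="redundant")
    ax1.bar(x + 0.2, profile["unique"], width=0.4, color="steelblue",
            label="non-redundant")
    ax1.set_xlabel("read length (nt)")
    ax1.set_ylabel("sequences")
    ax1.legend()
    ax2.bar(x, profile["ratio"], color="grey")
    ax2.set_xlabel("read length (nt)")
    ax2.set_ylabel("redundancy ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
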