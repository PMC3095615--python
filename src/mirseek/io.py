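"""FASTA input/output helpers.

Small-RNA libraries are exchanged either as raw read FASTA (one record per
sequenced read) or in the collapsed convention where the read count is encoded
in the header, ``>tag42_x17`` meaning the sequence was seen 17 times.  All
sequences are normalised to uppercase DNA (U -> T) at ingest.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COUNT_RE = re.compile(r"_x(\d+)$")

_RC = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet."""
    return str(seq).upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def parse_count(header: str) -> int:
    """Read count from a collapsed-FASTA header (``..._x<count>``), else 1."""
    m = _COUNT_RE.search(header.split()[0])
    return int(m.group(1)) if m else 1


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, normalised sequence) pairs."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, normalize_seq(str(rec.seq))


def read_reads(path: str | Path) -> list[tuple[str, int]]:
    """Read a (possibly collapsed) sRNA FASTA into (sequence, count) pairs.

    Counts from ``_x<count>`` headers are honoured; duplicate sequences are
    NOT merged here (that is :func:`mirseek.preprocess.collapse`'s job).
    """
    return [(seq, parse_count(name)) for name, seq in read_fasta(path)]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(recs, str(path), "fasta-2line")


def write_collapsed(path: str | Path, tags: Iterable[tuple[str, int]]) -> None:
    """Write (sequence, count) pairs in the ``>tag<i>_x<count>`` convention."""
    write_fasta(
        path,
        ((f"tag{i}_x{count}", seq) for i, (seq, count) in enumerate(tags, start=1)),
    )
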