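"""Bundled reference tables of the cucumber analysis, used as fixtures.

Two curated tables ship with the package: the known miRNA family profile
(25 families with conservation status, tag size range and 5'-nucleotide
mode) and the novel-candidate annotation table (7 loci with coordinates,
abundance, hairpin metrics, Class A/B label and, where sequenced, the
miRNA* sequence with its read count).  They serve as regression anchors:
class assignment, family partitioning and table statistics are checked
against them.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

_FILES = {
    "table1": "table1_known_families.tsv",
    "table2": "table2_novel_mirnas.tsv",
}

_STAR_RE = re.compile(r"^([ACGTUN]+)\((\d+)\)$")


def _parse_number(x):
    if isinstance(x, str):
        x = x.replace("−", "-")  # unicode minus
    return float(x)


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged fixture (``"table1"`` or ``"table2"``) as a typed frame.

    table1 columns: family, conserved (bool), size_min, size_max,
    five_prime_end.  table2 columns: id, location, orientation, abundance,
    sequence, length_nt, hairpin_length_nt, mfe (float), class, star, plus
    parsed star_seq / star_count.
    """
    if table_id not in _FILES:
        raise ValueError(f"unknown fixture {table_id!r}; expected one of {sorted(_FILES)}")
    with resources.files("mirseek.data").joinpath(_FILES[table_id]).open() as fh:
        df = read_table(fh, table_id)
    return df


def read_table(path_or_buf, table_id: str) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, comment="#")
    try:
        if table_id == "table1":
            df["conserved"] = df["conserved"].astype(int).astype(bool)
            df["size_min"] = df["size_min"].astype(int)
            df["size_max"] = df["size_max"].astype(int)
        else:
            df["abundance"] = df["abundance"].astype(int)
            df["length_nt"] = df["length_nt"].astype(int)
            df["hairpin_length_nt"] = df["hairpin_length_nt"].astype(int)
            df["mfe"] = df["mfe"].map(_parse_number)
            stars = df["star"].map(_parse_star)
            df["star_seq"] = [s for s, _ in stars]
            df["star_count"] = [c for _, c in stars]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed {table_id} fixture: {exc}") from exc
    return df


def _parse_star(cell: str) -> tuple[str | None, int]:
    if cell in ("NO", "", "nan"):
        return None, 0
    m = _STAR_RE.match(cell)
    if not m:
        raise ValueError(f"unparseable miRNA* cell {cell!r}")
    return m.group(1), int(m.group(2))


def write_fixture(df: pd.DataFrame, path: str | Path, table_id: str) -> None:
    """Write a fixture frame back to TSV in its packaged column layout
    (round-trips through :func:`read_table`)."""
    cols = (
        ["family", "conserved", "size_min", "size_max", "five_prime_end"]
        if table_id == "table1"
        else ["id", "location", "orientation", "abundance", "sequence",
              "length_nt", "hairpin_length_nt", "mfe", "class", "star"]
    )
    out = df.copy()
    if table_id == "table1":
        out["conserved"] = out["conserved"].astype(int)
    else:
        out["mfe"] = out["mfe"].map(lambda v: f"{v:.2f}")
    out[cols].to_csv(path, sep="\t", index=False)
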