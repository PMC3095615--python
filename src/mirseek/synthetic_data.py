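"""Synthetic genomes and sRNA read populations with planted ground truth.

The generator emulates the statistical structure a plant sRNA discovery run
assumes: a multi-scaffold genome; MIR loci whose excised precursor folds
into a single stem-loop holding a mature/miRNA* duplex with 2-nt 3'
overhangs; a high-copy repeat family whose 24-nt reads multi-map far past
the repeat-locus threshold; and a degradation background of reads sampled
from random genomic positions with a 24-nt-dominated length distribution.

Every planted feature is recorded in a truth table so downstream stages can
be scored exactly (recovery, repeat exclusion, hairpin-length error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import revcomp, write_collapsed, write_fasta

logger = logging.getLogger(__name__)

#: Unique-read length distribution over 18-30 nt, 24-nt dominated as is
#: typical for plant sRNA libraries (heterochromatic siRNA background).
DEFAULT_LENGTH_DIST: dict[int, float] = {
    18: 0.03, 19: 0.04, 20: 0.05, 21: 0.09, 22: 0.10, 23: 0.10, 24: 0.51,
    25: 0.03, 26: 0.02, 27: 0.01, 28: 0.01, 29: 0.005, 30: 0.005,
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: bases that neither Watson-Crick pair nor G:U wobble with the key
_NON_PAIRING = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}


class PlacementError(ValueError):
    """Genome too short to place all loci without overlap."""


@dataclass(frozen=True)
class PlantedMir:
    """Ground truth for one planted MIR locus (coordinates 1-based,
    forward axis; ``start``/``end`` delimit the mature arm)."""

    mature_seq: str
    star_seq: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    mature_count: int
    star_count: int
    loop_len: int
    arm: str  # '5p' or '3p' - which precursor arm holds the mature miRNA
    precursor_seq: str
    precursor_start: int
    precursor_end: int

    @property
    def precursor_len(self) -> int:
        return len(self.precursor_seq)


@dataclass(frozen=True)
class RepeatFamily:
    unit_seq: str
    loci: tuple[tuple[str, int], ...]  # (scaffold, 1-based start)
    tags: tuple[tuple[str, int], ...]  # (24-nt tag sequence, read count)


@dataclass(frozen=True)
class SimTruth:
    mirs: tuple[PlantedMir, ...]
    repeat: RepeatFamily | None


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    genome_len: int = 100_000
    n_scaffolds: int = 4
    gc: float = 0.36
    n_planted: int = 10
    repeat_copies: int = 60
    background_reads: int = 2000
    length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    seed: int = 0
    # generator knobs
    n_duplex_mismatches: int = 2
    loop_len: int = 15
    lower_stem_range: tuple[int, int] = (25, 60)
    mature_count_range: tuple[int, int] = (5, 40)
    star_count_range: tuple[int, int] = (1, 8)
    repeat_unit_len: int = 90
    n_repeat_tags: int = 5

    def validate(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction in [0, 1]")
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"length_dist probabilities sum to {total}, not 1")
        if any(not 18 <= k <= 30 for k in self.length_dist):
            raise ValueError("length_dist support must lie within [18, 30]")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        if min(self.n_planted, self.repeat_copies, self.background_reads) < 0:
            raise ValueError("counts must be non-negative")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _build_precursor(rng: np.random.Generator, cfg: SimConfig):
    """Construct one stem-loop precursor with a valid mature/star duplex.

    Layout (mature on the 5' arm):  ext5 . mature . loop . star . ext3
    where star position L-3-k complements mature position k (2-nt 3'
    overhangs on both arms), ``n_duplex_mismatches`` interior star bases are
    mutated to non-pairing ones, the loop is drawn from {A, C} so it cannot
    base-pair internally, and ext3 = revcomp(ext5) forms the lower stem.
    """
    mature_len = int(rng.choice([20, 21, 22, 23, 24], p=[0.15, 0.45, 0.2, 0.12, 0.08]))
    mature = _random_seq(rng, mature_len, cfg.gc)
    star = list("N" * mature_len)
    for k in range(mature_len - 2):
        star[mature_len - 3 - k] = _COMP[mature[k]]
    star[-2] = str(rng.choice(list("ACGT")))
    star[-1] = str(rng.choice(list("ACGT")))
    # knock out interior duplex positions (keep both duplex ends intact)
    interior = np.arange(4, mature_len - 6)
    for k in rng.choice(interior, size=cfg.n_duplex_mismatches, replace=False):
        star[mature_len - 3 - k] = str(rng.choice(list(_NON_PAIRING[mature[k]])))
    star = "".join(star)
    loop = "".join(rng.choice(list("AC"), size=cfg.loop_len))
    ext_len = int(rng.integers(cfg.lower_stem_range[0], cfg.lower_stem_range[1] + 1))
    ext5 = _random_seq(rng, ext_len, cfg.gc)
    ext3 = revcomp(ext5)
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = ext5 + mature + loop + star + ext3
        mature_off = ext_len
        star_off = ext_len + mature_len + cfg.loop_len
    else:
        precursor = ext5 + star + loop + mature + ext3
        mature_off = ext_len + mature_len + cfg.loop_len
        star_off = ext_len
    return precursor, mature, star, mature_off, star_off, arm


def _valid_precursor(precursor: str, mature_off: int, star_off: int,
                     mature_len: int) -> bool:
    """Planted-locus contract: the precursor's own fold must hold a passing
    mature/star duplex whose inferred star arm sits on the planted star
    (within 1 nt per end) and whose trimmed stem-loop spans the precursor."""
    from .hairpin_fold import best_precursor

    window = type("W", (), {"seq": precursor, "tag_offset": mature_off})()
    best = best_precursor([window], precursor[mature_off:mature_off + mature_len])
    if best is None:
        return False
    lo, hi = best.assessment.star_span
    if abs(lo - star_off) > 1 or abs(hi - (star_off + mature_len)) > 1:
        return False
    return abs(best.hairpin_len - len(precursor)) <= 6


def _place(rng, occupied: list[tuple[int, int]], scaffold_len: int,
           size: int, margin: int, attempts: int = 200) -> int:
    for _ in range(attempts):
        pos = int(rng.integers(0, max(1, scaffold_len - size)))
        if all(pos + size + margin <= s or e + margin <= pos for s, e in occupied):
            occupied.append((pos, pos + size))
            return pos
    raise PlacementError(
        f"could not place a {size}-nt locus on a {scaffold_len}-nt scaffold "
        f"without overlap; increase genome_len or reduce locus count"
    )


def build_genome(cfg: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate a genome with planted MIR loci and a repeat family.

    Returns the scaffold map and the full ground truth.  Deterministic for a
    fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lens = [cfg.genome_len // cfg.n_scaffolds] * cfg.n_scaffolds
    lens[-1] += cfg.genome_len - sum(lens)
    scaffolds = {
        f"scaffold{i + 1:05d}": list(_random_seq(rng, n, cfg.gc))
        for i, n in enumerate(lens)
    }
    names = list(scaffolds)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    mirs = []
    for _ in range(cfg.n_planted):
        # rejection-sample until the planted locus honours its contract: the
        # excised precursor must re-fold into a stem-loop whose validated
        # duplex recovers the planted star arm
        for _attempt in range(100):
            precursor, mature, star, mature_off, star_off, arm = _build_precursor(rng, cfg)
            if _valid_precursor(precursor, mature_off, star_off, len(mature)):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a valid precursor in 100 draws")
        strand = "+" if rng.random() < 0.5 else "-"
        name = names[int(rng.integers(len(names)))]
        pos = _place(rng, occupied[name], len(scaffolds[name]),
                     len(precursor), margin=60)
        insert = precursor if strand == "+" else revcomp(precursor)
        scaffolds[name][pos : pos + len(precursor)] = list(insert)
        if strand == "+":
            m_start = pos + mature_off
        else:
            m_start = pos + len(precursor) - (mature_off + len(mature))
        mirs.append(
            PlantedMir(
                mature_seq=mature,
                star_seq=star,
                scaffold_id=name,
                start=m_start + 1,
                end=m_start + len(mature),
                strand=strand,
                mature_count=int(
                    rng.integers(cfg.mature_count_range[0], cfg.mature_count_range[1] + 1)
                ),
                star_count=int(
                    rng.integers(cfg.star_count_range[0], cfg.star_count_range[1] + 1)
                ),
                loop_len=cfg.loop_len,
                arm=arm,
                precursor_seq=precursor,
                precursor_start=pos + 1,
                precursor_end=pos + len(precursor),
            )
        )

    repeat = None
    if cfg.repeat_copies > 0:
        unit = _random_seq(rng, cfg.repeat_unit_len, cfg.gc)
        loci = []
        for _ in range(cfg.repeat_copies):
            name = names[int(rng.integers(len(names)))]
            pos = _place(rng, occupied[name], len(scaffolds[name]),
                         len(unit), margin=10)
            scaffolds[name][pos : pos + len(unit)] = list(unit)
            loci.append((name, pos + 1))
        offsets = np.linspace(0, cfg.repeat_unit_len - 24,
                              cfg.n_repeat_tags).astype(int)
        tags = tuple(
            (unit[o : o + 24], int(rng.integers(2, 21))) for o in sorted(set(offsets))
        )
        repeat = RepeatFamily(unit, tuple(loci), tags)

    genome = {name: "".join(chars) for name, chars in scaffolds.items()}
    return genome, SimTruth(tuple(mirs), repeat)


def simulate_reads(
    genome: Mapping[str, str], truth: SimTruth, cfg: SimConfig
) -> list[tuple[str, int]]:
    """Simulate the collapsed read population for a generated genome.

    Planted mature/star sequences contribute exactly their recorded counts;
    repeat tags contribute theirs; background reads are drawn uniformly from
    genomic positions (either strand) with lengths from ``cfg.length_dist``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    reads: list[tuple[str, int]] = []
    for mir in truth.mirs:
        reads.append((mir.mature_seq, mir.mature_count))
        if mir.star_count > 0:
            reads.append((mir.star_seq, mir.star_count))
    if truth.repeat is not None:
        reads.extend(truth.repeat.tags)
    names = list(genome)
    weights = np.array([len(genome[n]) for n in names], dtype=float)
    weights /= weights.sum()
    lengths = sorted(cfg.length_dist)
    probs = np.array([cfg.length_dist[k] for k in lengths])
    for _ in range(cfg.background_reads):
        name = names[int(rng.choice(len(names), p=weights))]
        seq = genome[name]
        k = int(rng.choice(lengths, p=probs))
        pos = int(rng.integers(0, len(seq) - k))
        read = seq[pos : pos + k]
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append((read, 1))
    return reads


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [m.scaffold_id for m in truth.mirs],
            "start": [m.start for m in truth.mirs],
            "end": [m.end for m in truth.mirs],
            "strand": [m.strand for m in truth.mirs],
            "mature_seq": [m.mature_seq for m in truth.mirs],
            "star_seq": [m.star_seq for m in truth.mirs],
            "mature_count": [m.mature_count for m in truth.mirs],
            "star_count": [m.star_count for m in truth.mirs],
            "arm": [m.arm for m in truth.mirs],
            "precursor_start": [m.precursor_start for m in truth.mirs],
            "precursor_end": [m.precursor_end for m in truth.mirs],
        }
    )


def write_bundle(outdir: str | Path, genome: Mapping[str, str],
                 truth: SimTruth, reads: Sequence[tuple[str, int]]) -> None:
    """Write genome FASTA, collapsed reads FASTA and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", genome.items())
    write_collapsed(outdir / "reads.fa", reads)
    truth_to_frame(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian-path resampling of
    the dinucleotide transition multigraph)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(200):
        # choose a candidate "last exit" edge per vertex (except the sink)
        # and accept when those edges form a tree rooted at the sink
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in vertices if v != last
        }
        ok = True
        for v in last_edge:
            cur, seen = v, {v}
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen or (cur != last and cur not in last_edge):
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - rejection loop essentially always succeeds
        return seq
    pools = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        pools[v] = rest
    out = [seq[0]]
    cur = seq[0]
    total = len(seq) - 1
    idx = {v: 0 for v in vertices}
    for _ in range(total):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
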