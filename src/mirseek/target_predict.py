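"""Plant-style miRNA target prediction by complementarity scoring.

Every transcript window of miRNA length is scored against the miRNA in the
antiparallel register: position i of the miRNA (1-based from its 5' end)
faces the window base ``end - i + 1``.  Penalties follow the canonical plant
rules — mismatch 1.0, G:U wobble 0.5, bulge 1.0, all doubled inside the
functionally critical positions 2-13 — and sites at or under ``max_score``
(default 4.0) are reported.  The scheme is deliberately restrictive, as
plant miRNA/target pairs are near-perfectly complementary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import normalize_seq

DEFAULT_MAX_SCORE = 4.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
BULGE_PENALTY = 1.0
CORE_START, CORE_END = 2, 13  # 1-based miRNA positions with doubled penalties

_COMPLEMENT = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA terms


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    score: float
    alignment: tuple[str, str, str]  # miRNA 5'->3', match line, site 3'->5'

    def __str__(self) -> str:
        mir, match, tgt = self.alignment
        return (
            f"{self.mirna_id} vs {self.transcript_id}:{self.start}-{self.end} "
            f"score={self.score}\n  miRNA  5' {mir} 3'\n"
            f"            {match}\n  target 3' {tgt} 5'"
        )


def _position_penalty(pos_1based: int, penalty: float) -> float:
    return 2 * penalty if CORE_START <= pos_1based <= CORE_END else penalty


def score_site(mirna_seq: str, target_subseq: str) -> float:
    """Penalty score of a miRNA against an equal-length (or one-bulge)
    target window, summed 5'->3' over miRNA positions.

    The window is given in transcript (sense) orientation; it is read
    3'->5' against the miRNA.  A length difference of one is modelled as a
    single-nt bulge at its best position; larger differences are rejected.
    """
    mir = normalize_seq(mirna_seq)
    tgt = normalize_seq(target_subseq)[::-1]  # align antiparallel
    diff = len(tgt) - len(mir)
    if diff == 0:
        return _score_ungapped(mir, tgt)
    if abs(diff) != 1:
        raise ValueError(
            f"length difference {abs(diff)} needs more than one bulge"
        )
    best = None
    longer, shorter, bulge_on_target = (
        (tgt, mir, True) if diff > 0 else (mir, tgt, False)
    )
    for skip in range(len(longer)):
        gapped = longer[:skip] + longer[skip + 1 :]
        # bulge penalty is positional on the miRNA
        pos = skip + 1 if not bulge_on_target else min(skip + 1, len(mir))
        score = _score_ungapped(
            mir if bulge_on_target else gapped,
            gapped if bulge_on_target else tgt,
        ) + _position_penalty(pos, BULGE_PENALTY)
        if best is None or score < best:
            best = score
    return best


def _score_ungapped(mir: str, tgt_rev: str) -> float:
    score = 0.0
    for i, (a, b) in enumerate(zip(mir, tgt_rev), start=1):
        if (a, b) in _COMPLEMENT:
            continue
        if (a, b) in _WOBBLE:
            score += _position_penalty(i, WOBBLE_PENALTY)
        else:
            score += _position_penalty(i, MISMATCH_PENALTY)
    return score


def scan_transcriptome(
    mirna_id: str,
    mirna_seq: str,
    transcripts: Mapping[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetSite]:
    """Scan every window of every transcript; report sites scoring at or
    under ``max_score``, sorted by (score, transcript, position).

    Site spans equal the miRNA length (ungapped register).
    """
    if not transcripts:
        raise ValueError("transcript set must be non-empty")
    mir = normalize_seq(mirna_seq)
    n = len(mir)
    sites = []
    for tid, tseq in transcripts.items():
        tseq = normalize_seq(tseq)
        for pos in range(len(tseq) - n + 1):
            window = tseq[pos : pos + n]
            score = _score_ungapped(mir, window[::-1])
            if score <= max_score:
                sites.append(
                    TargetSite(
                        mirna_id, tid, pos + 1, pos + n, score,
                        _alignment_strings(mir, window),
                    )
                )
    return sorted(sites, key=lambda s: (s.score, s.transcript_id, s.start))


def _alignment_strings(mir: str, window: str) -> tuple[str, str, str]:
    tgt_rev = window[::-1]
    match = "".join(
        "|" if (a, b) in _COMPLEMENT else ("o" if (a, b) in _WOBBLE else " ")
        for a, b in zip(mir, tgt_rev)
    )
    return mir.replace("T", "U"), match, tgt_rev.replace("T", "U")


def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in sites],
            "transcript_id": [s.transcript_id for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "score": [s.score for s in sites],
            "alignment_mirna": [s.alignment[0] for s in sites],
            "alignment_match": [s.alignment[1] for s in sites],
            "alignment_target": [s.alignment[2] for s in sites],
        }
    )
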