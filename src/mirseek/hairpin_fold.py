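"""Secondary-structure prediction and miRNA/miRNA* duplex validation.

The folding engine is a deterministic dynamic program over nested (pseudoknot
free) structures that maximises a simple additive score: each admissible base
pair (Watson-Crick or G:U) earns its pair score, and a pair immediately
stacked on another earns a stacking bonus.  Hairpin loops are constrained to
hold at least ``min_loop`` unpaired bases.  The reported "energy" is the
negated optimal score: an arbitrary-unit stand-in for a free energy — more
negative means more, and better stacked, pairing.  A thermodynamic backend
can be substituted by any caller that produces the same :class:`FoldResult`
contract; nothing downstream depends on absolute energy values.

Duplex validation applies the standard plant-miRNA annotation geometry: the
mature arm must pair into a single opposing arm of one stem-loop, the star
arm is the partner region shifted to leave 2-nt 3' overhangs on both arms,
and the duplex must keep at least ``min_matched_pairs`` paired mature bases
with a mature/star length difference of at most ``max_size_diff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from numba import njit

MIN_LOOP = 3
STACK_BONUS = 1.0

#: Default pair scores: G-C strongest, A-T intermediate, G-T wobble weakest.
DEFAULT_PAIR_SCORES: dict[frozenset[str], float] = {
    frozenset("AT"): 2.0,
    frozenset("GC"): 3.0,
    frozenset("GT"): 1.0,
}

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_NEG = -1e18
_TOL = 1e-6


def _score_matrix(pair_scores: dict[frozenset[str], float]) -> np.ndarray:
    mat = np.zeros((5, 5), dtype=np.float64)
    for key, val in pair_scores.items():
        a, b = (tuple(key) * 2)[:2]  # singleton frozenset would mean a==b
        mat[_ENCODE[a], _ENCODE[b]] = val
        mat[_ENCODE[b], _ENCODE[a]] = val
    return mat


@njit(cache=True)
def _fill(enc, psc, min_loop, stack_bonus):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    W = np.zeros((n, n), dtype=np.float64)
    P = np.full((n, n), _NEG, dtype=np.float64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            s = psc[enc[i], enc[j]]
            if s > 0.0:
                best = W[i + 1, j - 1]
                if span >= min_loop + 3 and P[i + 1, j - 1] > _NEG / 2:
                    alt = P[i + 1, j - 1] + stack_bonus
                    if alt > best:
                        best = alt
                P[i, j] = s + best
            w = W[i, j - 1]
            for k in range(i, j - min_loop):
                if P[k, j] > _NEG / 2:
                    left = W[i, k - 1] if k > i else 0.0
                    cand = left + P[k, j]
                    if cand > w:
                        w = cand
            W[i, j] = w
    return W, P


def _traceback(W, P, enc, psc, min_loop, stack_bonus) -> np.ndarray:
    """Deterministic traceback: prefer pairing, 5'-most partner, stacked path."""
    n = enc.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    frames = [("W", 0, n - 1)] if n > 1 else []
    while frames:
        kind, i, j = frames.pop()
        if j - i < min_loop + 1:
            continue
        if kind == "W":
            if W[i, j] < _TOL:
                continue
            paired = False
            for k in range(i, j - min_loop):
                if P[k, j] < _NEG / 2:
                    continue
                left = W[i, k - 1] if k > i else 0.0
                if abs(left + P[k, j] - W[i, j]) < _TOL:
                    if k > i:
                        frames.append(("W", i, k - 1))
                    frames.append(("P", k, j))
                    paired = True
                    break
            if not paired:
                frames.append(("W", i, j - 1))
        else:
            partner[i] = j
            partner[j] = i
            s = psc[enc[i], enc[j]]
            stacked = (
                j - i >= min_loop + 3
                and P[i + 1, j - 1] > _NEG / 2
                and abs(P[i, j] - (s + P[i + 1, j - 1] + stack_bonus)) < _TOL
            )
            if stacked:
                frames.append(("P", i + 1, j - 1))
            else:
                frames.append(("W", i + 1, j - 1))
    return partner


@dataclass(frozen=True)
class FoldResult:
    """Predicted nested secondary structure of one sequence."""

    seq: str
    structure: str
    energy: float
    pairs: tuple[tuple[int, int], ...]
    partner: np.ndarray = field(repr=False, compare=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def fold(
    seq: str,
    *,
    pair_scores: dict[frozenset[str], float] | None = None,
    stack_bonus: float = STACK_BONUS,
    min_loop: int = MIN_LOOP,
) -> FoldResult:
    """Fold a sequence into its maximum-scoring nested structure.

    Parameters
    ----------
    seq
        DNA/RNA string (A/C/G/T/U, N allowed but never pairs), 1-1000 nt.
    pair_scores
        Mapping ``frozenset({x, y}) -> score`` of admissible pairs; defaults
        to :data:`DEFAULT_PAIR_SCORES`.
    stack_bonus
        Extra score for each pair stacked directly on another.
    min_loop
        Minimum number of unpaired bases closed by a hairpin pair.
    """
    s = seq.upper().replace("U", "T")
    if not 1 <= len(s) <= 1000:
        raise ValueError(f"sequence length {len(s)} outside [1, 1000]")
    bad = set(s) - set(_ENCODE)
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    enc = np.array([_ENCODE[c] for c in s], dtype=np.int64)
    psc = _score_matrix(pair_scores or DEFAULT_PAIR_SCORES)
    if len(s) < min_loop + 2:
        partner = np.full(len(s), -1, dtype=np.int64)
        return FoldResult(s, "." * len(s), 0.0, (), partner)
    W, P = _fill(enc, psc, min_loop, float(stack_bonus))
    partner = _traceback(W, P, enc, psc, min_loop, float(stack_bonus))
    structure = "".join(
        "." if partner[i] < 0 else ("(" if partner[i] > i else ")")
        for i in range(len(s))
    )
    pairs = tuple((i, int(partner[i])) for i in range(len(s)) if partner[i] > i)
    return FoldResult(s, structure, -float(W[0, len(s) - 1]), pairs, partner)


@dataclass(frozen=True)
class DuplexAssessment:
    """Verdict on miRNA/miRNA* geometry within a folded precursor."""

    mature_span: tuple[int, int]  # 0-based half-open on the precursor
    star_span: tuple[int, int] | None
    matched_pairs: int
    size_diff: int
    overhang_3p: int
    passes: bool
    reason: str | None = None

    @property
    def star_seq_on(self) -> str | None:
        return None


def _hairpin_loops_within(pairs: Sequence[tuple[int, int]], lo: int, hi: int) -> int:
    """Count terminal (innermost) loops among pairs lying strictly in (lo, hi)."""
    inside = [(i, j) for i, j in pairs if lo < i and j < hi]
    n_loops = 0
    for i, j in inside:
        if not any(i < x and y < j for x, y in inside if (x, y) != (i, j)):
            n_loops += 1
    return n_loops


def validate_hairpin(
    fold_result: FoldResult,
    mature_span: tuple[int, int],
    *,
    min_matched_pairs: int = 16,
    max_size_diff: int = 4,
    overhang: int = 2,
    diag_tol: int = 6,
) -> DuplexAssessment:
    """Assess the miRNA/miRNA* duplex for a mature arm placed on a fold.

    ``mature_span`` is 0-based half-open on ``fold_result.seq``.  The star
    span is derived from the pairing partners of the mature arm (restricted
    to the majority side and to a consistent antiparallel diagonal, tolerance
    ``diag_tol``), then extended by ``overhang`` nt to impose the Dicer-style
    2-nt 3' overhang on the star arm.
    """
    ms, me = mature_span
    n = len(fold_result.seq)
    partner = fold_result.partner
    if not (0 <= ms < me <= n):
        raise ValueError(f"mature span {mature_span} outside sequence of length {n}")

    def fail(reason: str, matched: int = 0, star=None, size_diff: int = 0):
        return DuplexAssessment(
            (ms, me), star, matched, size_diff, overhang, False, reason
        )

    # The mature arm must not fold back onto itself (it would straddle the loop).
    for i in range(ms, me):
        if ms <= partner[i] < me:
            return fail("arm-in-loop")
    paired = [(i, int(partner[i])) for i in range(ms, me) if partner[i] >= 0]
    if not paired:
        return fail("unpaired-arm")
    right = [(i, p) for i, p in paired if p >= me]
    left = [(i, p) for i, p in paired if p < ms]
    arm = right if len(right) >= len(left) else left
    # densest antiparallel diagonal: partners of a clean duplex share i + p
    diags = [i + p for i, p in arm]
    center = max(diags, key=lambda d: sum(abs(d2 - d) <= diag_tol for d2 in diags))
    keep = [(i, p) for i, p in arm if abs(i + p - center) <= diag_tol]
    # The mature 3'-terminal ``overhang`` bases protrude from the duplex by
    # definition; partners they pick up (usually loop bases) must not define
    # the star span.
    span_pairs = [(i, p) for i, p in keep if i < me - overhang] or keep
    pmin = min(p for _, p in span_pairs)
    pmax = max(p for _, p in span_pairs)
    # star = [pmin, pmax + overhang] inclusive, on either arm (see module docs)
    star_lo = pmin
    star_hi = min(pmax + overhang + 1, n)
    if arm is left:
        star_hi = min(star_hi, ms)  # never run into the mature arm
    star_span = (star_lo, star_hi)
    # partners of the mature 3'-terminal bases sit just outside the star 5'
    # end when the duplex is fully paired; they still belong to the duplex
    matched = sum(1 for _, p in keep if star_lo - overhang <= p < star_hi)
    size_diff = abs((me - ms) - (star_hi - star_lo))

    # Single stem-loop requirement: at most one terminal loop between the arms.
    if arm is right:
        loop_a = max(i for i, _ in keep)
        loop_b = min(p for _, p in keep)
    else:
        loop_a = max(p for _, p in keep)
        loop_b = min(i for i, _ in keep)
    if _hairpin_loops_within(fold_result.pairs, loop_a, loop_b) > 1:
        return fail("branched", matched, star_span, size_diff)

    passes = matched >= min_matched_pairs and size_diff <= max_size_diff
    reason = None
    if not passes:
        reason = (
            "too-few-matched-pairs" if matched < min_matched_pairs else "size-diff"
        )
    return DuplexAssessment(
        (ms, me), star_span, matched, size_diff, overhang, passes, reason
    )


@dataclass(frozen=True)
class PrecursorResult:
    """A window whose fold passed duplex validation, with hairpin metrics.

    ``energy`` is the score of the trimmed stem-loop itself (not of the
    whole excised window), so precursors found in windows of different
    sizes are comparable.
    """

    window: object  # genome_scan.PrecursorWindow (duck-typed: .seq at minimum)
    fold: FoldResult
    assessment: DuplexAssessment
    hairpin_span: tuple[int, int]  # 0-based inclusive on the window sequence
    hairpin_len: int
    energy: float

    @property
    def star_seq(self) -> str:
        lo, hi = self.assessment.star_span
        return self.fold.seq[lo:hi]


def _hairpin_span(
    partner: np.ndarray, lo: int, hi: int, max_gap: int = 2
) -> tuple[int, int]:
    """Trimmed stem-loop span: extend outward from [lo, hi) through enclosing
    pairs separated by at most ``max_gap`` unpaired/foreign bases per side."""
    a, b = lo, hi - 1
    n = len(partner)
    while True:
        nxt = None
        for x in range(a - 1, max(a - max_gap - 2, -1), -1):
            p = partner[x]
            if p > b and p - b <= max_gap + 1:
                # only extend through helices of >= 3 stacked pairs; short
                # incidental pairings in random flanking sequence are not stem
                helix = 1
                xx, pp = x + 1, p - 1
                while xx < n and partner[xx] == pp:
                    helix += 1
                    xx, pp = xx + 1, pp - 1
                xx, pp = x - 1, p + 1
                while xx >= 0 and partner[xx] == pp:
                    helix += 1
                    xx, pp = xx - 1, pp + 1
                if helix >= 3:
                    nxt = (x, int(p))
                    break
        if nxt is None:
            break
        a, b = nxt
    return a, b


def best_precursor(
    windows: Iterable,
    tag: str,
    *,
    fold_kwargs: dict | None = None,
    validate_kwargs: dict | None = None,
) -> PrecursorResult | None:
    """Fold candidate windows and return the lowest-energy passing precursor.

    ``windows`` are objects with a ``.seq`` attribute (and optionally
    ``.tag_offset``) in which ``tag`` occurs verbatim.  Returns ``None`` when
    no window passes duplex validation.
    """
    tag = tag.upper().replace("U", "T")
    fkw = fold_kwargs or {}
    psc = _score_matrix(fkw.get("pair_scores") or DEFAULT_PAIR_SCORES)
    stack = fkw.get("stack_bonus", STACK_BONUS)
    best: PrecursorResult | None = None
    for win in windows:
        seq = win.seq
        off = getattr(win, "tag_offset", None)
        if off is None:
            off = seq.find(tag)
        if off < 0:
            continue
        fr = fold(seq, **fkw)
        assessment = validate_hairpin(
            fr, (off, off + len(tag)), **(validate_kwargs or {})
        )
        if not assessment.passes:
            continue
        s_lo, s_hi = assessment.star_span
        lo = min(off, s_lo)
        hi = max(off + len(tag), s_hi)
        a, b = _hairpin_span(fr.partner, lo, hi)
        energy = _span_energy(fr, a, b, psc, stack)
        result = PrecursorResult(win, fr, assessment, (a, b), b - a + 1, energy)
        if best is None or energy < best.energy:
            best = result
    return best


def _span_energy(
    fr: FoldResult, a: int, b: int, psc: np.ndarray, stack_bonus: float
) -> float:
    """Negated score of the structure restricted to pairs inside [a, b]."""
    enc = [_ENCODE[c] for c in fr.seq]
    score = 0.0
    inside = {(i, j) for i, j in fr.pairs if a <= i and j <= b}
    for i, j in inside:
        score += psc[enc[i], enc[j]]
        if (i + 1, j - 1) in inside:
            score += stack_bonus
    return -score
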