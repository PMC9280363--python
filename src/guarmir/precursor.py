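"""Precursor-candidate extraction and stem-loop validation.

Around every homology hit a family of nested windows is cut from the EST,
folded, and checked against the stem-loop criteria: the mature must sit
entirely on one arm of a hairpin, must not reach into the terminal loop,
the mature:star duplex may carry only a bounded number of mismatched
(non-Watson-Crick or unpaired) mature bases, and no bulge or interior
loop in the stem may exceed the configured size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .fold import FoldEngine, FoldResult, fold_nussinov, pair_table
from .homology import HomologHit
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

# reject reason tags
NO_HAIRPIN = "no_hairpin"
NOT_IN_STEM = "not_in_stem"
LOOP_OVERLAP = "loop_overlap"
DUPLEX_MISMATCHES = "duplex_mismatches"
BULGE_TOO_LARGE = "bulge_too_large"

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class CandidateWindow:
    """A sub-sequence of an EST containing the full mature site."""

    start: int  # on the EST, 0-based half-open
    end: int
    mature_offset: int  # start of the mature within the window
    mature_len: int


@dataclass(frozen=True)
class PrecursorCandidate:
    """A folded window with its stem-loop validity assessment."""

    est_id: str
    window_start: int
    window_end: int
    seq: str
    fold: FoldResult
    mature_offset: int
    mature_len: int
    arm: str | None
    duplex_mismatches: int
    valid: bool
    reject_reasons: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def energy_density(self) -> float:
        return self.fold.mfe / len(self.seq)


def extract_windows(
    est: SequenceRecord,
    hit: HomologHit,
    flank: int = 300,
    step: int = 25,
    min_flank: int = 10,
) -> list[CandidateWindow]:
    """Enumerate nested candidate windows around a hit, largest first.

    Because the mature may sit on either precursor arm, flank sizes on the
    two sides are varied independently over a coarse grid: symmetric
    windows plus windows padded ``min_flank`` on one side and a grid value
    on the other. Windows are clipped to the EST and de-duplicated.
    """
    if not (0 <= hit.est_start and hit.est_end <= len(est.seq)):
        raise ValueError("hit does not lie on the EST")
    grid = list(range(flank, min_flank, -step)) + [min_flank]
    spans: set[tuple[int, int]] = set()
    for f in grid:
        spans.add((f, f))
        spans.add((f, min_flank))
        spans.add((min_flank, f))
    windows: set[tuple[int, int]] = set()
    for left, right in spans:
        s = max(0, hit.est_start - left)
        e = min(len(est.seq), hit.est_end + right)
        windows.add((s, e))
    ordered = sorted(windows, key=lambda w: (-(w[1] - w[0]), w[0]))
    return [
        CandidateWindow(s, e, mature_offset=hit.est_start - s,
                        mature_len=hit.match_len)
        for s, e in ordered
    ]


def validate_hairpin(
    window_seq: str,
    fold: FoldResult,
    mature_offset: int,
    mature_len: int,
    max_duplex_mismatch: int = 5,
    max_bulge: int = 30,
    est_id: str = "",
    window_start: int = 0,
    window_end: int | None = None,
) -> PrecursorCandidate:
    """Assess one folded window against the stem-loop criteria.

    Arm placement is read off the mature's own pairing pattern, which is
    robust to decorative structure elsewhere in the window: the mature
    lies on the 5' arm when every paired mature base points downstream
    (star further 3'), on the 3' arm when every partner is upstream.
    Mature bases pairing with other mature bases, or partners on both
    sides, mean the mature straddles a terminal loop. A mature base
    counts as a duplex mismatch when it is unpaired or its pair is not
    Watson-Crick (a G:U wobble therefore counts against the budget, as
    in the mature:star comparison of homology pipelines), and no bulge
    or interior loop inside the mature:star ladder may exceed
    ``max_bulge``.
    """
    if window_end is None:
        window_end = window_start + len(window_seq)
    m_start, m_end = mature_offset, mature_offset + mature_len
    if not (0 <= m_start and m_end <= len(window_seq)):
        raise ValueError("mature region outside window")
    if len(fold.structure) != len(window_seq):
        raise ValueError("fold does not match window sequence")

    reasons: list[str] = []
    arm: str | None = None
    table = pair_table(fold.structure)
    ladder = [(p, table[p]) for p in range(m_start, m_end) if p in table]
    if not ladder:
        reasons.append(NO_HAIRPIN)
    else:
        partners = [q for _, q in ladder]
        if any(m_start <= q < m_end for q in partners):
            reasons.append(LOOP_OVERLAP)  # hairpin loop inside the mature
        elif all(q >= m_end for q in partners):
            arm = FIVE_PRIME
        elif all(q < m_start for q in partners):
            arm = THREE_PRIME
        else:
            reasons.append(LOOP_OVERLAP)  # partners on both sides
        if arm is not None:
            worst = 0
            for (p1, q1), (p2, q2) in zip(ladder, ladder[1:]):
                worst = max(worst, p2 - p1 - 1, abs(q1 - q2) - 1)
            if worst > max_bulge:
                reasons.append(BULGE_TOO_LARGE)

    canon = window_seq.upper().replace("U", "T")
    mm = 0
    for p in range(m_start, m_end):
        q = table.get(p)
        if q is None or (canon[p], canon[q]) not in _WC:
            mm += 1
    if mm > max_duplex_mismatch:
        reasons.append(DUPLEX_MISMATCHES)

    return PrecursorCandidate(
        est_id=est_id,
        window_start=window_start,
        window_end=window_end,
        seq=window_seq,
        fold=fold,
        mature_offset=mature_offset,
        mature_len=mature_len,
        arm=arm,
        duplex_mismatches=mm,
        valid=not reasons,
        reject_reasons=tuple(reasons),
    )


def select_precursor(
    candidates: list[PrecursorCandidate],
) -> PrecursorCandidate | None:
    """Pick the precursor for one hit from its validated windows.

    Among valid windows: lowest energy density (mfe/length), then the
    shorter window, then the leftmost. Returns None when no window is
    valid (the hit is dropped, logged).
    """
    valid = [c for c in candidates if c.valid]
    if not valid:
        if candidates:
            log.info("hit on %s: no valid precursor window among %d",
                     candidates[0].est_id, len(candidates))
        return None
    return min(valid, key=lambda c: (c.energy_density, c.length, c.window_start))


def fold_and_validate(
    est: SequenceRecord,
    hit: HomologHit,
    engine: FoldEngine | None = None,
    flank: int = 300,
    step: int = 25,
    min_flank: int = 10,
    max_duplex_mismatch: int = 5,
    max_bulge: int = 30,
    min_loop: int = 3,
    max_pair_distance: int = 3000,
) -> PrecursorCandidate | None:
    """Full per-hit stage: enumerate windows, fold each, validate, select."""
    if engine is None:
        def engine(seq: str) -> FoldResult:
            return fold_nussinov(seq, min_loop=min_loop,
                                 max_pair_distance=max_pair_distance)
    candidates = []
    for win in extract_windows(est, hit, flank=flank, step=step,
                               min_flank=min_flank):
        seq = est.seq[win.start:win.end]
        candidates.append(
            validate_hairpin(
                seq, engine(seq), win.mature_offset, win.mature_len,
                max_duplex_mismatch=max_duplex_mismatch, max_bulge=max_bulge,
                est_id=est.id, window_start=win.start, window_end=win.end,
            )
        )
    return select_precursor(candidates)
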