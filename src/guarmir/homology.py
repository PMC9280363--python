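"""Plus-strand homology scan of reference mature miRNAs against ESTs.

The scan is an exhaustive ungapped sliding-window comparison: every
reference mature is slid across every EST and windows within the mismatch
budget are reported. With ~20-25 nt queries over desk-scale EST sets this
is fast and needs no heuristic seeding; reverse-complement matches are
deliberately never reported (plus strand only).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

log = logging.getLogger(__name__)

_FAMILY_RE = re.compile(r"(miR|MIR|let|lin)-?(\d+)", re.IGNORECASE)

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def mirna_family(ref_id: str) -> str:
    """Extract the miRNA family name from a miRBase-style id.

    ``ath-miR156h`` -> ``miR156``; ``osa-miR444a.2`` -> ``miR444``;
    ``ppt-miR1044`` -> ``miR1044``. Ids without a recognisable family
    token are returned unchanged.
    """
    m = _FAMILY_RE.search(ref_id)
    if not m:
        return ref_id
    prefix = m.group(1)
    if prefix.lower() == "mir":
        prefix = "miR"
    return f"{prefix}{m.group(2)}"


def hamming_mismatches(a: str, b: str) -> int:
    """Number of differing positions between two equal-length sequences.

    Comparison is on the canonical alphabet (U and T are equivalent).
    Raises ``ValueError`` on unequal lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class HomologHit:
    """An ungapped plus-strand match of a full reference mature in an EST."""

    est_id: str
    ref_id: str
    family: str
    est_start: int  # 0-based half-open internally
    est_end: int
    strand: str
    mismatches: int
    match_len: int
    best: bool = False

    @property
    def start_1based(self) -> int:
        return self.est_start + 1

    @property
    def end_1based(self) -> int:
        return self.est_end  # half-open end == 1-based inclusive end


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to small integers on the canonical alphabet."""
    return np.fromiter((_BASE_CODES[c] for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


def scan_ests(
    ests: Sequence[SequenceRecord],
    matures: Sequence[SequenceRecord],
    max_mismatch: int = 4,
    min_match: int = 18,
    mature_len_range: tuple[int, int] = (19, 25),
) -> list[HomologHit]:
    """Scan every EST for plus-strand matches of every reference mature.

    A hit is any ungapped alignment of a full-length reference against an
    EST window with at most ``max_mismatch`` mismatches; references shorter
    than ``min_match`` or outside ``mature_len_range`` are skipped with a
    warning. Per (EST, family) the hit with fewest mismatches (earliest
    window, then lexicographically smallest reference id on ties) carries
    ``best=True``.
    """
    matures = list(matures)
    if not matures:
        raise ValueError("scan_ests: empty reference mature set")
    lo, hi = mature_len_range
    usable = []
    for ref in matures:
        n = len(ref.seq)
        if n < min_match or not (lo <= n <= hi):
            log.warning("skipping reference %s: length %d outside budgets",
                        ref.id, n)
            continue
        usable.append(ref)

    hits: list[HomologHit] = []
    ref_codes = [(ref, encode(ref.seq)) for ref in usable]
    for est in ests:
        est_arr = encode(est.seq)
        est_hits: list[HomologHit] = []
        for ref, rcode in ref_codes:
            k = len(rcode)
            if len(est_arr) < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(est_arr, k)
            mm = (windows != rcode).sum(axis=1)
            for off in np.nonzero(mm <= max_mismatch)[0]:
                est_hits.append(
                    HomologHit(
                        est_id=est.id, ref_id=ref.id,
                        family=mirna_family(ref.id),
                        est_start=int(off), est_end=int(off) + k,
                        strand="+", mismatches=int(mm[off]), match_len=k,
                    )
                )
        hits.extend(_flag_best(est_hits))
    return hits


def _flag_best(est_hits: list[HomologHit]) -> list[HomologHit]:
    best_idx: dict[str, int] = {}
    for i, h in enumerate(est_hits):
        j = best_idx.get(h.family)
        if j is None:
            best_idx[h.family] = i
            continue
        other = est_hits[j]
        if (h.mismatches, h.est_start, h.ref_id) < (
                other.mismatches, other.est_start, other.ref_id):
            best_idx[h.family] = i
    chosen = set(best_idx.values())
    return [replace(h, best=i in chosen) for i, h in enumerate(est_hits)]
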