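"""Rule-based miRNA target-site prediction on transcripts.

Plant miRNAs direct cleavage of near-perfectly complementary sites, so
target scanning is an exhaustive ungapped antiparallel comparison of the
miRNA against every transcript window under three rules: at most four
mismatches, at most four G:U wobbles (budgeted separately — a wobble is
not a mismatch), and strict Watson-Crick pairing at miRNA positions 10
and 11, the cleavage site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

MATCH = "match"
GU = "gu"
MISMATCH = "mismatch"

# classes indexed by (miRNA base code, transcript base code); codes
# A=0 C=1 G=2 T/U=3 N=4. Pairing is antiparallel: miRNA position i faces
# transcript base site[L-1-i].
_CLS_MATCH, _CLS_GU, _CLS_MM = 0, 1, 2
_PAIR_CLASS = np.full((5, 5), _CLS_MM, dtype=np.int8)
_PAIR_CLASS[0, 3] = _PAIR_CLASS[3, 0] = _CLS_MATCH  # A:U
_PAIR_CLASS[2, 1] = _PAIR_CLASS[1, 2] = _CLS_MATCH  # G:C
_PAIR_CLASS[2, 3] = _PAIR_CLASS[3, 2] = _CLS_GU     # G:U wobble

_CLS_NAME = (MATCH, GU, MISMATCH)
_CLS_GLYPH = ("|", "o", ".")

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODES[c] for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


@dataclass(frozen=True)
class TargetSite:
    """A predicted miRNA binding site on a transcript."""

    mirna_id: str
    transcript_id: str
    site_start: int  # transcript, 0-based half-open
    site_end: int
    align: tuple[str, ...]  # per-position class, indexed from miRNA 5' end
    mismatches: int
    gu_pairs: int
    valid: bool
    best: bool = False

    @property
    def glyphs(self) -> str:
        """Alignment rendered as | (match), o (G:U), . (mismatch)."""
        m = {MATCH: "|", GU: "o", MISMATCH: "."}
        return "".join(m[c] for c in self.align)


def classify_duplex(mirna: str, site: str) -> tuple[str, ...]:
    """Per-position pairing classes of a miRNA against one site window.

    ``site`` is the transcript window read 5'->3'; the duplex is
    antiparallel, so miRNA position i (from its 5' end) faces transcript
    base ``site[L-1-i]``. Classes: Watson-Crick -> match, G:U -> gu,
    anything else (including N) -> mismatch.
    """
    if len(mirna) != len(site):
        raise ValueError("site window must match miRNA length")
    m = _encode(mirna)
    s = _encode(site)[::-1]
    return tuple(_CLS_NAME[c] for c in _PAIR_CLASS[m, s])


def find_targets(
    mirnas: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    max_mismatch: int = 4,
    max_gu: int = 4,
    protected_positions: tuple[int, ...] = (10, 11),
) -> list[TargetSite]:
    """Exhaustively scan transcripts for windows satisfying all rules.

    ``protected_positions`` are 1-based from the miRNA 5' end and must be
    Watson-Crick matches. All qualifying (possibly overlapping) sites are
    returned; per (miRNA, transcript) the site with the fewest
    mismatches + wobbles (leftmost on a tie) carries ``best=True``.
    A miRNA longer than a transcript simply yields no sites there.
    """
    sites: list[TargetSite] = []
    for mirna in mirnas:
        m = _encode(mirna.seq)
        k = len(m)
        prot = [p - 1 for p in protected_positions if 1 <= p <= k]
        for tr in transcripts:
            t = _encode(tr.seq)
            if len(t) < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(t, k)[:, ::-1]
            cls = _PAIR_CLASS[m[np.newaxis, :], windows]
            mm = (cls == _CLS_MM).sum(axis=1)
            gu = (cls == _CLS_GU).sum(axis=1)
            ok = (mm <= max_mismatch) & (gu <= max_gu)
            if prot:
                ok &= (cls[:, prot] == _CLS_MATCH).all(axis=1)
            found: list[TargetSite] = []
            for off in np.nonzero(ok)[0]:
                found.append(
                    TargetSite(
                        mirna_id=mirna.id, transcript_id=tr.id,
                        site_start=int(off), site_end=int(off) + k,
                        align=tuple(_CLS_NAME[c] for c in cls[off]),
                        mismatches=int(mm[off]), gu_pairs=int(gu[off]),
                        valid=True,
                    )
                )
            if found:
                ibest = min(
                    range(len(found)),
                    key=lambda i: (found[i].mismatches + found[i].gu_pairs,
                                   found[i].site_start),
                )
                found[ibest] = replace(found[ibest], best=True)
            sites.extend(found)
    return sites
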