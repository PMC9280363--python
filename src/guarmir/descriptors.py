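"""Precursor descriptor statistics: composition, MFE, MFEI and filters.

The minimal-folding-free-energy index

    MFEI = ((MFE / precursor length) * 100) / GC%

is the workhorse statistic separating pre-miRNA hairpins from other
structured RNAs (tRNA ~0.64, rRNA ~0.59, mRNA 0.62-0.66 in magnitude);
candidates are kept when |MFEI| clears a threshold (default 0.6), with a
stricter 0.85 flag marking high-confidence hairpins.

Energies are stored signed (negative); magnitudes appear only in reports,
matching the common "-kcal/mol" display convention. N bases are excluded
from both the AU% and GC% numerators and from their shared denominator,
the one convention under which AU% + GC% always sums to 100.

Two published descriptor tables for cluster bean (guar) EST-derived
miRNAs ship with the package as reference fixtures; see
:func:`load_descriptor_table` and :func:`load_mature_table`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from importlib import resources

from .precursor import PrecursorCandidate


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 rounds up in magnitude)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class Composition:
    n_a: int
    n_u: int
    n_g: int
    n_c: int
    n_n: int
    au_pct: float
    gc_pct: float
    au_ratio: float | None  # A/U, None when U count is 0
    cg_ratio: float | None  # C/G, None when G count is 0

    @property
    def length(self) -> int:
        return self.n_a + self.n_u + self.n_g + self.n_c + self.n_n


def composition(seq: str) -> Composition:
    """Base composition of a precursor sequence (T counted as U)."""
    if not seq:
        raise ValueError("composition of empty sequence")
    c = Counter(seq.upper().replace("T", "U"))
    bad = set(c) - set("AUGCN")
    if bad:
        raise ValueError(f"non-canonical characters: {sorted(bad)}")
    a, u, g, cc, n = c["A"], c["U"], c["G"], c["C"], c["N"]
    denom = a + u + g + cc
    au_pct = 100.0 * (a + u) / denom if denom else 0.0
    gc_pct = 100.0 * (g + cc) / denom if denom else 0.0
    return Composition(
        n_a=a, n_u=u, n_g=g, n_c=cc, n_n=n,
        au_pct=au_pct, gc_pct=gc_pct,
        au_ratio=a / u if u else None,
        cg_ratio=cc / g if g else None,
    )


def mfei(mfe: float, length: int, gc_pct: float) -> float | None:
    """Minimal folding free energy index; sign follows ``mfe``.

    Returns None (missing) when ``gc_pct`` is 0; raises on non-positive
    length.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_pct == 0:
        return None
    return ((mfe / length) * 100.0) / gc_pct


@dataclass(frozen=True)
class DescriptorRow:
    """The per-candidate (or per-family) descriptor bundle."""

    family: str
    n_a: int
    n_u: int
    n_g: int
    n_c: int
    n_n: int
    length: int
    au_pct: float
    gc_pct: float
    mfe: float
    mfei: float | None
    au_ratio: float | None = None
    cg_ratio: float | None = None
    est_id: str = ""
    mature_seq: str = ""
    mismatches: int = 0
    strict: bool = False


def describe(candidate: PrecursorCandidate, family: str,
             mature_seq: str = "", mismatches: int = 0) -> DescriptorRow:
    """Descriptor bundle for one selected precursor candidate."""
    comp = composition(candidate.seq)
    return DescriptorRow(
        family=family,
        n_a=comp.n_a, n_u=comp.n_u, n_g=comp.n_g, n_c=comp.n_c, n_n=comp.n_n,
        length=len(candidate.seq),
        au_pct=comp.au_pct, gc_pct=comp.gc_pct,
        mfe=candidate.fold.mfe,
        mfei=mfei(candidate.fold.mfe, len(candidate.seq), comp.gc_pct),
        au_ratio=comp.au_ratio, cg_ratio=comp.cg_ratio,
        est_id=candidate.est_id,
        mature_seq=mature_seq, mismatches=mismatches,
    )


def filter_candidates(
    rows: list[DescriptorRow],
    mfei_threshold: float = 0.6,
    strict_flag_threshold: float = 0.85,
) -> tuple[list[DescriptorRow], list[DescriptorRow]]:
    """Apply the MFEI filter cascade and collapse duplicate matures.

    A row is accepted when |MFEI| >= ``mfei_threshold`` (rows with missing
    MFEI are rejected). Within a family, rows sharing an identical mature
    sequence collapse to one representative: fewest mismatches against the
    reference, then lowest (most negative) MFE. Accepted rows carry
    ``strict=True`` when |MFEI| >= ``strict_flag_threshold``. Returns
    ``(accepted, rejected)``; the two lists partition the input.
    """
    passing: list[DescriptorRow] = []
    rejected: list[DescriptorRow] = []
    for row in rows:
        if row.mfei is not None and abs(row.mfei) >= mfei_threshold:
            passing.append(row)
        else:
            rejected.append(row)
    best: dict[tuple[str, str], DescriptorRow] = {}
    order: list[tuple[str, str]] = []
    for row in passing:
        key = (row.family, row.mature_seq)
        if key not in best:
            best[key] = row
            order.append(key)
        elif (row.mismatches, row.mfe) < (best[key].mismatches, best[key].mfe):
            rejected.append(best[key])
            best[key] = row
        else:
            rejected.append(row)
    accepted = [
        replace(best[k], strict=abs(best[k].mfei) >= strict_flag_threshold)
        for k in order
    ]
    return accepted, rejected


@dataclass(frozen=True)
class ColumnSummary:
    minimum: float
    maximum: float
    mean: float              # exact
    report_decimals: int = 2

    @property
    def mean_rounded(self) -> float:
        """Mean at the column's reporting precision (half away from zero)."""
        return round_half_away(self.mean, self.report_decimals)


@dataclass(frozen=True)
class DescriptorSummary:
    """Magnitude summaries over a descriptor table plus a mature-length
    histogram (empty when no rows carry mature sequences)."""

    n_rows: int
    mfe: ColumnSummary        # magnitudes, 1 dp means
    mfei: ColumnSummary       # magnitudes, 2 dp means
    au_pct: ColumnSummary
    gc_pct: ColumnSummary
    length: ColumnSummary     # mean reported to nearest integer
    mature_len_hist: dict[int, int]
    mature_len_mode: int | None


def _col(values: list[float], nd: int = 2) -> ColumnSummary:
    mean = sum(values) / len(values)
    return ColumnSummary(min(values), max(values), mean, nd)


def mature_length_mode(lengths: list[int]) -> tuple[dict[int, int], int]:
    """Histogram and mode of mature lengths (smallest length on a tie)."""
    hist = dict(sorted(Counter(lengths).items()))
    top = max(hist.values())
    mode = min(k for k, v in hist.items() if v == top)
    return hist, mode


def summarize(rows: list[DescriptorRow]) -> DescriptorSummary:
    """Column summaries over magnitudes. Means are exact; each column
    carries the reporting precision of the field's tables (MFE 1 dp, MFEI
    2 dp, length integer) for display via ``mean_rounded``."""
    if not rows:
        raise ValueError("summarize of empty descriptor table")
    lengths = [r.length for r in rows]
    mat = [len(r.mature_seq) for r in rows if r.mature_seq]
    hist: dict[int, int] = {}
    mode: int | None = None
    if mat:
        hist, mode = mature_length_mode(mat)
    return DescriptorSummary(
        n_rows=len(rows),
        mfe=_col([abs(r.mfe) for r in rows], 1),
        mfei=_col([abs(r.mfei) for r in rows if r.mfei is not None], 2),
        au_pct=_col([r.au_pct for r in rows], 2),
        gc_pct=_col([r.gc_pct for r in rows], 2),
        length=_col([float(r.length) for r in rows], 0),
        mature_len_hist=hist,
        mature_len_mode=mode,
    )


# ---------------------------------------------------------------------------
# Packaged reference fixtures (published cluster-bean descriptor tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaturePair:
    """A known reference mature and the predicted mature it identified."""

    est_id: str
    clone_id: str
    precursor_start: int  # 1-based inclusive, as published
    precursor_stop: int
    known_mature: str
    predicted_mature: str
    family: str
    homolog_id: str


def _data_lines(name: str) -> list[list[str]]:
    text = resources.files("guarmir.data").joinpath(name).read_text()
    lines = [ln.split("\t") for ln in text.strip().split("\n")]
    return lines[1:]


def load_descriptor_table() -> list[DescriptorRow]:
    """The packaged 57-family precursor descriptor table (as published)."""
    rows = []
    for cells in _data_lines("table1_descriptors.tsv"):
        (family, au_pct, gc_pct, n_a, n_u, n_g, n_c, n_n, length,
         mfe_s, mfei_s) = cells
        rows.append(
            DescriptorRow(
                family=family,
                n_a=int(n_a), n_u=int(n_u), n_g=int(n_g), n_c=int(n_c),
                n_n=int(n_n), length=int(length),
                au_pct=float(au_pct), gc_pct=float(gc_pct),
                mfe=float(mfe_s), mfei=float(mfei_s),
            )
        )
    return rows


def load_mature_table() -> list[MaturePair]:
    """The packaged 49-row known/predicted mature sequence table."""
    rows = []
    for cells in _data_lines("table4_matures.tsv"):
        est_id, clone, start, stop, known, pred, family, homolog = cells
        rows.append(
            MaturePair(
                est_id=est_id, clone_id=clone,
                precursor_start=int(start), precursor_stop=int(stop),
                known_mature=known, predicted_mature=pred,
                family=family, homolog_id=homolog,
            )
        )
    return rows
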