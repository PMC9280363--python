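"""RNA secondary-structure folding for precursor validation.

The built-in engine is a pair-energy dynamic program in the Nussinov
style: each admissible base pair contributes a fixed stacking-free energy
(G:C -3, A:U -2, G:U -1 kcal/mol) and the program returns the structure
minimising the total, subject to a minimum hairpin-loop size and a
maximum pair span. It is deliberately simple — deterministic, dependency
free and exactly reproducible — and every energy-based acceptance
statistic in this package is anchored on published descriptor fixtures
rather than on the engine. A thermodynamic engine (ViennaRNA) can be
plugged in behind the same contract when installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .homology import encode

#: default pair energies, kcal/mol, indexed by canonical base codes
DEFAULT_PAIR_ENERGY = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

_NUSSINOV_TAG = "nussinov-pair-energy"


@dataclass(frozen=True)
class FoldResult:
    """A dot-bracket structure with its folding free energy."""

    structure: str
    mfe: float  # kcal/mol, <= 0
    engine: str

    def __post_init__(self) -> None:
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


FoldEngine = Callable[[str], FoldResult]


def _energy_matrix(pair_energy: dict[str, float]) -> np.ndarray:
    # codes: A=0 C=1 G=2 T/U=3 N=4; 0.0 marks a non-pairable combination
    e = np.zeros((5, 5), dtype=np.float64)
    e[2, 1] = e[1, 2] = pair_energy["GC"]
    e[0, 3] = e[3, 0] = pair_energy["AU"]
    e[2, 3] = e[3, 2] = pair_energy["GU"]
    return e


@njit(cache=False)
def _nussinov_kernel(codes, min_loop, max_dist, pair_e):  # pragma: no cover
    n = codes.shape[0]
    E = np.zeros((n, n), dtype=np.float64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]
            kmax = min(j, i + max_dist)
            for k in range(i + min_loop + 1, kmax + 1):
                e = pair_e[codes[i], codes[k]]
                if e == 0.0:
                    continue
                cand = e
                if k - 1 >= i + 1:
                    cand += E[i + 1, k - 1]
                if k + 1 <= j:
                    cand += E[k + 1, j]
                if cand < best:
                    best = cand
            E[i, j] = best
    return E


def _traceback(E: np.ndarray, codes: np.ndarray, min_loop: int,
               max_dist: int, pair_e: np.ndarray) -> list[tuple[int, int]]:
    # Pairing is preferred over leaving i unpaired, with the leftmost
    # admissible partner, which makes the structure string deterministic.
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(codes) - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            best = E[i, j]
            kmax = min(j, i + max_dist)
            paired = False
            for k in range(i + min_loop + 1, kmax + 1):
                e = pair_e[codes[i], codes[k]]
                if e == 0.0:
                    continue
                cand = e
                if k - 1 >= i + 1:
                    cand += E[i + 1, k - 1]
                if k + 1 <= j:
                    cand += E[k + 1, j]
                if cand == best:
                    pairs.append((i, k))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1
    return pairs


def fold_nussinov(
    seq: str,
    min_loop: int = 3,
    max_pair_distance: int = 3000,
    pair_energy: dict[str, float] | None = None,
) -> FoldResult:
    """Fold ``seq`` with the built-in pair-energy dynamic program.

    Parameters
    ----------
    seq:
        Nucleotide sequence over {A,C,G,T,U,N}; N never pairs.
    min_loop:
        Minimum number of unpaired bases in every hairpin loop.
    max_pair_distance:
        Maximum sequence separation of a base pair.
    pair_energy:
        Energy per pair type in kcal/mol; defaults to
        :data:`DEFAULT_PAIR_ENERGY`.
    """
    pair_e = _energy_matrix(pair_energy or DEFAULT_PAIR_ENERGY)
    n = len(seq)
    if n < min_loop + 2:
        return FoldResult("." * n, 0.0, _NUSSINOV_TAG)
    codes = encode(seq)
    E = _nussinov_kernel(codes, min_loop, max_pair_distance, pair_e)
    pairs = _traceback(E, codes, min_loop, max_pair_distance, pair_e)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult("".join(db), float(E[0, n - 1]), _NUSSINOV_TAG)


def viennarna_engine(temperature: float = 37.0) -> FoldEngine:
    """Return a thermodynamic folding engine backed by ViennaRNA.

    Requires the ``RNA`` python bindings; raises ``ImportError`` otherwise.
    """
    import RNA  # noqa: optional dependency

    def fold(seq: str) -> FoldResult:
        md = RNA.md()
        md.temperature = temperature
        fc = RNA.fold_compound(seq.replace("T", "U"), md)
        structure, mfe = fc.mfe()
        return FoldResult(structure, float(mfe), f"viennarna@{temperature}C")

    return fold


# ---------------------------------------------------------------------------
# Structure inspection helpers
# ---------------------------------------------------------------------------

def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    stack: list[int] = []
    table: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            table[i] = j
            table[j] = i
    if stack:
        raise ValueError("unbalanced structure")
    return table


@dataclass(frozen=True)
class StemLoop:
    """One hairpin stem: nested pairs sharing a single terminal loop."""

    pairs: tuple[tuple[int, int], ...]  # outermost first, (i, j) with i < j
    loop_start: int  # first position of the terminal loop (inclusive)
    loop_end: int    # last position of the terminal loop (inclusive)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def max_internal_loop(self) -> int:
        """Largest bulge/interior-loop stretch between consecutive pairs."""
        worst = 0
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            worst = max(worst, i2 - i1 - 1, j1 - j2 - 1)
        return worst


def stem_loops(structure: str) -> list[StemLoop]:
    """Decompose a structure into its hairpin stem-loops.

    Each hairpin (innermost pair) is extended outward through directly
    nesting pairs until a multiloop branch point or the exterior is
    reached; bulges and interior loops are absorbed into the stem.
    """
    table = pair_table(structure)
    opens = sorted(i for i, j in table.items() if i < j)
    # children count per pair: number of pairs directly nested inside
    children: dict[int, list[int]] = {i: [] for i in opens}
    parent: dict[int, int | None] = {}
    stack: list[int] = []
    for pos, c in enumerate(structure):
        if c == "(":
            parent[pos] = stack[-1] if stack else None
            if stack:
                children[stack[-1]].append(pos)
            stack.append(pos)
        elif c == ")":
            stack.pop()
    loops: list[StemLoop] = []
    for i in opens:
        if children[i]:
            continue  # not a hairpin-closing pair
        j = table[i]
        chain = [(i, j)]
        p = parent[i]
        while p is not None and len(children[p]) == 1:
            chain.append((p, table[p]))
            p = parent[p]
        chain.reverse()
        loops.append(StemLoop(tuple(chain), loop_start=i + 1, loop_end=j - 1))
    return loops


def dominant_stem_loop(structure: str) -> StemLoop | None:
    """The stem-loop with the most pairs (leftmost hairpin on a tie)."""
    loops = stem_loops(structure)
    if not loops:
        return None
    return max(loops, key=lambda s: (s.n_pairs, -s.loop_start))
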