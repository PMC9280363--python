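"""Synthetic EST/transcript generation with ground-truth manifests.

Emulates the pipeline's real-world inputs — an EST collection harbouring
conserved miRNA hairpin precursors, and transcripts carrying
near-complementary miRNA binding sites — at desk scale, with every
planted feature recorded so recovery can be measured exactly. Background
sequence is i.i.d. uniform over {A,C,G,T} (GC bias is a parameter, never
an assumption), planted matures are perturbed by substitutions only, and
all randomness flows from one integer seed, making outputs byte-identical
across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .precursor import FIVE_PRIME, THREE_PRIME
from .seqio import SequenceRecord, write_table

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
_DNA_BASES = np.array(list("ACGT"))


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMP[c] for c in reversed(seq.upper().replace("T", "U")))


@dataclass(frozen=True)
class PlantedPrecursor:
    est_id: str
    window_start: int  # 0-based half-open on the EST
    window_end: int
    mature_seq: str  # the (possibly mutated) planted mature, RNA
    ref_id: str
    n_mutations: int
    mutated_positions: tuple[int, ...]
    arm: str


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    mirna_id: str
    mismatches: int
    gu_pairs: int


@dataclass
class TruthManifest:
    """Everything needed to score recovery and regenerate the dataset."""

    params: dict
    seed: int
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    """Manifest as TSV sections under a reproducibility header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# guarmir {__version__} truth manifest\n")
        fh.write(f"# seed={manifest.seed}\n")
        for k in sorted(manifest.params):
            fh.write(f"# {k}={manifest.params[k]}\n")
    for rows, row_type, suffix in (
        (manifest.planted_precursors, PlantedPrecursor, "precursors"),
        (manifest.planted_sites, PlantedSite, "sites"),
    ):
        section = path.with_name(f"{path.stem}.{suffix}.tsv")
        write_table(rows, section, row_type=row_type)


def make_hairpin(
    mature: str,
    loop_len: int = 8,
    arm: str = FIVE_PRIME,
    wobble_count: int = 0,
    seed: int = 0,
) -> str:
    """Construct a hairpin precursor around a mature miRNA (RNA, 5'->3').

    The star arm is the reverse complement of the mature with
    ``wobble_count`` substitutions that turn Watson-Crick pairs into G:U
    wobbles (possible only opposite mature G or U bases); the terminal
    loop is ``loop_len`` random bases. The mature occupies the requested
    arm.
    """
    mature = mature.upper().replace("T", "U")
    if not (19 <= len(mature) <= 25):
        raise ValueError(f"mature length {len(mature)} outside 19..25")
    if arm not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown arm {arm!r}")
    rng = np.random.default_rng(seed)
    star = list(revcomp_rna(mature))
    if wobble_count:
        L = len(mature)
        eligible = [p for p in range(L) if mature[p] in "GU"]
        if wobble_count > len(eligible):
            raise ValueError(
                f"cannot place {wobble_count} wobbles: only {len(eligible)} "
                "mature G/U positions"
            )
        chosen = rng.choice(len(eligible), size=wobble_count, replace=False)
        for ci in sorted(chosen):
            p = eligible[ci]
            star[L - 1 - p] = "U" if mature[p] == "G" else "G"
    loop = "".join(rng.choice(list("ACGU"), size=loop_len))
    star_s = "".join(star)
    if arm == FIVE_PRIME:
        return mature + loop + star_s
    return star_s + loop + mature


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA_BASES, size=n, p=p))


def _mutate_mature(
    mature: str, rng: np.random.Generator,
    mutation_rate: float, n_mutations: int | None,
) -> tuple[str, tuple[int, ...]]:
    bases = "ACGU"
    seq = list(mature)
    if n_mutations is not None:
        if n_mutations > len(seq):
            raise ValueError("more mutations requested than mature positions")
        positions = sorted(
            rng.choice(len(seq), size=n_mutations, replace=False).tolist()
        )
    else:
        positions = [
            p for p in range(len(seq)) if rng.random() < mutation_rate
        ]
    for p in positions:
        alternatives = [b for b in bases if b != seq[p]]
        seq[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq), tuple(positions)


def generate_est_set(
    references: list[SequenceRecord],
    n_ests: int = 200,
    est_len: int = 500,
    planted_fraction: float = 0.25,
    mutation_rate: float = 0.05,
    n_mutations: int | None = None,
    loop_len: int = 8,
    arm: str = FIVE_PRIME,
    gc_background: float = 0.5,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Generate an EST collection with planted hairpin precursors.

    The first ``round(planted_fraction * n_ests)`` ESTs each embed one
    hairpin built from a randomly chosen reference mature, mutated by
    per-base substitution at ``mutation_rate`` (or by exactly
    ``n_mutations`` substitutions when given), at a uniform random offset.
    Remaining ESTs are pure background.
    """
    if not references:
        raise ValueError("generate_est_set: empty reference set")
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_planted = round(planted_fraction * n_ests)
    params = dict(
        n_ests=n_ests, est_len=est_len, planted_fraction=planted_fraction,
        mutation_rate=mutation_rate, n_mutations=n_mutations,
        loop_len=loop_len, arm=arm, gc_background=gc_background,
    )
    manifest = TruthManifest(params=params, seed=seed)
    ests: list[SequenceRecord] = []
    width = max(4, len(str(n_ests)))
    for i in range(n_ests):
        est_id = f"synt_est_{i:0{width}d}"
        background = _random_dna(rng, est_len, gc_background)
        if i < n_planted:
            ref = references[rng.integers(len(references))]
            mutated, positions = _mutate_mature(
                ref.seq.replace("T", "U"), rng, mutation_rate, n_mutations)
            hp = make_hairpin(
                mutated, loop_len=loop_len, arm=arm,
                seed=int(rng.integers(2 ** 31)),
            )
            hp_dna = hp.replace("U", "T")
            if len(hp_dna) > est_len:
                raise ValueError("hairpin longer than est_len")
            off = int(rng.integers(est_len - len(hp_dna) + 1))
            seq = background[:off] + hp_dna + background[off + len(hp_dna):]
            manifest.planted_precursors.append(
                PlantedPrecursor(
                    est_id=est_id, window_start=off,
                    window_end=off + len(hp_dna), mature_seq=mutated,
                    ref_id=ref.id, n_mutations=len(positions),
                    mutated_positions=positions, arm=arm,
                )
            )
        else:
            seq = background
        ests.append(SequenceRecord(id=est_id, seq=seq, alphabet_hint="dna"))
    return ests, manifest


_PAIRS_WITH = {"A": "U", "U": "A", "G": "C", "C": "G"}  # miRNA base -> site RNA base


def generate_transcript_set(
    mirnas: list[SequenceRecord],
    n_transcripts: int = 50,
    transcript_len: int = 500,
    planted_sites_per_transcript: int = 1,
    perturbation: tuple[int, int] = (0, 0),
    protected_positions: tuple[int, ...] = (10, 11),
    perturb_protected: bool = False,
    gc_background: float = 0.5,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Generate transcripts with planted miRNA complementary sites.

    Each planted site is the reverse complement of a randomly chosen
    miRNA with exactly ``perturbation = (mismatches, gu_pairs)`` applied
    at random distinct positions, avoiding the protected (cleavage-site)
    miRNA positions unless ``perturb_protected`` is set. G:U wobbles can
    only be made opposite mature G or U bases; an infeasible request
    raises ``ValueError``.
    """
    if not mirnas:
        raise ValueError("generate_transcript_set: empty miRNA set")
    n_mm, n_gu = perturbation
    rng = np.random.default_rng(seed)
    params = dict(
        n_transcripts=n_transcripts, transcript_len=transcript_len,
        planted_sites_per_transcript=planted_sites_per_transcript,
        mismatches=n_mm, gu_pairs=n_gu, gc_background=gc_background,
        perturb_protected=perturb_protected,
    )
    manifest = TruthManifest(params=params, seed=seed)
    transcripts: list[SequenceRecord] = []
    width = max(4, len(str(n_transcripts)))
    for i in range(n_transcripts):
        tr_id = f"synt_tr_{i:0{width}d}"
        seq = _random_dna(rng, transcript_len, gc_background)
        taken: list[tuple[int, int]] = []
        for _ in range(planted_sites_per_transcript):
            mirna = mirnas[rng.integers(len(mirnas))]
            site, mm, gu = _perturbed_site(
                mirna.seq, n_mm, n_gu, protected_positions,
                perturb_protected, rng,
            )
            k = len(site)
            if k > transcript_len:
                raise ValueError("miRNA site longer than transcript")
            for _attempt in range(200):
                off = int(rng.integers(transcript_len - k + 1))
                if all(off + k <= s or off >= e for s, e in taken):
                    break
            else:
                raise ValueError("could not place non-overlapping site")
            taken.append((off, off + k))
            seq = seq[:off] + site + seq[off + k:]
            manifest.planted_sites.append(
                PlantedSite(
                    transcript_id=tr_id, site_start=off, site_end=off + k,
                    mirna_id=mirna.id, mismatches=mm, gu_pairs=gu,
                )
            )
        transcripts.append(
            SequenceRecord(id=tr_id, seq=seq, alphabet_hint="dna"))
    return transcripts, manifest


def _perturbed_site(
    mirna_seq: str, n_mm: int, n_gu: int,
    protected_positions: tuple[int, ...], perturb_protected: bool,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Build a site window (DNA, 5'->3') for one miRNA with exact
    mismatch/wobble counts. Site position L-1-p faces miRNA position p."""
    mirna = mirna_seq.upper().replace("T", "U")
    L = len(mirna)
    if n_mm + n_gu > L:
        raise ValueError("requested perturbations exceed miRNA length")
    site = [_PAIRS_WITH[c] for c in mirna]  # site base facing position p
    prot = set() if perturb_protected else {p - 1 for p in protected_positions}
    free = [p for p in range(L) if p not in prot]
    gu_ok = [p for p in free if mirna[p] in "GU"]
    if n_gu > len(gu_ok):
        raise ValueError("not enough G/U positions for requested wobbles")
    gu_pos = set(
        int(gu_ok[i]) for i in rng.choice(len(gu_ok), n_gu, replace=False)
    ) if n_gu else set()
    mm_pool = [p for p in free if p not in gu_pos]
    if n_mm > len(mm_pool):
        raise ValueError("not enough positions for requested mismatches")
    mm_pos = set(
        int(mm_pool[i]) for i in rng.choice(len(mm_pool), n_mm, replace=False)
    ) if n_mm else set()
    for p in gu_pos:
        site[p] = "U" if mirna[p] == "G" else "G"
    for p in mm_pos:
        wc = _PAIRS_WITH[mirna[p]]
        wobble = {"G": "U", "U": "G"}.get(mirna[p])
        options = [b for b in "ACGU" if b not in (wc, wobble)]
        site[p] = options[rng.integers(len(options))]
    # site string read 5'->3' on the transcript: reverse the facing order
    site_rna = "".join(reversed(site))
    return site_rna.replace("U", "T"), n_mm, n_gu
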