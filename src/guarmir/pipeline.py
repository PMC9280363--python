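"""Pipeline orchestration: clean -> scan -> fold/validate -> describe ->
filter -> targets -> phylogeny, with per-stage survivor counts logged.

The protein-coding/Rfam screening of full-scale EST studies is replaced
by a pluggable exclusion list (a file of EST ids to drop after
cleaning); external database searches are out of scope at desk scale.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .descriptors import (
    DescriptorRow, DescriptorSummary, describe, filter_candidates,
    load_descriptor_table, load_mature_table, mature_length_mode, mfei,
    round_half_away, summarize,
)
from .homology import HomologHit, scan_ests
from .precursor import PrecursorCandidate, fold_and_validate
from .seqio import SequenceRecord, clean_sequences, write_table
from .synth import TruthManifest
from .targets import TargetSite, find_targets
from .phylo import bootstrap_supports, progressive_msa

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage contract violation; the message names the failing stage."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study defaults."""

    max_mismatch: int = 4          # homology scan mismatch budget
    min_match: int = 18            # minimum reference mature length used
    mature_len_min: int = 19
    mature_len_max: int = 25
    flank: int = 300               # precursor window half-extent
    window_step: int = 25
    min_flank: int = 10
    min_loop: int = 3              # hairpin loop minimum, folding
    max_pair_distance: int = 3000
    max_bulge: int = 30            # largest bulge/interior loop tolerated
    max_duplex_mismatch: int = 5   # mature:star duplex budget
    mfei_threshold: float = 0.6    # |MFEI| acceptance threshold
    strict_flag_threshold: float = 0.85
    max_target_mismatch: int = 4
    max_gu: int = 4
    protected_positions: tuple[int, ...] = (10, 11)
    n_bootstrap: int = 1000
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in hints:
                raise ValueError(f"unknown config key {key!r}")
            t = hints[key]
            if t == "int":
                kwargs[key] = int(raw)
            elif t == "float":
                kwargs[key] = float(raw)
            elif "tuple" in str(t):
                kwargs[key] = tuple(int(x) for x in raw.split(",") if x)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    @classmethod
    def strict(cls, **overrides) -> "PipelineConfig":
        """Preset using the tighter 3-mismatch homology budget."""
        overrides.setdefault("max_mismatch", 3)
        return cls(**overrides)


@dataclass(frozen=True)
class HitRow:
    """Table form of a homology hit (1-based inclusive coordinates)."""

    est_id: str
    ref_id: str
    family: str
    start: int
    end: int
    strand: str
    mismatches: int
    match_len: int
    best: bool

    @classmethod
    def from_hit(cls, h: HomologHit) -> "HitRow":
        return cls(est_id=h.est_id, ref_id=h.ref_id, family=h.family,
                   start=h.est_start + 1, end=h.est_end, strand=h.strand,
                   mismatches=h.mismatches, match_len=h.match_len,
                   best=h.best)

    def to_hit(self) -> HomologHit:
        return HomologHit(est_id=self.est_id, ref_id=self.ref_id,
                          family=self.family, est_start=self.start - 1,
                          est_end=self.end, strand=self.strand,
                          mismatches=self.mismatches,
                          match_len=self.match_len, best=self.best)


@dataclass(frozen=True)
class CandidateRow:
    """Flat, table-writable form of a selected precursor candidate."""

    est_id: str
    family: str
    start: int  # 1-based inclusive, reporting convention
    end: int
    length: int
    structure: str
    mfe: float
    arm: str | None
    duplex_mismatches: int
    valid: bool
    reject_reasons: tuple[str, ...]


@dataclass(frozen=True)
class TargetRow:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    mismatches: int
    gu_pairs: int
    align: str  # glyph string: | match, o wobble, . mismatch
    best: bool


@dataclass
class PipelineResult:
    hits: list[HomologHit]
    candidates: list[tuple[HomologHit, PrecursorCandidate]]
    descriptors: list[DescriptorRow]
    accepted: list[DescriptorRow]
    rejected: list[DescriptorRow]
    summary: DescriptorSummary | None
    targets: list[TargetSite]
    newick: str | None
    stage_counts: dict[str, int]
    recovery: dict[str, float] = field(default_factory=dict)


def _predicted_mature(est: SequenceRecord, hit: HomologHit) -> str:
    return est.seq[hit.est_start:hit.est_end].replace("T", "U")


def run_pipeline(
    ests: list[SequenceRecord],
    matures: list[SequenceRecord],
    config: PipelineConfig | None = None,
    transcripts: list[SequenceRecord] | None = None,
    exclusion_ids: set[str] | None = None,
    manifest: TruthManifest | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run all stages in order and (optionally) write the result bundle.

    ``transcripts`` default to the cleaned ESTs themselves — target
    scanning against the same transcript set used for discovery, as in
    EST-only studies. With a synthetic truth ``manifest``, planted-feature
    recovery rates are computed into ``result.recovery``.
    """
    config = config or PipelineConfig()
    counts: dict[str, int] = {}

    if not ests:
        raise PipelineError("clean: no EST sequences supplied")
    kept, rejected_seqs = clean_sequences(ests)
    counts["input_ests"] = len(ests)
    counts["cleaned_ests"] = len(kept)
    if exclusion_ids:
        kept = [r for r in kept if r.id not in exclusion_ids]
        counts["after_exclusion"] = len(kept)
    if not kept:
        raise PipelineError("clean: all EST sequences rejected")
    mat_kept, _ = clean_sequences(matures)
    counts["cleaned_matures"] = len(mat_kept)
    if not mat_kept:
        raise PipelineError("clean: no usable reference matures")

    hits = scan_ests(
        kept, mat_kept,
        max_mismatch=config.max_mismatch, min_match=config.min_match,
        mature_len_range=(config.mature_len_min, config.mature_len_max),
    )
    counts["hits"] = len(hits)
    counts["hit_families"] = len({h.family for h in hits})
    best_hits = [h for h in hits if h.best]
    counts["best_hits"] = len(best_hits)

    by_id = {r.id: r for r in kept}
    candidates: list[tuple[HomologHit, PrecursorCandidate]] = []
    for hit in best_hits:
        cand = fold_and_validate(
            by_id[hit.est_id], hit,
            flank=config.flank, step=config.window_step,
            min_flank=config.min_flank,
            max_duplex_mismatch=config.max_duplex_mismatch,
            max_bulge=config.max_bulge, min_loop=config.min_loop,
            max_pair_distance=config.max_pair_distance,
        )
        if cand is not None:
            candidates.append((hit, cand))
    counts["folded_candidates"] = len(candidates)

    rows = [
        describe(cand, family=hit.family,
                 mature_seq=_predicted_mature(by_id[hit.est_id], hit),
                 mismatches=hit.mismatches)
        for hit, cand in candidates
    ]
    accepted, rejected_rows = filter_candidates(
        rows, mfei_threshold=config.mfei_threshold,
        strict_flag_threshold=config.strict_flag_threshold,
    )
    counts["accepted"] = len(accepted)
    counts["accepted_families"] = len({r.family for r in accepted})
    summary = summarize(accepted) if accepted else None

    tx = transcripts if transcripts is not None else kept
    mirna_records = [
        SequenceRecord(id=f"{r.family}|{r.est_id}", seq=r.mature_seq,
                       alphabet_hint="rna")
        for r in accepted
    ]
    targets = find_targets(
        mirna_records, tx,
        max_mismatch=config.max_target_mismatch, max_gu=config.max_gu,
        protected_positions=config.protected_positions,
    ) if mirna_records else []
    counts["target_sites"] = len(targets)

    newick = None
    if len(accepted) >= 3:
        labels, seen = [], set()
        seqs = []
        for hit, cand in candidates:
            key = f"{hit.family}|{hit.est_id}"
            if any(r.est_id == hit.est_id and r.family == hit.family
                   for r in accepted) and key not in seen:
                seen.add(key)
                labels.append(key)
                seqs.append(cand.seq)
        if len(labels) >= 3:
            msa = progressive_msa(labels, seqs)
            tree, _ = bootstrap_supports(
                labels, msa, n_reps=config.n_bootstrap, seed=config.seed)
            newick = tree.newick(with_support=True)

    result = PipelineResult(
        hits=hits, candidates=candidates, descriptors=rows,
        accepted=accepted, rejected=rejected_rows, summary=summary,
        targets=targets, newick=newick, stage_counts=counts,
    )
    if manifest is not None:
        result.recovery = _score_recovery(result, manifest)
    for stage, n in counts.items():
        log.info("stage %s: %d", stage, n)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _score_recovery(result: PipelineResult,
                    manifest: TruthManifest) -> dict[str, float]:
    """Fraction of planted features recovered by the pipeline."""
    out: dict[str, float] = {}
    planted = manifest.planted_precursors
    if planted:
        found = 0
        by_est: dict[str, list] = {}
        for hit, cand in result.candidates:
            by_est.setdefault(hit.est_id, []).append((hit, cand))
        for p in planted:
            for hit, cand in by_est.get(p.est_id, []):
                if cand.valid and hit.match_len == len(p.mature_seq):
                    found += 1
                    break
        out["precursor_recovery_pct"] = 100.0 * found / len(planted)
    sites = manifest.planted_sites
    if sites:
        reported = {
            (t.transcript_id, t.site_start, t.site_end) for t in result.targets
        }
        hit_n = sum(
            1 for s in sites
            if (s.transcript_id, s.site_start, s.site_end) in reported
        )
        out["target_recovery_pct"] = 100.0 * hit_n / len(sites)
    return out


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table([HitRow.from_hit(h) for h in result.hits],
                out_dir / "hits.tsv", row_type=HitRow)
    cand_rows = [
        CandidateRow(
            est_id=c.est_id, family=h.family,
            start=c.window_start + 1, end=c.window_end,
            length=c.length, structure=c.fold.structure, mfe=c.fold.mfe,
            arm=c.arm, duplex_mismatches=c.duplex_mismatches,
            valid=c.valid, reject_reasons=c.reject_reasons,
        )
        for h, c in result.candidates
    ]
    write_table(cand_rows, out_dir / "candidates.tsv", row_type=CandidateRow)
    write_table(result.descriptors, out_dir / "descriptors.tsv",
                row_type=DescriptorRow)
    write_table(result.accepted, out_dir / "accepted.tsv",
                row_type=DescriptorRow)
    target_rows = [
        TargetRow(
            mirna_id=t.mirna_id, transcript_id=t.transcript_id,
            start=t.site_start + 1, end=t.site_end,
            mismatches=t.mismatches, gu_pairs=t.gu_pairs,
            align=t.glyphs, best=t.best,
        )
        for t in result.targets
    ]
    write_table(target_rows, out_dir / "targets.tsv", row_type=TargetRow)
    if result.newick:
        (out_dir / "tree.nwk").write_text(result.newick + "\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"# guarmir {__version__}\n")
        for stage, n in result.stage_counts.items():
            fh.write(f"{stage}\t{n}\n")
        for k, v in result.recovery.items():
            fh.write(f"{k}\t{v:.2f}\n")


# ---------------------------------------------------------------------------
# Fixture verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CheckResult:
    name: str
    computed: float
    expected: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance


def verify_fixtures(
    descriptors: list[DescriptorRow] | None = None,
    matures=None,
) -> list[CheckResult]:
    """Recompute the reference-table statistics and compare each to its
    published value. Row lists default to the packaged fixtures; passing
    modified lists exercises fault detection."""
    rows = descriptors if descriptors is not None else load_descriptor_table()
    pairs = matures if matures is not None else load_mature_table()
    by_family = {r.family: r for r in rows}
    checks: list[CheckResult] = []

    # recomputed MFEI must reproduce the printed cell of its own row
    for family, decimals in (("miR1132", 2), ("miR2919", 3)):
        r = by_family[family]
        checks.append(CheckResult(
            f"mfei_{family}",
            round_half_away(mfei(r.mfe, r.length, r.gc_pct), decimals),
            r.mfei, 0.0))
    r = by_family["miR1132"]
    gc = 100.0 * (r.n_g + r.n_c) / (r.n_a + r.n_u + r.n_g + r.n_c)
    checks.append(CheckResult("gc_pct_miR1132_from_counts",
                              round_half_away(gc, 2), 37.14, 0.01))
    worst = max(abs(r.au_pct + r.gc_pct - 100.0) for r in rows)
    checks.append(CheckResult("au_plus_gc_max_deviation", worst, 0.0, 0.01))

    s = summarize(rows)
    checks.append(CheckResult("mfe_min", s.mfe.minimum, 5.8, 0.05))
    checks.append(CheckResult("mfe_max", s.mfe.maximum, 177.3, 0.05))
    checks.append(CheckResult("mfe_mean", s.mfe.mean, 25.4, 0.1))
    checks.append(CheckResult("mfei_min", s.mfei.minimum, 0.59, 0.005))
    checks.append(CheckResult("mfei_max", s.mfei.maximum, 1.36, 0.005))
    checks.append(CheckResult("au_pct_max", s.au_pct.maximum, 83.12, 0.01))
    checks.append(CheckResult("gc_pct_max", s.gc_pct.maximum, 60.45, 0.01))
    checks.append(CheckResult("precursor_len_mean", s.length.mean, 100.0, 0.5))

    _, mode = mature_length_mode([len(p.predicted_mature) for p in pairs])
    checks.append(CheckResult("mature_len_mode", float(mode), 21.0, 0.0))
    return checks
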