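import numpy as np
import pytest

from guarmir.seqio import SequenceRecord
from guarmir.synth import generate_transcript_set, revcomp_rna
from guarmir.targets import GU, MATCH, MISMATCH, classify_duplex, find_targets

from conftest import random_seq

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def oracle_classes(mirna: str, site: str):
    """Independent per-position lookup oracle for duplex classes."""
    m = mirna.upper().replace("T", "U")
    s = site.upper().replace("T", "U")
    out = []
    for i, base in enumerate(m):
        facing = s[len(s) - 1 - i]
        if (base, facing) in _WC:
            out.append(MATCH)
        elif (base, facing) in _WOBBLE:
            out.append(GU)
        else:
            out.append(MISMATCH)
    return tuple(out)


def oracle_scan(mirnas, transcripts, max_mismatch=4, max_gu=4,
                protected=(10, 11)):
    found = set()
    for mi in mirnas:
        k = len(mi.seq)
        for tr in transcripts:
            for off in range(len(tr.seq) - k + 1):
                cls = oracle_classes(mi.seq, tr.seq[off:off + k])
                mm = cls.count(MISMATCH)
                gu = cls.count(GU)
                if mm > max_mismatch or gu > max_gu:
                    continue
                if any(cls[p - 1] != MATCH for p in protected if p <= k):
                    continue
                found.add((mi.id, tr.id, off))
    return found


MIRNA = "UGACAGAAGAAAGAGAGCACA"  # 21 nt


def site_dna(mirna: str) -> str:
    return revcomp_rna(mirna).replace("U", "T")


class TestClassifyDuplex:
    def test_perfect_complement_all_match(self):
        assert set(classify_duplex(MIRNA, site_dna(MIRNA))) == {MATCH}

    def test_single_wobble_at_position_3(self):
        # facing base of miRNA position 3 (1-based) is site index L-3
        site = list(site_dna(MIRNA))
        assert MIRNA[2] == "A"  # A:U -> change facing U to ... no wobble for A
        # use position 1 (U) instead: facing A -> G makes U:G
        site[len(site) - 1] = "G"
        cls = classify_duplex(MIRNA, "".join(site))
        assert cls[0] == GU
        assert cls.count(GU) == 1 and cls.count(MISMATCH) == 0

    def test_n_is_a_mismatch(self):
        site = list(site_dna(MIRNA))
        site[5] = "N"
        cls = classify_duplex(MIRNA, "".join(site))
        assert cls.count(MISMATCH) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_duplex(MIRNA, "ACGT")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_lookup_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            m = random_seq(rng, 21, "ACGU")
            w = random_seq(rng, 21, "ACGTN")
            assert classify_duplex(m, w) == oracle_classes(m, w)


class TestFindTargets:
    def _mirna(self):
        return SequenceRecord(id="miRX", seq=MIRNA, alphabet_hint="rna")

    def test_planted_exact_site(self, rng):
        bg = random_seq(rng, 200)
        tr = SequenceRecord(id="t1", seq=bg[:80] + site_dna(MIRNA) + bg[101:])
        sites = find_targets([self._mirna()], [tr])
        planted = [s for s in sites if s.site_start == 80]
        assert len(planted) == 1
        assert planted[0].mismatches == 0 and planted[0].gu_pairs == 0
        assert planted[0].valid and planted[0].best

    def test_mismatch_at_cleavage_position_excludes_site(self):
        site = list(site_dna(MIRNA))
        facing_10 = len(site) - 10  # faces miRNA position 10 (1-based)
        base = MIRNA[9]
        # replace with a base that neither pairs nor wobbles with position 10
        bad = {"A": "C", "C": "A", "G": "G", "U": "U"}[base]
        site[facing_10] = bad.replace("U", "T")
        tr = SequenceRecord(id="t1", seq="".join(site))
        assert find_targets([self._mirna()], [tr]) == []
        # control: the same corruption at an unprotected position is tolerated
        site_ok = list(site_dna(MIRNA))
        site_ok[0] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site_ok[0]]
        tr_ok = SequenceRecord(id="t2", seq="".join(site_ok))
        assert len(find_targets([self._mirna()], [tr_ok])) == 1

    @pytest.mark.parametrize(
        "mm, gu, expected_found",
        [(4, 0, True), (5, 0, False), (0, 4, True), (0, 5, False),
         (4, 4, True)],
    )
    def test_rule_budget_boundaries(self, mm, gu, expected_found):
        refs = [self._mirna()]
        transcripts, manifest = generate_transcript_set(
            refs, n_transcripts=8, transcript_len=120,
            perturbation=(mm, gu), seed=11,
        )
        reported = {
            (s.transcript_id, s.site_start)
            for s in find_targets(refs, transcripts)
        }
        planted = {(p.transcript_id, p.site_start)
                   for p in manifest.planted_sites}
        if expected_found:
            assert planted <= reported
        else:
            assert not (planted & reported)

    def test_mirna_longer_than_transcript_is_empty(self):
        tr = SequenceRecord(id="t", seq="ACGT")
        assert find_targets([self._mirna()], [tr]) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mirnas = [SequenceRecord(id=f"m{i}", seq=random_seq(rng, 21, "ACGU"),
                                 alphabet_hint="rna") for i in range(3)]
        transcripts = [
            SequenceRecord(id=f"t{i}", seq=random_seq(rng, 300))
            for i in range(5)
        ]
        # plant a few perturbed sites so valid windows exist
        for i, mi in enumerate(mirnas):
            s = transcripts[i].seq
            planted = site_dna(mi.seq)
            transcripts[i] = SequenceRecord(
                id=transcripts[i].id,
                seq=s[:40] + planted + s[40 + len(planted):])
        got = {(s.mirna_id, s.transcript_id, s.site_start)
               for s in find_targets(mirnas, transcripts)}
        assert got == oracle_scan(mirnas, transcripts)

    def test_relaxing_budgets_is_monotone(self, rng):
        mirnas = [SequenceRecord(id="m", seq=MIRNA, alphabet_hint="rna")]
        transcripts, _ = generate_transcript_set(
            mirnas, n_transcripts=10, transcript_len=150,
            perturbation=(2, 2), seed=5)

        def keys(mm, gu):
            return {(s.transcript_id, s.site_start)
                    for s in find_targets(mirnas, transcripts,
                                          max_mismatch=mm, max_gu=gu)}

        assert keys(2, 2) <= keys(4, 2) <= keys(4, 4) <= keys(6, 6)

    def test_site_implies_bounded_hamming_to_revcomp(self, rng):
        # a reported site's reverse complement is within (mm+gu) of the miRNA
        from guarmir.homology import hamming_mismatches
        mirnas = [SequenceRecord(id="m", seq=MIRNA, alphabet_hint="rna")]
        transcripts, _ = generate_transcript_set(
            mirnas, n_transcripts=10, transcript_len=150,
            perturbation=(3, 2), seed=9)
        for s in find_targets(mirnas, transcripts):
            window = next(t.seq for t in transcripts
                          if t.id == s.transcript_id)[s.site_start:s.site_end]
            rc = revcomp_rna(window)
            assert hamming_mismatches(rc, MIRNA) <= s.mismatches + s.gu_pairs
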