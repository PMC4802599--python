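"""Known-miRNA matching, precursor extraction, folding DP, novel calling."""

import numpy as np
import pandas as pd
import pytest

import senmir
from senmir.annotate import (
    MIN_LOOP,
    PAIR_ENERGY,
    STACK_BONUS,
    NovelCriteria,
    evaluate_hairpin,
    passes_criteria,
)
from senmir.reads import TagTable
from senmir.util import revcomp

from conftest import random_seq

_PAIRABLE = set(PAIR_ENERGY)


# ---------------------------------------------------------------------------
# independent folding oracle: enumerate every nested structure explicitly
# ---------------------------------------------------------------------------

def enumerate_structures(seq, i, j):
    if j - i < MIN_LOOP + 1:
        yield frozenset()
        return
    yield from enumerate_structures(seq, i + 1, j)
    for k in range(i + MIN_LOOP + 1, j + 1):
        if (seq[i], seq[k]) in _PAIRABLE:
            for left in enumerate_structures(seq, i + 1, k - 1):
                for right in enumerate_structures(seq, k + 1, j):
                    yield left | right | {(i, k)}


def score_structure(seq, pairs):
    total = sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs)
    total += STACK_BONUS * sum(1 for i, j in pairs if (i + 1, j - 1) in pairs)
    return total


def brute_force_fold_score(seq):
    return min(
        score_structure(seq, s)
        for s in enumerate_structures(seq, 0, len(seq) - 1)
    )


class TestFoldHairpin:
    def test_perfect_inverted_repeat_fully_paired(self, rng):
        stem = random_seq(rng, 30)
        seq = stem + "A" * 8 + revcomp(stem)
        pairs, score = senmir.fold_hairpin(seq)
        expected = {(i, len(seq) - 1 - i) for i in range(30)}
        assert expected <= set(pairs)
        assert score <= -60  # 30 pairs at <= -1 each plus stacking

    def test_homopolymer_has_no_pairs(self):
        pairs, score = senmir.fold_hairpin("A" * 40)
        assert pairs == [] and score == 0.0

    def test_pairing_is_nested_and_valid(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 40)
            pairs, score = senmir.fold_hairpin(seq)
            for i, j in pairs:
                assert j - i > MIN_LOOP
                assert (seq[i], seq[j]) in _PAIRABLE
            for (i, j) in pairs:
                for (k, l) in pairs:
                    assert not (i < k < j < l)  # no pseudoknots
            assert score_structure(seq, set(pairs)) == pytest.approx(score)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            seq = random_seq(rng, int(rng.integers(8, 17)))
            _, score = senmir.fold_hairpin(seq)
            assert score == pytest.approx(brute_force_fold_score(seq))

    def test_matches_exhaustive_enumeration_at_25nt(self, rng):
        for _ in range(3):
            seq = random_seq(rng, 25)
            _, score = senmir.fold_hairpin(seq)
            assert score == pytest.approx(brute_force_fold_score(seq))

    def test_rejects_bad_alphabet_and_oversize(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            senmir.fold_hairpin("ACGTX")
        with pytest.raises(ValueError, match="longer"):
            senmir.fold_hairpin("A" * 301)


class TestIsomirMatching:
    MATURE = "TGACAGAAGAGAGTGAGCACA"  # 21 nt

    def _reference(self):
        return [("zma-miR156a MIMAT0000001", self.MATURE)]

    def _assign(self, tag):
        table = TagTable(counts=pd.DataFrame({"lib": [1]}, index=[tag]))
        _, assignment = senmir.annotate_known(table, self._reference())
        return assignment.get(tag)

    def test_identical_tag_assigned(self):
        assert self._assign(self.MATURE) == "zma-miR156a"

    def test_all_end_shift_variants_within_two_assigned(self, rng):
        # constructive oracle: every <=2-nt end-shifted variant must match
        for d5 in range(-2, 3):
            for d3 in range(-2, 3):
                tag = self.MATURE
                tag = tag[d5:] if d5 > 0 else random_seq(rng, -d5) + tag
                tag = tag[:len(tag) + d3] if d3 < 0 else tag + random_seq(rng, d3)
                assert self._assign(tag) == "zma-miR156a", (d5, d3)

    def test_three_nt_shift_rejected(self):
        assert self._assign(self.MATURE[3:]) is None
        assert self._assign(self.MATURE + "ACG") is None

    def test_internal_mismatch_rejected(self):
        tag = self.MATURE[:10] + ("A" if self.MATURE[10] != "A" else "C") \
            + self.MATURE[11:]
        assert self._assign(tag) is None

    def test_counts_of_assigned_tags_summed(self):
        tags = [self.MATURE, self.MATURE[1:], self.MATURE + "G"]
        table = TagTable(
            counts=pd.DataFrame({"lib": [5, 2, 1]}, index=tags)
        )
        records, _ = senmir.annotate_known(table, self._reference())
        assert records[0].counts == {"lib": 8}

    def test_family_parsed_from_id(self):
        assert senmir.parse_family("zma-miR159a-3p") == "zma-miR159"
        assert senmir.parse_family("novel-1") == "novel-1"

    def test_duplicate_reference_ids_rejected(self):
        ref = self._reference() * 2
        table = TagTable(counts=pd.DataFrame({"lib": [1]}, index=[self.MATURE]))
        with pytest.raises(ValueError, match="duplicate"):
            senmir.annotate_known(table, ref)


class TestExtractPrecursor:
    def test_windows_equal_direct_slice(self, rng):
        genome = {"chr": random_seq(rng, 10_000)}
        tag_len, flank = 21, 150
        windows = senmir.extract_precursor(("chr", 5000, "+"), genome,
                                           tag_len, flank)
        by_orient = {w["orientation"]: w for w in windows}
        assert by_orient["5p"]["sequence"] == genome["chr"][5000:5000 + 21 + 150]
        assert by_orient["3p"]["sequence"] == genome["chr"][5000 - 150:5021]
        assert all(len(w["sequence"]) == tag_len + flank for w in windows)
        assert not any(w["truncated"] for w in windows)

    def test_minus_strand_windows_reverse_complemented(self, rng):
        genome = {"chr": random_seq(rng, 2_000)}
        windows = senmir.extract_precursor(("chr", 1000, "-"), genome, 20, 100)
        by_orient = {w["orientation"]: w for w in windows}
        assert by_orient["5p"]["sequence"] == revcomp(genome["chr"][900:1020])
        assert by_orient["3p"]["sequence"] == revcomp(genome["chr"][1000:1120])
        # tag occupies the first tag_len bases of the 5p-orientation window
        w = by_orient["5p"]
        assert w["sequence"][w["tag_offset"]:w["tag_offset"] + 20] == revcomp(
            genome["chr"][1000:1020]
        )

    def test_truncation_at_reference_start_flagged(self, rng):
        genome = {"chr": random_seq(rng, 300)}
        windows = senmir.extract_precursor(("chr", 10, "+"), genome, 20, 150)
        by_orient = {w["orientation"]: w for w in windows}
        assert by_orient["3p"]["truncated"]
        assert by_orient["3p"]["sequence"] == genome["chr"][0:30]


class TestNovelCalling:
    def _planted_table(self, study):
        novel = [m for m in study.truth.mirnas if m.status == "novel"]
        counts = pd.DataFrame(
            {"lib": [10] * len(novel)}, index=[m.mature for m in novel]
        )
        table = TagTable(counts=counts)
        return senmir.map_tags(table, study.genome), novel

    def test_planted_hairpins_recovered_exactly(self, small_study):
        table, novel = self._planted_table(small_study)
        calls = senmir.call_novel_mirnas(table, small_study.genome)
        assert len(calls) == len(novel)
        called = {(r.mature, r.locus) for r in calls}
        expected = {
            (m.mature, ("chr1", m.mature_start, m.mature_end, m.strand))
            for m in novel
        }
        assert called == expected

    def test_calls_are_deterministic(self, small_study):
        table, _ = self._planted_table(small_study)
        a = senmir.call_novel_mirnas(table, small_study.genome)
        b = senmir.call_novel_mirnas(table, small_study.genome)
        assert [(r.mirna_id, r.mature, r.locus) for r in a] == [
            (r.mirna_id, r.mature, r.locus) for r in b
        ]

    def test_majority_of_calls_are_20_to_23_nt(self, small_study):
        table, _ = self._planted_table(small_study)
        calls = senmir.call_novel_mirnas(table, small_study.genome)
        frac = np.mean([20 <= len(r.mature) <= 23 for r in calls])
        assert frac > 0.5

    def test_loop_spanning_tag_rejected(self, rng):
        stem = random_seq(rng, 25)
        hairpin = stem + "AACCAAT" + revcomp(stem)
        window = random_seq(rng, 60) + hairpin + random_seq(rng, 60)
        lo = 60 + 15  # tag covers stem end + entire loop + star start
        cand = evaluate_hairpin(window, (lo, lo + 21))
        assert not passes_criteria(cand, NovelCriteria())

    def test_arm_resident_tag_accepted(self, rng):
        stem = random_seq(rng, 25)
        hairpin = stem + "AACCAAT" + revcomp(stem)
        window = random_seq(rng, 60) + hairpin + random_seq(rng, 60)
        cand = evaluate_hairpin(window, (62, 62 + 21))  # inside the 5' arm
        assert cand.arm == "5p"
        assert passes_criteria(cand, NovelCriteria())

    def test_random_windows_mostly_rejected(self, rng):
        # random sequence occasionally contains miRNA-like foldbacks, so the
        # criteria are discriminative statistically, not absolutely
        rejected = 0
        n = 40
        for _ in range(n):
            window = random_seq(rng, 200)
            lo = int(rng.integers(30, 150))
            cand = evaluate_hairpin(window, (lo, lo + 21))
            rejected += not passes_criteria(cand, NovelCriteria())
        assert rejected / n >= 0.6


def test_known_novel_partition(small_study):
    """A mapped candidate tag is known, novel, or unclassified - never two."""
    mature_ref = small_study.mature_reference
    tags = [m.mature for m in small_study.truth.mirnas]
    counts = pd.DataFrame({"lib": [1] * len(tags)}, index=tags)
    table = senmir.map_tags(TagTable(counts=counts), small_study.genome)
    _, assignment = senmir.annotate_known(table, mature_ref)
    unassigned = table.subset([t for t in table.tags if t not in assignment])
    novel = senmir.call_novel_mirnas(unassigned, small_study.genome)
    novel_tags = {r.mature for r in novel}
    assert set(assignment) & novel_tags == set()
    known_planted = {m.mature for m in small_study.truth.mirnas
                     if m.status == "known"}
    assert set(assignment) == known_planted
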