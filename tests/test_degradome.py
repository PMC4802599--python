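"""Duplex scoring, target-site search, tag profiles and category calls."""

import numpy as np
import pandas as pd
import pytest

import senmir
from senmir.degradome import (
    GAP_PENALTY,
    MISMATCH_PENALTY,
    SEED_REGION,
    SEED_WEIGHT,
    WOBBLE_PENALTY,
    cleavage_position,
)
from senmir.util import revcomp

from conftest import random_seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
WOBBLE = {("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# literal-transcription oracle for duplex scoring
# ---------------------------------------------------------------------------

def oracle_weight(k: int) -> float:
    return SEED_WEIGHT if SEED_REGION[0] <= k <= SEED_REGION[1] else 1.0


def oracle_pair_penalty(m: str, t: str) -> float:
    if COMPLEMENT[m] == t:
        return 0.0
    if (m, t) in WOBBLE:
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def oracle_score(mirna: str, site: str) -> float | None:
    """Brute-force best score over all allowed single-gap placements."""
    L = len(mirna)
    rev = site[::-1]
    if len(site) == L:
        return sum(
            oracle_pair_penalty(mirna[k - 1], rev[k - 1]) * oracle_weight(k)
            for k in range(1, L + 1)
        )
    if len(site) == L - 1:
        best = None
        for g in range(1, L + 1):  # miRNA position g bulged
            s = GAP_PENALTY * oracle_weight(g)
            si = 0
            for k in range(1, L + 1):
                if k == g:
                    continue
                s += oracle_pair_penalty(mirna[k - 1], rev[si]) * oracle_weight(k)
                si += 1
            best = s if best is None else min(best, s)
        return best
    if len(site) == L + 1:
        best = None
        for g in range(1, L):  # unpaired site base after miRNA position g;
            # the gap penalty is charged at the 3'-adjacent position g+1
            s = GAP_PENALTY * oracle_weight(g + 1)
            for k in range(1, L + 1):
                si = k - 1 if k <= g else k
                s += oracle_pair_penalty(mirna[k - 1], rev[si]) * oracle_weight(k)
            best = s if best is None else min(best, s)
        return best
    return None


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self, rng):
        m = random_seq(rng, 21)
        d = senmir.score_duplex(m, revcomp(m))
        assert d.score == 0.0
        assert set(d.states) == {"match"}

    def test_mismatch_position_weighting(self):
        m = "A" * 21
        site = list(revcomp(m))  # all T... site 5'->3' is T*21
        # mismatch at miRNA position 1 = site's 3'-most base
        s1 = site.copy()
        s1[-1] = "C"
        assert senmir.score_duplex(m, "".join(s1)).score == 1.0
        # mismatch at miRNA position 10 (doubled region)
        s10 = site.copy()
        s10[len(site) - 10] = "C"
        assert senmir.score_duplex(m, "".join(s10)).score == 2.0

    def test_wobble_at_position_five_scores_one(self):
        m = "AAAA" + "G" + "A" * 16  # position 5 is G
        site = list(revcomp(m))
        site[len(site) - 5] = "T"  # G:U wobble at position 5 (doubled x0.5)
        assert senmir.score_duplex(m, "".join(site)).score == 1.0

    def test_length_difference_beyond_one_gap_rejected(self, rng):
        m = random_seq(rng, 21)
        assert senmir.score_duplex(m, random_seq(rng, 24)) is None

    def test_matches_literal_oracle_on_random_duplexes(self, rng):
        for _ in range(300):
            L = int(rng.integers(18, 25))
            m = random_seq(rng, L)
            site = random_seq(rng, L + int(rng.integers(-1, 2)))
            d = senmir.score_duplex(m, site)
            assert d.score == pytest.approx(oracle_score(m, site))

    def test_adding_a_mismatch_never_decreases_score(self, rng):
        for _ in range(50):
            m = random_seq(rng, 21)
            site = list(revcomp(m))
            base = senmir.score_duplex(m, "".join(site)).score
            k = int(rng.integers(0, 21))
            mutated = site.copy()
            mutated[k] = {"A": "C", "C": "A", "G": "A", "T": "C"}[mutated[k]]
            assert senmir.score_duplex(m, "".join(mutated)).score >= base


def oracle_find_sites(mirna: str, transcript: str, max_score: float):
    """Exhaustive all-window scoring, same conventions as the implementation."""
    L = len(mirna)
    found = []
    for wlen in (L, L - 1, L + 1):
        for s0 in range(0, len(transcript) - wlen + 1):
            site = transcript[s0:s0 + wlen]
            d = senmir.score_duplex(mirna, site)
            if d is not None and d.score <= max_score:
                found.append((s0, wlen, d.score))
    return found


class TestFindTargetSites:
    def test_embedded_reverse_complement_found_with_zero_score(self, rng):
        m = random_seq(rng, 21)
        tx = random_seq(rng, 200) + revcomp(m) + random_seq(rng, 200)
        sites = senmir.find_target_sites("mir", m, {"t": tx}, max_score=0.0)
        exact = [s for s in sites if s.score == 0.0]
        assert len(exact) == 1
        aln = exact[0]
        assert aln.window_start == 200
        # cleavage: transcript base pairing miRNA position 10, 1-based
        assert aln.cleavage_pos == 200 + 21 - 9

    def test_site_set_matches_exhaustive_scan(self, rng):
        for trial in range(5):
            m = random_seq(rng, 20)
            tx = random_seq(rng, 400) + revcomp(m) + random_seq(rng, 100)
            # plant a one-mismatch site too
            near_site = list(revcomp(m))
            near_site[7] = {"A": "C", "C": "A", "G": "A", "T": "C"}[near_site[7]]
            tx += "".join(near_site) + random_seq(rng, 50)
            max_score = 4.0
            sites = senmir.find_target_sites("mir", m, {"t": tx}, max_score)
            oracle = oracle_find_sites(m, tx, max_score)
            # every oracle window is represented by a reported cleavage site
            reported = {(a.window_start, a.window_end - a.window_start)
                        for a in sites}
            for s0, wlen, score in oracle:
                d = senmir.score_duplex(m, tx[s0:s0 + wlen])
                cp = cleavage_position(s0, wlen, d)
                assert any(a.cleavage_pos == cp and a.score <= score
                           for a in sites), (trial, s0, wlen, score)
            # and every reported site has an oracle witness
            for a in sites:
                assert any(
                    s0 == a.window_start and wlen == a.window_end - a.window_start
                    and score == pytest.approx(a.score)
                    for s0, wlen, score in oracle
                )

    def test_planted_truth_sites_recovered(self, small_study):
        mature = {m.mirna_id: m.mature for m in small_study.truth.mirnas}
        for mid, tx_id, pos in small_study.truth.cleavage_sites:
            sites = senmir.find_target_sites(
                mid, mature[mid], {tx_id: small_study.transcripts[tx_id]}, 4.0
            )
            assert any(a.cleavage_pos == pos and a.score == 0.0 for a in sites)

    def test_deterministic_ordering(self, rng):
        m = random_seq(rng, 21)
        txs = {f"t{i}": random_seq(rng, 300) + revcomp(m) for i in range(3)}
        sites = senmir.find_target_sites("mir", m, txs, 4.0)
        keys = [(a.transcript_id, a.cleavage_pos) for a in sites]
        assert keys == sorted(keys)


class TestTagProfile:
    def test_single_tag_increments_one_based_position(self, rng):
        tx = random_seq(rng, 200)
        tag = tx[57:93]
        profiles = senmir.build_tag_profile([tag], {"t": tx})
        assert profiles["t"][57] == 1  # 0-based 57 == 1-based 58
        assert profiles["t"].sum() == 1

    def test_total_mass_equals_matched_tags(self, rng):
        tx = random_seq(rng, 300)
        tags = [tx[i:i + 36] for i in (0, 50, 50, 100)] + [random_seq(rng, 36)]
        profiles = senmir.build_tag_profile(tags, {"t": tx})
        assert profiles["t"].sum() == 4

    def test_profiles_match_independent_recount(self, rng):
        txs = {f"t{i}": random_seq(rng, 250) for i in range(3)}
        tags = []
        for tx in txs.values():
            for _ in range(20):
                p = int(rng.integers(0, 214))
                tags.append(tx[p:p + 36])
        profiles = senmir.build_tag_profile(tags, txs)
        for tx_id, seq in txs.items():
            recount = np.zeros(len(seq), dtype=int)
            for tag in tags:
                for p in range(len(seq) - len(tag) + 1):
                    if seq[p:p + len(tag)] == tag:
                        recount[p] += 1
            assert (profiles[tx_id] == recount).all()


def oracle_category(profile: np.ndarray, pos1: int) -> int:
    """Literal transcription of the category rules."""
    c = profile[pos1 - 1]
    assert c >= 1
    if c == 1:
        return 4
    mx = profile.max()
    if c == mx and (profile == mx).sum() == 1:
        return 0
    if c == mx:
        return 1
    if c > np.median(profile[profile > 0]):
        return 2
    return 3


class TestAssignCategory:
    def test_unique_max_above_one_is_category_zero(self):
        profile = np.zeros(100, dtype=int)
        profile[57] = 10
        assert senmir.assign_category(profile, 58) == 0

    def test_count_one_is_category_four_regardless(self):
        profile = np.zeros(50, dtype=int)
        profile[10] = 1
        profile[20] = 30
        assert senmir.assign_category(profile, 11) == 4

    def test_shared_max_is_category_one(self):
        profile = np.zeros(50, dtype=int)
        profile[10] = profile[30] = 7
        assert senmir.assign_category(profile, 11) == 1

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            senmir.assign_category(np.zeros(10, dtype=int), 5)

    def test_thousand_random_profiles_match_literal_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(20, 120))
            profile = rng.poisson(0.5, size=n).astype(int)
            hot = rng.integers(0, n, size=3)
            profile[hot] += rng.integers(1, 20, size=3).astype(int)
            pos_candidates = np.nonzero(profile > 0)[0]
            pos1 = int(rng.choice(pos_candidates)) + 1
            assert senmir.assign_category(profile, pos1) == oracle_category(
                profile, pos1
            )


class TestFunctionClassification:
    def test_three_of_ten_is_thirty_percent(self):
        hits = pd.DataFrame({"transcript_id": [f"t{i}" for i in range(10)]})
        ann = pd.DataFrame({
            "transcript_id": [f"t{i}" for i in range(10)],
            "functional_class": ["transcriptional regulator"] * 3 + ["other"] * 7,
        })
        pct = senmir.classify_target_function(hits, ann)
        row = pct[pct["functional_class"] == "transcriptional regulator"]
        assert row["percentage"].iloc[0] == pytest.approx(30.0)

    def test_single_class_is_hundred_percent(self):
        hits = pd.DataFrame({"transcript_id": ["a", "a", "b"]})
        ann = pd.DataFrame({
            "transcript_id": ["a", "b"],
            "functional_class": ["other", "other"],
        })
        pct = senmir.classify_target_function(hits, ann)
        assert pct["percentage"].iloc[0] == pytest.approx(100.0)
        assert pct["percentage"].sum() == pytest.approx(100.0)

    def test_hand_counted_twenty_row_fixture(self):
        classes = (["transcriptional regulator"] * 6
                   + ["translational regulator"] * 4
                   + ["metabolic enzyme"] * 3
                   + ["signal transducer"] * 2
                   + ["stress responder"] * 1
                   + ["other"] * 4)
        ann = pd.DataFrame({
            "transcript_id": [f"t{i}" for i in range(20)],
            "functional_class": classes,
        })
        hits = pd.DataFrame({"transcript_id": [f"t{i}" for i in range(20)] * 2})
        pct = senmir.classify_target_function(hits, ann).set_index(
            "functional_class"
        )["percentage"]
        assert pct["transcriptional regulator"] == pytest.approx(30.0)
        assert pct["translational regulator"] == pytest.approx(20.0)
        assert pct["stress responder"] == pytest.approx(5.0)

    def test_unannotated_transcript_named(self):
        hits = pd.DataFrame({"transcript_id": ["mystery"]})
        ann = pd.DataFrame({"transcript_id": ["a"], "functional_class": ["other"]})
        with pytest.raises(KeyError, match="mystery"):
            senmir.classify_target_function(hits, ann)


def test_category_partition_exhaustive(rng):
    """Every profile with signal at the site yields exactly one category 0-4."""
    for _ in range(200):
        profile = rng.poisson(1.0, size=60).astype(int)
        profile[25] += 1
        cat = senmir.assign_category(profile, 26)
        assert cat in (0, 1, 2, 3, 4)
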