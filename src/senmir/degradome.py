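"""Degradome (PARE) target identification and cleavage-site category calling.

A miRNA target site is scored with plant-style complementarity penalties:
mismatch 1.0, G:U wobble 0.5, gap 1.0 (at most one gap), all penalties
doubled across miRNA positions 2-13 (5' end = position 1).  Alignments with
penalty S <= max_score (default 4.0) are candidate sites; the predicted
cleavage position is the transcript base pairing miRNA position 10, reported
1-based.  Degradome tags mark uncapped 5' ends: their per-transcript
5'-end count profile classifies each site into categories 0-4 relative to
the transcript-wide maximum and the median over positions with >= 1 read.

Orientation convention: both miRNA and site are given 5'->3'; miRNA
position k pairs the k-th base from the site's 3' end.  A gap is either a
bulged miRNA base (site one nucleotide shorter) or an unpaired site base
(one longer); the gap penalty is charged at the bulged miRNA position, or
for a site bulge at the miRNA position 3' of the insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 1.0
SEED_REGION = (2, 13)  # inclusive, 1-based miRNA positions with doubled penalty
SEED_WEIGHT = 2.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# penalty[mirna_base, target_base]: Watson-Crick 0, G:U wobble 0.5, else 1
_PAIR_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
for _m, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0.0
for _m, _t in (("G", "T"), ("T", "G")):  # G:U / U:G in RNA terms
    _PAIR_PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = WOBBLE_PENALTY


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper().replace("U", "T")],
                        dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGU(T) character in sequence: {exc}") from exc


def position_weights(length: int) -> np.ndarray:
    """Per-miRNA-position penalty weights (position 1 = 5' end)."""
    w = np.ones(length)
    lo, hi = SEED_REGION
    w[lo - 1:hi] = SEED_WEIGHT
    return w


@dataclass
class DuplexAlignment:
    """One scored miRNA:site duplex."""

    states: tuple[str, ...]  # per miRNA position: match|wobble|mismatch|gap
    score: float
    gap: str  # "none" | "mirna" | "target"
    gap_pos: int | None  # miRNA gap: bulged position (1-based);
    #                      target gap: insertion after this miRNA position


def score_duplex(mirna: str, site: str) -> DuplexAlignment | None:
    """Score a miRNA against a candidate site; None if >1 gap is needed.

    Site length equal to the miRNA scores gaplessly; one shorter bulges one
    miRNA base out; one longer leaves one site base unpaired.  The single
    gap is placed to minimize the penalty.
    """
    m = _encode(mirna)
    s = _encode(site)[::-1]  # index k-1 pairs miRNA position k
    L = len(m)
    w = position_weights(L)
    diff = len(s) - L
    if diff == 0:
        raw = _PAIR_PENALTY[m, s]
        return DuplexAlignment(_states(raw), float((raw * w).sum()), "none", None)
    if diff == -1:
        best = None
        for g in range(L):  # miRNA position g+1 bulged out
            keep = np.delete(np.arange(L), g)
            raw = _PAIR_PENALTY[m[keep], s]
            pen = float((raw * w[keep]).sum() + GAP_PENALTY * w[g])
            if best is None or pen < best.score:
                states = list(_states(raw))
                states.insert(g, "gap")
                best = DuplexAlignment(tuple(states), pen, "mirna", g + 1)
        return best
    if diff == 1:
        best = None
        for g in range(1, L):  # unpaired site base after miRNA position g
            s_keep = np.concatenate([s[:g], s[g + 1:]])
            raw = _PAIR_PENALTY[m, s_keep]
            pen = float((raw * w).sum() + GAP_PENALTY * w[g])
            if best is None or pen < best.score:
                best = DuplexAlignment(_states(raw), pen, "target", g)
        return best
    return None


def _states(raw: np.ndarray) -> tuple[str, ...]:
    out = []
    for p in raw:
        if p == 0.0:
            out.append("match")
        elif p == WOBBLE_PENALTY:
            out.append("wobble")
        else:
            out.append("mismatch")
    return tuple(out)


def cleavage_position(window_start: int, window_len: int,
                      duplex: DuplexAlignment) -> int:
    """1-based transcript coordinate pairing miRNA position 10.

    With miRNA position 10 itself bulged, the cut is taken 5' of the base
    pairing position 9 (the start of the 3' cleavage fragment).
    """
    if duplex.gap == "none":
        x = 9  # 0-based index from the site's 3' end
    elif duplex.gap == "mirna":
        g = duplex.gap_pos
        x = 9 if 10 < g else (8 if 10 > g else 8)
    else:  # target gap after miRNA position g
        x = 9 if 10 <= duplex.gap_pos else 10
    return window_start + window_len - 1 - x + 1


@dataclass
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    window_start: int  # 0-based transcript coordinate of the site
    window_end: int
    score: float
    states: tuple[str, ...]
    cleavage_pos: int  # 1-based
    gap: str


def _window_scores(m: np.ndarray, t: np.ndarray, w: np.ndarray,
                   wlen: int) -> np.ndarray | None:
    """Best penalty for every transcript window of length ``wlen``.

    Vectorized over windows; gap placements are enumerated and minimized.
    """
    L = len(m)
    if len(t) < wlen or wlen < 1:
        return None
    win = np.lib.stride_tricks.sliding_window_view(t, wlen)[:, ::-1]
    if wlen == L:
        return (_PAIR_PENALTY[m[None, :], win] * w).sum(axis=1)
    if wlen == L - 1:
        best = None
        for g in range(L):
            keep = np.delete(np.arange(L), g)
            pen = (_PAIR_PENALTY[m[keep][None, :], win] * w[keep]).sum(axis=1)
            pen = pen + GAP_PENALTY * w[g]
            best = pen if best is None else np.minimum(best, pen)
        return best
    if wlen == L + 1:
        best = None
        cols = np.arange(wlen)
        for g in range(1, L):
            keep = cols[cols != g]
            pen = (_PAIR_PENALTY[m[None, :], win[:, keep]] * w).sum(axis=1)
            pen = pen + GAP_PENALTY * w[g]
            best = pen if best is None else np.minimum(best, pen)
        return best
    raise ValueError("window length must be within one of the miRNA length")


def find_target_sites(
    mirna_id: str,
    mirna: str,
    transcripts: dict[str, str],
    max_score: float = 4.0,
) -> list[TargetAlignment]:
    """All target sites with S <= max_score across a transcript set.

    Gapless windows and both single-gap variants are scanned; overlapping
    representations reduce to the best-scoring alignment per (transcript,
    cleavage position), gapless preferred on ties.  Output is ordered by
    (transcript id, cleavage position).
    """
    m = _encode(mirna)
    L = len(m)
    w = position_weights(L)
    results: dict[tuple[str, int], TargetAlignment] = {}

    def _consider(aln: TargetAlignment) -> None:
        key = (aln.transcript_id, aln.cleavage_pos)
        prev = results.get(key)
        if (
            prev is None
            or aln.score < prev.score
            or (aln.score == prev.score and aln.gap == "none" != prev.gap)
        ):
            results[key] = aln

    for tx_id in sorted(transcripts):
        seq = transcripts[tx_id]
        t = _encode(seq)
        for wlen in (L, L - 1, L + 1):
            scores = _window_scores(m, t, w, wlen)
            if scores is None:
                continue
            for s0 in np.nonzero(scores <= max_score)[0]:
                duplex = score_duplex(mirna, seq[s0:s0 + wlen])
                _consider(TargetAlignment(
                    mirna_id=mirna_id, transcript_id=tx_id,
                    window_start=int(s0), window_end=int(s0 + wlen),
                    score=duplex.score, states=duplex.states,
                    cleavage_pos=cleavage_position(int(s0), wlen, duplex),
                    gap=duplex.gap,
                ))
    return sorted(results.values(),
                  key=lambda a: (a.transcript_id, a.cleavage_pos))


def build_tag_profile(
    tags: Iterable[str],
    transcripts: dict[str, str],
) -> dict[str, np.ndarray]:
    """Per-transcript 5'-end count vectors from degradome tag sequences.

    Each tag is exact-matched against every transcript; every occurrence's
    start position (the tag's 5' terminus) increments that transcript's
    profile.  Multi-transcript tags count on every matching transcript.
    """
    counts: dict[str, int] = {}
    for tag in tags:
        counts[tag] = counts.get(tag, 0) + 1
    profiles = {tx: np.zeros(len(seq), dtype=int)
                for tx, seq in transcripts.items()}
    for tag, n in counts.items():
        if not tag:
            continue
        for tx, seq in transcripts.items():
            start = 0
            while (pos := seq.find(tag, start)) >= 0:
                profiles[tx][pos] += n
                start = pos + 1
    return profiles


def assign_category(profile: np.ndarray, cleavage_pos: int) -> int:
    """CleaveLand-convention category for a 1-based cleavage position.

    4: exactly one read at the site; 0: site count equals a unique
    transcript-wide maximum; 1: equals a shared maximum; 2: above the
    median of positions with >= 1 read but below the maximum; 3: otherwise.
    Requires >= 1 read at the site.
    """
    profile = np.asarray(profile)
    c = int(profile[cleavage_pos - 1])
    if c < 1:
        raise ValueError("no degradome signal at the cleavage position")
    if c == 1:
        return 4
    mx = int(profile.max())
    n_max = int((profile == mx).sum())
    if c == mx:
        return 0 if n_max == 1 else 1
    median_nonzero = float(np.median(profile[profile > 0]))
    return 2 if c > median_nonzero else 3


def degradome_hits(
    alignments: list[TargetAlignment],
    profiles: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Combine target alignments with degradome evidence.

    Alignments without any read at the predicted cleavage position are
    dropped (no hit emitted); the rest carry the tag count, the profile
    summary and the category.
    """
    rows = []
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None or len(profile) < aln.cleavage_pos:
            continue
        count = int(profile[aln.cleavage_pos - 1])
        if count < 1:
            continue
        nonzero = profile[profile > 0]
        rows.append(
            {
                "mirna_id": aln.mirna_id,
                "transcript_id": aln.transcript_id,
                "score": aln.score,
                "cleavage_pos": aln.cleavage_pos,
                "tag_count": count,
                "profile_max": int(profile.max()),
                "n_max_positions": int((profile == profile.max()).sum()),
                "median_nonzero": float(np.median(nonzero)),
                "category": assign_category(profile, aln.cleavage_pos),
                "gap": aln.gap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "score", "cleavage_pos",
                 "tag_count", "profile_max", "n_max_positions",
                 "median_nonzero", "category", "gap"],
    )


def classify_target_function(
    hits: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Percentage of distinct target transcripts per functional class."""
    ann = annotation.set_index("transcript_id")["functional_class"]
    targets = sorted(set(hits["transcript_id"]))
    missing = [t for t in targets if t not in ann.index]
    if missing:
        raise KeyError(f"unannotated target transcripts: {missing}")
    classes = ann.loc[targets]
    pct = (classes.value_counts() / max(len(targets), 1) * 100.0).reset_index()
    pct.columns = ["functional_class", "percentage"]
    return pct.sort_values(
        ["percentage", "functional_class"], ascending=[False, True],
        ignore_index=True,
    )
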