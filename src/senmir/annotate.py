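"""Known-miRNA annotation and hairpin-based novel miRNA prediction.

Known annotation matches tags against a miRBase-style mature reference,
tolerating isomiR end variation (up to 2 nt shift at either end, no internal
mismatches).  Novel prediction extracts genomic windows around unannotated
mapped tags, folds them with an in-package pseudoknot-free base-pair
maximization (minimum loop 3, stacking bonus) and applies plant-miRNA
structural criteria: the tag must sit in one hairpin arm, pair with a
compact star region with at most 4 unpaired positions and no interior bulge
longer than 2 nt, and the mature:star stem must fold at or below a
stability threshold (default -18 units; GC pairs contribute -3, AU -2,
GU wobble -1, each stacked pair an extra -0.5).

The folding backend is pluggable: any callable with the
``fold_hairpin(sequence) -> (pairs, score)`` contract can replace the
default DP.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import TagTable
from .util import revcomp

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
STACK_BONUS = -0.5
MIN_LOOP = 3
MAX_PRECURSOR = 300

_FAMILY_RE = re.compile(r"^([a-z]{2,4}-(?:miR|MIR)\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    """Family from a mature id: "zma-miR159a-3p" -> "zma-miR159"."""
    m = _FAMILY_RE.match(mirna_id)
    return m.group(1) if m else mirna_id


@dataclass
class MiRNARecord:
    mirna_id: str
    family: str
    status: str  # "known" | "novel"
    mature: str
    locus: tuple[str, int, int, str] | None  # (ref, start, end, strand)
    counts: dict[str, int]
    rpm: dict[str, float] = field(default_factory=dict)
    tags: list[str] = field(default_factory=list)
    fold_score: float | None = None


# ---------------------------------------------------------------------------
# known-miRNA annotation (isomiR-tolerant exact matching)
# ---------------------------------------------------------------------------

def isomir_shift(tag: str, mature: str, max_shift: int = 2) -> tuple[int, int] | None:
    """Best (5' shift, 3' shift) aligning ``tag`` to ``mature``, or None.

    A shift of (d5, d3) means the tag corresponds to the mature with its 5'
    start moved by d5 and its 3' end moved by d3 (positive d5 trims the 5'
    end, positive d3 extends past the 3' end).  Bases outside the mature are
    unconstrained; the overlapping stretch must match exactly, with no
    internal mismatches.  Among valid shifts the smallest |d5|+|d3| wins
    (5'-shift magnitude breaks ties).
    """
    best: tuple[int, tuple[int, int]] | None = None
    lm, lt = len(mature), len(tag)
    for d5 in range(-max_shift, max_shift + 1):
        d3 = lt - lm + d5
        if abs(d3) > max_shift:
            continue
        m_lo, m_hi = max(d5, 0), lm + min(d3, 0)
        if m_hi - m_lo <= 0:
            continue
        t_lo = m_lo - d5
        if tag[t_lo:t_lo + (m_hi - m_lo)] != mature[m_lo:m_hi]:
            continue
        key = (abs(d5) + abs(d3), (abs(d5), abs(d3)))
        if best is None or key < best[0]:
            best = (key, (d5, d3))
    return best[1] if best else None


def parse_mature_reference(
    reference: list[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """(id, family, sequence) triples from (header, sequence) FASTA pairs."""
    seen = set()
    out = []
    for header, seq in reference:
        mid = header.split()[0]
        if mid in seen:
            raise ValueError(f"duplicate reference id: {mid}")
        seen.add(mid)
        out.append((mid, parse_family(mid), seq))
    return out


def annotate_known(
    table: TagTable,
    mature_reference: list[tuple[str, str]],
    max_shift: int = 2,
) -> tuple[list[MiRNARecord], dict[str, str]]:
    """Assign tags to reference mature miRNAs (status "known").

    A tag annotates a mature if identical or identical up to a <= 2 nt
    5'/3' end shift.  Counts of all tags assigned to one mature id are
    summed.  Returns the records plus the tag -> mature id assignment map.
    """
    reference = parse_mature_reference(mature_reference)
    assignment: dict[str, str] = {}
    for tag in table.counts.index:
        best: tuple[tuple, str] | None = None
        for mid, _, mature in reference:
            shift = isomir_shift(tag, mature, max_shift)
            if shift is None:
                continue
            key = (abs(shift[0]) + abs(shift[1]), mid)
            if best is None or key < best[0]:
                best = (key, mid)
        if best:
            assignment[tag] = best[1]

    records = []
    for mid, family, mature in reference:
        tags = [t for t, m in assignment.items() if m == mid]
        if not tags:
            continue
        counts = table.counts.loc[tags].sum(axis=0).astype(int).to_dict()
        locus = None
        exact = [t for t in tags if t == mature]
        anchor = exact[0] if exact else tags[0]
        for ref, start, strand in table.hits.get(anchor, []):
            locus = (ref, start, start + len(anchor), strand)
            break
        records.append(
            MiRNARecord(
                mirna_id=mid, family=family, status="known", mature=mature,
                locus=locus, counts=counts, tags=sorted(tags),
            )
        )
    return records, assignment


# ---------------------------------------------------------------------------
# precursor extraction and folding
# ---------------------------------------------------------------------------

def extract_precursor(
    hit: tuple[str, int, str],
    genome: dict[str, str],
    tag_length: int,
    flank: int = 150,
) -> list[dict]:
    """Two candidate precursor windows around a genomic tag hit.

    One window assumes the tag is the 5' arm (hairpin extends 3' of the
    tag), the other the 3' arm.  Windows are strand-corrected (minus-strand
    hits return reverse-complemented sequence, still 5'->3') and truncated
    at reference ends with ``truncated`` flagged.  ``tag_offset`` is the
    tag's 0-based position within the returned window sequence.
    """
    ref, start, strand = hit
    seq = genome[ref]
    end = start + tag_length
    windows = []
    for orientation in ("5p", "3p"):
        if (orientation == "5p") == (strand == "+"):
            lo, hi = start, min(len(seq), end + flank)
        else:
            lo, hi = max(0, start - flank), end
        window = seq[lo:hi]
        if strand == "-":
            window = revcomp(window)
            tag_offset = hi - end
        else:
            tag_offset = start - lo
        windows.append(
            {
                "orientation": orientation,
                "sequence": window,
                "ref": ref,
                "start": lo,
                "end": hi,
                "strand": strand,
                "tag_offset": tag_offset,
                "truncated": (hi - lo) < tag_length + flank,
            }
        )
    return windows


def _pair_energy_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    e = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            en = PAIR_ENERGY.get((seq[i], seq[j]))
            if en is not None:
                e[i, j] = en
    return e


def fold_hairpin(sequence: str) -> tuple[list[tuple[int, int]], float]:
    """Pseudoknot-free minimum-score folding of a candidate precursor.

    Base-pair maximization weighted by pair identity (GC -3, AU -2, GU -1)
    with a -0.5 stacking bonus per directly stacked pair and a minimum
    hairpin loop of 3 nt.  Returns the pair list (0-based, i<j, nested) and
    the total score (<= 0; lower is more stable).  Sequences longer than
    300 nt or containing non-ACGU(T) characters are rejected.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) > MAX_PRECURSOR:
        raise ValueError(f"precursor longer than {MAX_PRECURSOR} nt: {len(seq)}")
    if any(c not in "ACGT" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGT"})
        raise ValueError(f"non-ACGU(T) characters in sequence: {bad}")
    n = len(seq)
    if n == 0:
        return [], 0.0
    e = _pair_energy_matrix(seq)
    # V[i,j]: best score of s[i..j] given (i,j) paired; W[i,j]: best score
    V = np.full((n, n), np.inf)
    W = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        i_arr = np.arange(0, n - span)
        j_arr = i_arr + span
        inner = W[i_arr + 1, j_arr - 1]
        stacked = V[i_arr + 1, j_arr - 1] + STACK_BONUS
        V[i_arr, j_arr] = e[i_arr, j_arr] + np.minimum(inner, stacked)
        for i, j in zip(i_arr, j_arr):
            best = min(W[i + 1, j], W[i, j - 1], V[i, j])
            if span > 1:
                ks = np.arange(i, j)
                split = W[i, ks] + W[ks + 1, j]
                best = min(best, float(split.min()))
            W[i, j] = min(best, 0.0)

    pairs: list[tuple[int, int]] = []

    def _trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        if j - i - 1 < MIN_LOOP + 2:
            return
        if (
            np.isfinite(V[i + 1, j - 1])
            and V[i, j] == e[i, j] + V[i + 1, j - 1] + STACK_BONUS
            and V[i + 1, j - 1] + STACK_BONUS <= W[i + 1, j - 1]
        ):
            _trace_v(i + 1, j - 1)
        else:
            _trace_w(i + 1, j - 1)

    def _trace_w(i: int, j: int) -> None:
        while i < j:
            if W[i, j] == 0.0:
                return
            if W[i, j] == W[i + 1, j]:
                i += 1
                continue
            if W[i, j] == W[i, j - 1]:
                j -= 1
                continue
            if np.isfinite(V[i, j]) and W[i, j] == V[i, j]:
                _trace_v(i, j)
                return
            for k in range(i, j):
                if W[i, j] == W[i, k] + W[k + 1, j]:
                    _trace_w(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    _trace_w(0, n - 1)
    return sorted(pairs), float(W[0, n - 1])


@dataclass
class HairpinCandidate:
    """Structural evaluation of a tag within a candidate precursor window."""

    sequence: str
    pairs: list[tuple[int, int]]  # fold of the trimmed mature:star stem
    fold_score: float  # score of the trimmed mature:star stem
    mature_interval: tuple[int, int]  # 0-based half-open, within sequence
    star_interval: tuple[int, int] | None
    arm: str | None  # "5p" | "3p" | None (no acceptable star found)
    n_mature_mismatches: int  # unpaired/mismatched mature positions
    max_bulge: int  # bulge length used by the mature:star duplex
    loop_length: int | None  # gap between mature and star


_CAN_PAIR = np.zeros((4, 4), dtype=bool)
_B = {"A": 0, "C": 1, "G": 2, "T": 3}
for _x, _y in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
               ("G", "T"), ("T", "G")):  # G:U wobble pairs
    _CAN_PAIR[_B[_x], _B[_y]] = True


def _encode(seq: str) -> np.ndarray:
    return np.array([_B[c] for c in seq], dtype=np.int8)


def _best_star(
    seq: np.ndarray, lo: int, hi: int, max_bulge: int, min_loop: int
) -> tuple[int, int, int, int] | None:
    """Best-complementing star region for the mature at [lo, hi).

    Scans every non-overlapping placement (either side of the mature,
    separated by at least ``min_loop``) and bulge sizes 0..``max_bulge`` on
    either strand; G:U counts as paired.  Returns (star_lo, star_hi,
    n_mismatches, bulge) minimizing (mismatches, bulge, distance); None if
    nothing fits in the window.
    """
    L = hi - lo
    m = seq[lo:hi]
    n = len(seq)
    best: tuple[tuple, tuple[int, int, int, int]] | None = None

    def consider(s_lo: int, s_len: int, mism: int, bulge: int) -> None:
        nonlocal best
        if s_lo + s_len <= lo - min_loop:
            dist = lo - (s_lo + s_len)
        elif s_lo >= hi + min_loop:
            dist = s_lo - hi
        else:
            return  # overlaps the mature or loop too short
        key = (mism, bulge, dist, s_lo)
        if best is None or key < best[0]:
            best = (key, (s_lo, s_lo + s_len, mism, bulge))

    for s_len in range(L - max_bulge, L + max_bulge + 1):
        if s_len < 1 or s_len > n:
            continue
        bulge = abs(s_len - L)
        # windows of the candidate star, reversed so column k pairs m[k]
        win = np.lib.stride_tricks.sliding_window_view(seq, s_len)[:, ::-1]
        if bulge == 0:
            mism = (~_CAN_PAIR[m[None, :], win]).sum(axis=1)
            for s0 in range(len(mism)):
                consider(s0, s_len, int(mism[s0]), 0)
        elif s_len > L:  # bulged star bases (skipped star positions)
            cols = np.arange(s_len)
            best_mism = None
            for g in range(1, L):
                keep = np.concatenate([cols[:g], cols[g + bulge:]])
                mm = (~_CAN_PAIR[m[None, :], win[:, keep]]).sum(axis=1)
                best_mism = mm if best_mism is None else np.minimum(best_mism, mm)
            for s0 in range(len(best_mism)):
                consider(s0, s_len, int(best_mism[s0]), bulge)
        else:  # bulged mature bases (skipped mature positions)
            idx = np.arange(L)
            best_mism = None
            for g in range(1, L - bulge):
                keep = np.concatenate([idx[:g], idx[g + bulge:]])
                mm = (~_CAN_PAIR[m[keep][None, :], win]).sum(axis=1)
                best_mism = mm if best_mism is None else np.minimum(best_mism, mm)
            for s0 in range(len(best_mism)):
                consider(s0, s_len, int(best_mism[s0]), bulge)
    return best[1] if best else None


def evaluate_hairpin(
    sequence: str,
    mature_interval: tuple[int, int],
    fold=fold_hairpin,
    max_bulge: int = 2,
    min_loop: int = MIN_LOOP,
) -> HairpinCandidate:
    """Characterize the mature:star duplex of a candidate precursor window.

    The star is located by direct complementarity (best-pairing region on
    either side of the mature, G:U allowed, at most one bulge of
    ``max_bulge`` nt on either strand) — the thermodynamically agnostic
    analogue of how plant miRNA predictors pair mature and star arms.  The
    stability score then comes from folding the trimmed [mature..star] stem
    alone, so flanking sequence cannot subsidize a weak hairpin.
    """
    seq = sequence.upper().replace("U", "T")
    lo, hi = mature_interval
    enc = _encode(seq)
    star = _best_star(enc, lo, hi, max_bulge, min_loop)
    if star is None:
        return HairpinCandidate(
            sequence=seq, pairs=[], fold_score=0.0,
            mature_interval=mature_interval, star_interval=None, arm=None,
            n_mature_mismatches=hi - lo, max_bulge=0, loop_length=None,
        )
    s_lo, s_hi, mism, bulge = star
    if s_lo >= hi:  # star downstream of the mature: mature is the 5' arm
        arm, loop_length = "5p", s_lo - hi
        trim_lo, trim_hi = lo, s_hi
    else:
        arm, loop_length = "3p", lo - s_hi
        trim_lo, trim_hi = s_lo, hi
    trim = seq[trim_lo:trim_hi]
    if len(trim) <= MAX_PRECURSOR:
        pairs, stem_score = fold(trim)
        pairs = [(i + trim_lo, j + trim_lo) for i, j in pairs]
    else:
        pairs, stem_score = [], 0.0
    return HairpinCandidate(
        sequence=seq,
        pairs=pairs,
        fold_score=stem_score,
        mature_interval=mature_interval,
        star_interval=(s_lo, s_hi),
        arm=arm,
        n_mature_mismatches=mism,
        max_bulge=bulge,
        loop_length=loop_length,
    )


# ---------------------------------------------------------------------------
# novel-miRNA calling
# ---------------------------------------------------------------------------

@dataclass
class NovelCriteria:
    """Plant-miRNA hairpin criteria for novel calls (all configurable)."""

    min_tag_len: int = 18
    max_tag_len: int = 26
    max_star_mismatches: int = 4
    max_bulge: int = 2
    max_fold_score: float = -18.0
    min_loop: int = 3
    max_loop: int = 60  # maximal space between mature and star
    flank: int = 150


def passes_criteria(cand: HairpinCandidate, crit: NovelCriteria) -> bool:
    """Structural acceptance of an evaluated hairpin candidate.

    A tag that straddles the hairpin loop cannot recruit a non-overlapping
    complementary star and fails the mismatch criterion.
    """
    return (
        cand.arm is not None
        and cand.n_mature_mismatches <= crit.max_star_mismatches
        and cand.max_bulge <= crit.max_bulge
        and cand.loop_length is not None
        and crit.min_loop <= cand.loop_length <= crit.max_loop
        and cand.fold_score <= crit.max_fold_score
    )


def call_novel_mirnas(
    table: TagTable,
    genome: dict[str, str],
    criteria: NovelCriteria | None = None,
    fold=fold_hairpin,
) -> list[MiRNARecord]:
    """Call novel miRNA loci from unannotated, genome-mapped tags.

    A locus is called when the tag (18-26 nt) lies wholly within one arm of
    a candidate hairpin: a star region on one side of the tag (not spanning
    it, separated by a loop of >= 3 nt) pairs the tag with <= 4 mismatched
    positions and no bulge over 2 nt, and the trimmed mature:star stem
    folds at or below the stability threshold.  Identical tags at multiple
    loci yield multiple records, deduplicated by (sequence, locus).  Calls
    are pure functions of (tag, genome, criteria).
    """
    crit = criteria or NovelCriteria()
    calls: dict[tuple[str, tuple], dict] = {}
    for tag in table.counts.index:
        if not crit.min_tag_len <= len(tag) <= crit.max_tag_len:
            continue
        for hit in table.hits.get(tag, []):
            best: HairpinCandidate | None = None
            for window in extract_precursor(hit, genome, len(tag), crit.flank):
                off = window["tag_offset"]
                cand = evaluate_hairpin(
                    window["sequence"], (off, off + len(tag)), fold=fold,
                    max_bulge=crit.max_bulge, min_loop=crit.min_loop,
                )
                if not passes_criteria(cand, crit):
                    continue
                if best is None or cand.fold_score < best.fold_score:
                    best = cand
            if best is None:
                continue
            locus = (hit[0], hit[1], hit[1] + len(tag), hit[2])
            key = (tag, locus)
            if key not in calls or best.fold_score < calls[key]["score"]:
                calls[key] = {
                    "tag": tag,
                    "locus": locus,
                    "score": best.fold_score,
                }
    records = []
    ordered = sorted(calls.values(), key=lambda c: (c["locus"], c["tag"]))
    for i, call in enumerate(ordered, start=1):
        mid = f"novel-miR-{i}"
        tag = call["tag"]
        records.append(
            MiRNARecord(
                mirna_id=mid,
                family=mid,
                status="novel",
                mature=tag,
                locus=call["locus"],
                counts=table.counts.loc[tag].astype(int).to_dict(),
                tags=[tag],
                fold_score=call["score"],
            )
        )
    return records


def records_to_frame(records: list[MiRNARecord]) -> pd.DataFrame:
    """Tabular view of miRNA records (one row per miRNA)."""
    rows = []
    for r in records:
        row = {
            "mirna_id": r.mirna_id,
            "family": r.family,
            "status": r.status,
            "length": len(r.mature),
            "sequence": r.mature,
            "locus": (
                f"{r.locus[0]}:{r.locus[1]}-{r.locus[2]}({r.locus[3]})"
                if r.locus else ""
            ),
            "fold_score": r.fold_score,
        }
        row.update(r.counts)
        rows.append(row)
    return pd.DataFrame(rows)
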