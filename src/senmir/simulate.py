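"""Synthetic study generator with planted ground truth.

Emulates the two-genotype maize leaf-senescence design: an early-senescing
line (ELS-1) and a stay-green line (Yu87-1), each sampled at 20 and 30 days
after pollination (DAP), one pooled small-RNA library per sample.  The
generator plants known and novel miRNA hairpins plus ncRNA loci in a toy
genome, draws sequencing reads with negative-binomial count noise around a
known expression matrix, writes a degradome library whose 5' ends peak at
planted cleavage sites, and produces qPCR Ct and chlorophyll absorbance
tables that invert exactly to planted trajectories at zero noise.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import revcomp, write_fasta, write_fastq
from .wetlab import absorbance_for_concentrations

GENOTYPES = ("ELS-1", "Yu87-1")
TIMEPOINTS = (20, 30)
LIBRARIES = ("ELS-1_20DAP", "ELS-1_30DAP", "Yu87-1_20DAP", "Yu87-1_30DAP")
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "cis-reg")
REFERENCE_GENE = "18SrRNA"

# independent RNG streams derived from (seed, stream id)
_STREAM_READS = 101
_STREAM_DEGRADOME = 102
_STREAM_PHENOTYPE = 103

# SA-miRNA families are drawn from the front of this list so the planted
# candidate set spans the senescence-associated maize families, alternating
# up/down so library compositions stay balanced between timepoints.
_FAMILY_ORDER = (
    "zma-miR156", "zma-miR167", "zma-miR395", "zma-miR171", "zma-miR399",
    "zma-miR172", "zma-miR408", "zma-miR159", "zma-miR529", "zma-miR160",
    "zma-miR164", "zma-miR166", "zma-miR168", "zma-miR169", "zma-miR319",
    "zma-miR393", "zma-miR394", "zma-miR396", "zma-miR397", "zma-miR398",
)

# Functional classes for planted target transcripts, with the mixture used
# when assigning annotations (largest-remainder rounding).
TARGET_CLASS_MIX = (
    ("transcriptional regulator", 0.30),
    ("translational regulator", 0.18),
    ("metabolic enzyme", 0.14),
    ("signal transducer", 0.10),
    ("stress responder", 0.05),
    ("other", 0.23),
)

# sRNA length mixture for ncRNA-derived fragments: 24-nt heavy (siRNA-like)
# so pooled libraries reproduce the 24-nt mode with >half of reads at
# 20-24 nt, alongside the 20-23 nt miRNA reads.
_NCRNA_LEN = (18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32)
_NCRNA_LEN_P = (
    0.03, 0.03, 0.05, 0.06, 0.06, 0.08, 0.45, 0.06, 0.05,
    0.03, 0.03, 0.03, 0.02, 0.01, 0.01,
)


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator.

    The defaults are the simulated study conditions: 4 libraries
    (2 genotypes x 2 DAP), 40 known + 10 novel planted miRNA loci, 8 of
    them senescence-associated with a 4-fold within-ELS-1 contrast
    (|log2| = 2, comfortably past the 1.5 selection threshold) and a mild
    2-fold same-direction trend in the stay-green line (|log2| = 1, below
    the threshold, as the study reports for the shared families).
    """

    seed: int = 0
    genome_length: int = 200_000
    n_known_mirnas: int = 40
    n_novel_mirnas: int = 10
    n_ncrna_loci: int = 20
    n_sa_mirnas: int = 8
    reads_per_library: int = 50_000
    sa_fold_change: float = 4.0
    sa_yu_fold_change: float = 2.0
    # Negative-binomial dispersion of per-miRNA counts (var = m + a*m^2).
    # Each library is a single re-sequenced pooled sample, so the count
    # noise is technical: slightly overdispersed Poisson.  0 disables noise.
    noise_dispersion: float = 0.002
    degradome_peak_fraction: float = 0.7
    degradome_depth: int = 12_000
    degradome_tag_length: int = 36
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_fraction: float = 0.7
    mirna_fraction: float = 0.70
    ncrna_fraction: float = 0.18
    low_quality_fraction: float = 0.06
    unmappable_fraction: float = 0.06
    ct_noise_sd: float = 0.15
    absorbance_noise_sd: float = 0.0
    n_decoy_mature: int = 5
    hairpin_loop_length: int = 12
    min_feature_gap: int = 30

    def validate(self) -> None:
        if self.n_sa_mirnas > self.n_known_mirnas + self.n_novel_mirnas:
            raise ValueError(
                "n_sa_mirnas exceeds the number of planted miRNA loci "
                f"({self.n_sa_mirnas} > {self.n_known_mirnas + self.n_novel_mirnas})"
            )
        if self.sa_fold_change <= 2 ** 1.5:
            raise ValueError(
                "sa_fold_change must exceed 2^1.5 so planted candidates pass "
                "the |log2 FC| > 1.5 selection with margin"
            )
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        fracs = (
            self.mirna_fraction, self.ncrna_fraction,
            self.low_quality_fraction, self.unmappable_fraction,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("read-class fractions must be >= 0 and sum to <= 1")


@dataclass
class PlantedMiRNA:
    mirna_id: str
    family: str
    status: str  # "known" | "novel"
    mature: str
    star: str
    arm: str  # "5p" | "3p": which precursor arm carries the mature
    strand: str
    hairpin_start: int  # 0-based half-open genome coordinates of precursor
    hairpin_end: int
    mature_start: int  # genome coordinates of the mature sequence itself
    mature_end: int


@dataclass
class PlantedTruth:
    """Ground truth against which pipeline recovery is scored."""

    libraries: tuple[str, ...]
    mirnas: list[PlantedMiRNA]
    expression: pd.DataFrame  # expected RPM, index mirna_id x libraries
    sa_flags: dict[str, bool]
    sa_direction: dict[str, str]  # "up" | "down" (ELS-1 30 vs 20 DAP)
    cleavage_sites: list[tuple[str, str, int]]  # (mirna_id, tx_id, 1-based pos)
    phenotype: pd.DataFrame  # genotype, dap, chl_a, chl_b (mg/L)

    def check_consistency(self) -> None:
        """SA flags must be re-derivable from the expected-RPM matrix."""
        for mid in self.expression.index:
            els = np.log2(
                self.expression.loc[mid, "ELS-1_30DAP"]
                / self.expression.loc[mid, "ELS-1_20DAP"]
            )
            yu = np.log2(
                self.expression.loc[mid, "Yu87-1_30DAP"]
                / self.expression.loc[mid, "Yu87-1_20DAP"]
            )
            flag = abs(els) > 1.5 and abs(yu) <= 1.5
            if flag != self.sa_flags[mid]:
                raise AssertionError(f"sa_flags inconsistent with expression for {mid}")

    def to_dict(self) -> dict:
        return {
            "libraries": list(self.libraries),
            "mirnas": [dataclasses.asdict(m) for m in self.mirnas],
            "expression": {
                "index": list(self.expression.index),
                "columns": list(self.expression.columns),
                "values": self.expression.to_numpy().tolist(),
            },
            "sa_flags": self.sa_flags,
            "sa_direction": self.sa_direction,
            "cleavage_sites": [list(t) for t in self.cleavage_sites],
            "phenotype": self.phenotype.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        expr = pd.DataFrame(
            d["expression"]["values"],
            index=d["expression"]["index"],
            columns=d["expression"]["columns"],
        )
        return cls(
            libraries=tuple(d["libraries"]),
            mirnas=[PlantedMiRNA(**m) for m in d["mirnas"]],
            expression=expr,
            sa_flags=dict(d["sa_flags"]),
            sa_direction=dict(d["sa_direction"]),
            cleavage_sites=[tuple(t) for t in d["cleavage_sites"]],
            phenotype=pd.DataFrame(d["phenotype"]),
        )


@dataclass
class ToyStudy:
    """A fully generated synthetic study: genome, references and truth."""

    config: SimConfig
    genome: dict[str, str]
    features: pd.DataFrame  # feature_id, feature_type, label, ref, start, end, strand
    truth: PlantedTruth
    mature_reference: list[tuple[str, str]]  # (miRBase-style header, sequence)
    ncrna_reference: list[tuple[str, str]]  # (header with class=..., sequence)
    transcripts: dict[str, str]
    transcript_annotation: pd.DataFrame  # transcript_id, functional_class


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=n))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Introduce n_mut substitutions at distinct interior positions."""
    if n_mut == 0 or len(seq) < 4:
        return seq
    chars = list(seq)
    positions = rng.choice(np.arange(1, len(seq) - 1), size=n_mut, replace=False)
    for p in positions:
        chars[p] = rng.choice([c for c in "ACGT" if c != chars[p]])
    return "".join(chars)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Split ``total`` into integer parts proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    raw = weights * total / weights.sum()
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2.

    dispersion == 0 degenerates to deterministic rounding (no noise).
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return np.rint(mean).astype(int)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _expression_weights(
    config: SimConfig, rng: np.random.Generator, mirna_ids: list[str]
) -> tuple[pd.DataFrame, dict[str, bool], dict[str, str]]:
    """Per-library relative abundance weights, SA flags and directions.

    SA miRNAs are the first ``n_sa_mirnas`` ids, alternating up/down with a
    common base weight so library totals stay balanced across timepoints.
    """
    n = len(mirna_ids)
    w = np.zeros((n, 4))
    sa_flags: dict[str, bool] = {}
    sa_direction: dict[str, str] = {}
    base = 2.0
    f_els = config.sa_fold_change
    f_yu = config.sa_yu_fold_change
    for i, mid in enumerate(mirna_ids):
        if i < config.n_sa_mirnas:
            up = i % 2 == 0
            sa_flags[mid] = True
            sa_direction[mid] = "up" if up else "down"
            if up:
                w[i] = (base, base * f_els, base, base * f_yu)
            else:
                w[i] = (base * f_els, base, base * f_yu, base)
        else:
            sa_flags[mid] = False
            sa_direction[mid] = "flat"
            w[i] = rng.uniform(1.5, 3.0)
    expr = pd.DataFrame(
        1e6 * w / w.sum(axis=0, keepdims=True),
        index=mirna_ids,
        columns=list(LIBRARIES),
    )
    return expr, sa_flags, sa_direction


def _phenotype_targets() -> pd.DataFrame:
    """Planted chlorophyll trajectories (mg/L) over 10-30 DAP.

    ELS-1 chlorophyll a collapses from 25.58 mg/L at 25 DAP to 0.35 mg/L
    at 30 DAP while the stay-green line eases from 27.41 to 23.01 mg/L;
    ELS-1 chlorophyll b drops from 13.45 to 2.30 mg/L by 20 DAP.
    """
    rows = [
        ("ELS-1", 10, 28.50, 13.45),
        ("ELS-1", 20, 26.80, 2.30),
        ("ELS-1", 25, 25.58, 1.90),
        ("ELS-1", 30, 0.35, 0.21),
        ("Yu87-1", 10, 28.90, 13.20),
        ("Yu87-1", 20, 27.90, 12.40),
        ("Yu87-1", 25, 27.41, 11.80),
        ("Yu87-1", 30, 23.01, 9.60),
    ]
    return pd.DataFrame(rows, columns=["genotype", "dap", "chl_a", "chl_b"])


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return n
        n += 1
        start = idx + 1


def generate_toy_genome(config: SimConfig) -> ToyStudy:
    """Assemble the toy genome, references, transcripts and planted truth.

    The genome carries one hairpin precursor per planted miRNA (mature and
    star arms complementary with <= 2 substitutions, 12-nt loop) and the
    ncRNA loci, separated by random filler.  Each planted mature sequence
    occurs at exactly one genomic position (either strand); generation is
    retried with a derived seed in the astronomically unlikely event of a
    collision.
    """
    config.validate()
    last_err: Exception | None = None
    for attempt in range(20):
        try:
            return _generate_attempt(config, attempt)
        except _CollisionError as exc:  # pragma: no cover - ~4^-21 per mature
            last_err = exc
    raise RuntimeError(f"could not generate collision-free genome: {last_err}")


class _CollisionError(Exception):
    pass


def _generate_attempt(config: SimConfig, attempt: int) -> ToyStudy:
    rng = np.random.default_rng((config.seed, attempt))

    # --- miRNA identities -------------------------------------------------
    known_ids, families = [], {}
    for i in range(config.n_known_mirnas):
        fam = _FAMILY_ORDER[i % len(_FAMILY_ORDER)]
        letter = chr(ord("a") + i // len(_FAMILY_ORDER))
        mid = f"{fam}{letter}"
        known_ids.append(mid)
        families[mid] = fam
    novel_ids = [f"planted-novel-{i + 1}" for i in range(config.n_novel_mirnas)]
    for mid in novel_ids:
        families[mid] = mid
    mirna_ids = known_ids + novel_ids

    matures: dict[str, str] = {}
    for mid in known_ids:
        matures[mid] = _random_seq(rng, int(rng.choice([20, 21, 21, 21, 22])))
    for mid in novel_ids:
        matures[mid] = _random_seq(rng, int(rng.choice([20, 21, 21, 22, 23])))
    if len(set(matures.values())) != len(matures):
        raise _CollisionError("duplicate planted mature sequence")

    # --- hairpins, ncRNA loci, filler ------------------------------------
    blocks: list[dict] = []
    for mid in mirna_ids:
        mature = matures[mid]
        # >= 1 star mismatch keeps the mature's genomic position unique
        # (a perfect inverted repeat would also match on the star arm)
        star = _mutate(rng, revcomp(mature), int(rng.integers(1, 3)))
        arm = str(rng.choice(["5p", "3p"]))
        loop = _random_seq(rng, config.hairpin_loop_length)
        if arm == "5p":
            precursor = mature + loop + star
            mature_off = 0
        else:
            precursor = star + loop + mature
            mature_off = len(star) + len(loop)
        strand = str(rng.choice(["+", "-"]))
        blocks.append(
            {
                "kind": "hairpin",
                "id": mid,
                "seq": precursor if strand == "+" else revcomp(precursor),
                "strand": strand,
                "mature": mature,
                "star": star,
                "arm": arm,
                "mature_off": mature_off,
                "precursor_len": len(precursor),
            }
        )
    ncrna_reference: list[tuple[str, str]] = []
    for i in range(config.n_ncrna_loci):
        cls = NCRNA_CLASSES[i % len(NCRNA_CLASSES)]
        seq = _random_seq(rng, int(rng.integers(100, 151)))
        name = f"ncRNA-{i + 1}"
        ncrna_reference.append((f"{name} class={cls}", seq))
        blocks.append({"kind": "ncrna", "id": name, "label": cls, "seq": seq,
                       "strand": "+"})

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]
    total_block = sum(len(b["seq"]) for b in blocks)
    n_gaps = len(blocks) + 1
    leftover = config.genome_length - total_block - n_gaps * config.min_feature_gap
    if leftover < 0:
        raise ValueError(
            "infeasible config: planted loci plus minimum gaps exceed "
            f"genome_length ({total_block + n_gaps * config.min_feature_gap} "
            f"> {config.genome_length})"
        )
    cuts = np.sort(rng.integers(0, leftover + 1, size=len(blocks)))
    gaps = np.diff(np.concatenate([[0], cuts, [leftover]])) + config.min_feature_gap

    pieces: list[str] = []
    feature_rows: list[tuple] = []
    planted: list[PlantedMiRNA] = []
    pos = 0
    for block, gap in zip(blocks, gaps[:-1]):
        pieces.append(_random_seq(rng, int(gap)))
        pos += int(gap)
        start, end = pos, pos + len(block["seq"])
        if block["kind"] == "hairpin":
            if block["strand"] == "+":
                m_start = start + block["mature_off"]
            else:
                m_start = end - block["mature_off"] - len(block["mature"])
            m_end = m_start + len(block["mature"])
            status = "known" if block["id"] in known_ids else "novel"
            planted.append(
                PlantedMiRNA(
                    mirna_id=block["id"],
                    family=families[block["id"]],
                    status=status,
                    mature=block["mature"],
                    star=block["star"],
                    arm=block["arm"],
                    strand=block["strand"],
                    hairpin_start=start,
                    hairpin_end=end,
                    mature_start=m_start,
                    mature_end=m_end,
                )
            )
            feature_rows.append(
                (block["id"], "mirna_hairpin", status, "chr1", start, end,
                 block["strand"])
            )
            feature_rows.append(
                (f"{block['id']}/mature", "mature_mirna", families[block["id"]],
                 "chr1", m_start, m_end, block["strand"])
            )
        else:
            feature_rows.append(
                (block["id"], "ncRNA", block["label"], "chr1", start, end, "+")
            )
        pieces.append(block["seq"])
        pos = end
    pieces.append(_random_seq(rng, int(gaps[-1])))
    genome_seq = "".join(pieces)
    assert len(genome_seq) == config.genome_length
    genome = {"chr1": genome_seq}

    features = pd.DataFrame(
        feature_rows,
        columns=["feature_id", "feature_type", "label", "ref", "start", "end",
                 "strand"],
    )

    # uniqueness of every planted mature across both strands
    rc = revcomp(genome_seq)
    ncrna_cat = " ".join(seq for _, seq in ncrna_reference)
    for mid, mature in matures.items():
        hits = _count_occurrences(genome_seq, mature) + _count_occurrences(rc, mature)
        if hits != 1:
            raise _CollisionError(f"mature of {mid} occurs {hits} times in genome")
        if mature in ncrna_cat:
            raise _CollisionError(f"mature of {mid} collides with an ncRNA locus")

    # --- mature miRNA reference (known + decoys, miRBase-style headers) ---
    mature_reference = [
        (f"{mid} MIMAT{90000 + i:07d} Zea mays {mid.split('zma-')[-1]}", matures[mid])
        for i, mid in enumerate(known_ids)
    ]
    for i in range(config.n_decoy_mature):
        fam = f"zma-miR{2000 + i}"
        seq = _random_seq(rng, 21)
        if seq in genome_seq or revcomp(seq) in genome_seq:  # pragma: no cover
            raise _CollisionError("decoy mature collides with genome")
        mature_reference.append(
            (f"{fam}a MIMAT{95000 + i:07d} Zea mays decoy", seq)
        )

    # --- expression truth -------------------------------------------------
    expression, sa_flags, sa_direction = _expression_weights(config, rng, mirna_ids)

    # --- target transcripts and cleavage sites ----------------------------
    sa_ids = [mid for mid in mirna_ids if sa_flags[mid]]
    target_ids = list(dict.fromkeys(sa_ids + novel_ids))
    transcripts: dict[str, str] = {}
    cleavage_sites: list[tuple[str, str, int]] = []
    for mid in target_ids:
        mature = matures[mid]
        tlen = int(rng.integers(400, 601))
        site = revcomp(mature)
        lo, hi = 50, tlen - config.degradome_tag_length - len(mature) + 10
        s = int(rng.integers(lo, hi))
        seq = _random_seq(rng, tlen)
        seq = seq[:s] + site + seq[s + len(site):]
        tx_id = f"tx-{mid}"
        transcripts[tx_id] = seq
        # miRNA position 10 pairs with transcript index s + L - 10 (0-based)
        cleavage_sites.append((mid, tx_id, s + len(mature) - 9))
    classes = _largest_remainder(
        len(target_ids), np.array([f for _, f in TARGET_CLASS_MIX])
    )
    ann_rows = []
    class_pool: list[str] = []
    for (cls, _), k in zip(TARGET_CLASS_MIX, classes):
        class_pool.extend([cls] * int(k))
    for tx_id, cls in zip(transcripts, class_pool):
        ann_rows.append((tx_id, cls))
    transcript_annotation = pd.DataFrame(
        ann_rows, columns=["transcript_id", "functional_class"]
    )

    truth = PlantedTruth(
        libraries=LIBRARIES,
        mirnas=planted,
        expression=expression,
        sa_flags=sa_flags,
        sa_direction=sa_direction,
        cleavage_sites=cleavage_sites,
        phenotype=_phenotype_targets(),
    )
    truth.check_consistency()
    return ToyStudy(
        config=config,
        genome=genome,
        features=features,
        truth=truth,
        mature_reference=mature_reference,
        ncrna_reference=ncrna_reference,
        transcripts=transcripts,
        transcript_annotation=transcript_annotation,
    )


# --------------------------------------------------------------------------
# sRNA libraries
# --------------------------------------------------------------------------

def simulate_srna_libraries(
    study: ToyStudy, config: SimConfig | None = None
) -> dict[str, list[tuple[str, str, int]]]:
    """Draw the four sRNA libraries as (read id, sequence, phred) records.

    miRNA reads are exact mature copies with negative-binomial counts around
    the expected-RPM means; the remaining depth is filled with ncRNA
    fragments, low-quality reads (Phred 2) and unmappable random reads so
    every library holds exactly ``reads_per_library`` records.  A configured
    fraction of good reads carries the full 3' adapter.
    """
    config = config or study.config
    rng = np.random.default_rng((config.seed, _STREAM_READS))
    truth = study.truth
    mature = {m.mirna_id: m.mature for m in truth.mirnas}
    mirna_ids = list(truth.expression.index)
    ncrna_seqs = [seq for _, seq in study.ncrna_reference]

    libraries: dict[str, list[tuple[str, str, int]]] = {}
    for lib in truth.libraries:
        depth = config.reads_per_library
        mean = truth.expression[lib].to_numpy() / 1e6 * (
            config.mirna_fraction * depth
        )
        counts = _nb_counts(rng, mean, config.noise_dispersion)
        n_mirna = int(counts.sum())
        if n_mirna > depth:
            raise ValueError(
                f"library {lib}: drawn miRNA reads ({n_mirna}) exceed depth {depth}"
            )
        remainder = depth - n_mirna
        weights = np.array([
            config.ncrna_fraction,
            config.low_quality_fraction,
            config.unmappable_fraction,
        ])
        if weights.sum() > 0:
            n_ncrna, n_lowq, n_unmap = (
                int(x) for x in _largest_remainder(remainder, weights)
            )
        else:
            # degenerate noise-free configs: top up with extra miRNA copies
            n_ncrna = n_lowq = n_unmap = 0
            counts = counts + _largest_remainder(
                remainder, np.maximum(mean, 1e-12)
            )
        if not ncrna_seqs:
            n_unmap += n_ncrna
            n_ncrna = 0

        inserts: list[tuple[str, int]] = []  # (sequence, phred)
        for mid, c in zip(mirna_ids, counts):
            inserts.extend([(mature[mid], 40)] * int(c))
        for _ in range(n_ncrna):
            src = ncrna_seqs[int(rng.integers(0, len(ncrna_seqs)))]
            ln = int(rng.choice(_NCRNA_LEN, p=_NCRNA_LEN_P))
            ln = min(ln, len(src))
            start = int(rng.integers(0, len(src) - ln + 1))
            inserts.append((src[start:start + ln], 40))
        for _ in range(n_lowq):
            inserts.append((_random_seq(rng, int(rng.integers(21, 25))), 2))
        for _ in range(n_unmap):
            inserts.append((_random_seq(rng, int(rng.integers(21, 25))), 40))

        records = []
        with_adapter = rng.random(len(inserts)) < config.adapter_fraction
        for i, ((seq, qual), pad) in enumerate(zip(inserts, with_adapter)):
            if pad:
                seq = seq + config.adapter
            records.append((f"{lib}:read{i}", seq, qual))
        order = rng.permutation(len(records))
        libraries[lib] = [records[i] for i in order]
        assert len(libraries[lib]) == depth
    return libraries


# --------------------------------------------------------------------------
# degradome library
# --------------------------------------------------------------------------

def simulate_degradome_library(
    study: ToyStudy, config: SimConfig | None = None
) -> list[tuple[str, str, int]]:
    """Fixed-length degradome tags: transcript suffix prefixes.

    Each tag starts at its transcript's planted cleavage position with
    probability ``degradome_peak_fraction``, otherwise at a uniform
    background position.  Tags are the first ``degradome_tag_length``
    nucleotides of the 3' cleavage fragment; tags truncated by the
    transcript end carry a ``trunc`` marker in the read id.
    """
    config = config or study.config
    rng = np.random.default_rng((config.seed, _STREAM_DEGRADOME))
    truth = study.truth
    sites = truth.cleavage_sites
    if not sites:
        return []
    for mid, tx_id, pos in sites:
        if not 1 <= pos <= len(study.transcripts[tx_id]):
            raise ValueError(
                f"cleavage position {pos} outside transcript {tx_id} "
                f"(length {len(study.transcripts[tx_id])})"
            )
    per_site = _largest_remainder(config.degradome_depth, np.ones(len(sites)))
    records: list[tuple[str, str, int]] = []
    tag_len = config.degradome_tag_length
    i = 0
    for (mid, tx_id, pos), n_tags in zip(sites, per_site):
        tx = study.transcripts[tx_id]
        at_site = rng.random(int(n_tags)) < config.degradome_peak_fraction
        for hit in at_site:
            if hit:
                start = pos - 1
            else:
                # background 5' ends anywhere that leaves a mappable tag
                start = int(rng.integers(0, max(1, len(tx) - 18)))
            tag = tx[start:start + tag_len]
            marker = ":trunc" if len(tag) < tag_len else ""
            records.append((f"deg:{i}{marker}", tag, 40))
            i += 1
    order = rng.permutation(len(records))
    return [records[j] for j in order]


# --------------------------------------------------------------------------
# phenotype tables (qPCR Ct, absorbance)
# --------------------------------------------------------------------------

def simulate_phenotype_tables(
    study: ToyStudy, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table and chlorophyll absorbance table with planted structure.

    Absorbances are the exact inverse of the chlorophyll equations at the
    planted trajectories (plus optional Gaussian noise); Ct values encode
    the planted relative expression through the ddCt model: with the
    calibrator sample c, Ct_target = 25 - log2(RPM_s / RPM_c) and
    Ct_reference = 15, so 2^-ddCt returns the planted ratio exactly at
    zero noise.  Three replicates per sample.
    """
    config = config or study.config
    rng = np.random.default_rng((config.seed, _STREAM_PHENOTYPE))
    truth = study.truth

    abs_rows = []
    for _, row in truth.phenotype.iterrows():
        a645, a663 = absorbance_for_concentrations(row["chl_a"], row["chl_b"])
        if a645 < 0 or a663 < 0:
            raise ValueError(
                "target chlorophyll trajectory not representable by "
                f"nonnegative absorbances: {row.to_dict()}"
            )
        for rep in (1, 2, 3):
            noise = rng.normal(0.0, config.absorbance_noise_sd, size=2)
            abs_rows.append(
                (row["genotype"], int(row["dap"]), rep,
                 max(0.0, a645 + noise[0]), max(0.0, a663 + noise[1]))
            )
    absorbance = pd.DataFrame(
        abs_rows, columns=["genotype", "dap", "replicate", "A645", "A663"]
    )

    calibrator = "ELS-1_20DAP"
    sa_ids = [mid for mid in truth.expression.index if truth.sa_flags[mid]]
    ct_rows = []
    for lib in truth.libraries:
        genotype, dap = lib.rsplit("_", 1)
        for mid in sa_ids:
            rel = truth.expression.loc[mid, lib] / truth.expression.loc[mid, calibrator]
            for rep in (1, 2, 3):
                ct_t = 25.0 - float(np.log2(rel)) + rng.normal(0, config.ct_noise_sd)
                ct_r = 15.0 + rng.normal(0, config.ct_noise_sd)
                ct_rows.append(
                    (lib, genotype, int(dap.replace("DAP", "")), mid,
                     REFERENCE_GENE, rep, ct_t, ct_r, lib == calibrator)
                )
    ct = pd.DataFrame(
        ct_rows,
        columns=["sample_id", "genotype", "dap", "gene", "reference_gene",
                 "replicate", "ct_target", "ct_reference", "is_calibrator"],
    )
    return ct, absorbance


# --------------------------------------------------------------------------
# file emission
# --------------------------------------------------------------------------

def write_study(study: ToyStudy, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every synthetic input to ``outdir``; returns a path manifest."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_fasta(_p("genome.fa"), study.genome.items())
    study.features.to_csv(_p("features.tsv"), sep="\t", index=False)
    write_fasta(_p("mature_reference.fa"), study.mature_reference)
    write_fasta(_p("ncrna_reference.fa"), study.ncrna_reference)
    write_fasta(_p("transcripts.fa"), study.transcripts.items())
    study.transcript_annotation.to_csv(
        _p("transcript_annotation.tsv"), sep="\t", index=False
    )

    libraries = simulate_srna_libraries(study)
    for lib, records in libraries.items():
        write_fastq(os.path.join(outdir, f"{lib}.fastq"), records)
        paths[f"{lib}.fastq"] = os.path.join(outdir, f"{lib}.fastq")
    write_fastq(_p("degradome.fastq"), simulate_degradome_library(study))

    ct, absorbance = simulate_phenotype_tables(study)
    ct.to_csv(_p("qpcr_ct.tsv"), sep="\t", index=False)
    absorbance.to_csv(_p("absorbance.tsv"), sep="\t", index=False)

    with open(_p("planted_truth.json"), "w") as fh:
        json.dump(study.truth.to_dict(), fh, indent=1)
    return paths


def load_truth(path: str | os.PathLike) -> PlantedTruth:
    with open(path) as fh:
        return PlantedTruth.from_dict(json.load(fh))
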