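"""Raw-read processing: adapter trimming, quality/length filtering, tag
collapsing, exact genome mapping and ncRNA removal.

The product is a :class:`TagTable`: unique 18-32 nt tag sequences with
per-library read counts, genome hits and (after screening) ncRNA class
labels.  Mapping is exact full-length matching on both strands; there is no
mismatch tolerance, which is reproducible and sufficient for the synthetic
genomes this pipeline is exercised on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .util import revcomp

NCRNA_ALLOWED_CLASSES = {"rRNA", "tRNA", "snRNA", "snoRNA", "cis-reg"}

_SEED_LEN = 18  # tags are >= 18 nt after length filtering


def trim_adapter(seq: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the 3' adapter: longest suffix of the read that is an exact
    prefix of the adapter, requiring at least ``min_overlap`` nt."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[:-k]
    return seq


def trim_and_quality_filter(
    reads: Iterable[tuple[str, str, Sequence[int]]],
    adapter: str,
    min_mean_quality: float = 20.0,
    min_overlap: int = 6,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Adapter-trim and quality-filter a FASTQ stream.

    Reads whose mean Phred quality is below ``min_mean_quality`` or that
    contain an N are discarded before trimming.  Returns the surviving
    (id, trimmed sequence) records and per-reason discard counts.
    """
    clean: list[tuple[str, str]] = []
    stats = {"input": 0, "low_quality": 0, "contains_n": 0, "kept": 0}
    for name, seq, quals in reads:
        stats["input"] += 1
        if "N" in seq:
            stats["contains_n"] += 1
            continue
        if len(quals) and float(np.mean(quals)) < min_mean_quality:
            stats["low_quality"] += 1
            continue
        clean.append((name, trim_adapter(seq, adapter, min_overlap)))
        stats["kept"] += 1
    return clean, stats


@dataclass
class TagTable:
    """Unique tags with per-library counts, genome hits and ncRNA labels.

    ``counts`` is indexed by tag sequence with one integer column per
    library.  ``hits`` maps tag -> list of (reference id, 0-based start,
    strand); tags absent from ``hits`` have not been mapped yet, tags with
    an empty list mapped nowhere.  ``ncrna_class`` labels tags that matched
    the ncRNA screen (they are removed from filtered tables but kept in the
    removal report).
    """

    counts: pd.DataFrame
    hits: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    ncrna_class: dict[str, str] = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def library_totals(self) -> pd.Series:
        """Read-weighted total per library over the current tags."""
        return self.counts.sum(axis=0)

    def mapped_mask(self) -> pd.Series:
        return pd.Series(
            [bool(self.hits.get(t)) for t in self.counts.index],
            index=self.counts.index,
        )

    def subset(self, tags: Sequence[str]) -> "TagTable":
        tags = list(tags)
        return TagTable(
            counts=self.counts.loc[tags].copy(),
            hits={t: self.hits[t] for t in tags if t in self.hits},
            ncrna_class={
                t: self.ncrna_class[t] for t in tags if t in self.ncrna_class
            },
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "tag", df.index)
        df.insert(1, "length", [len(t) for t in df.index])
        df["hits"] = [
            ";".join(f"{r}:{s}:{st}" for r, s, st in self.hits.get(t, []))
            for t in df.index
        ]
        df["ncrna_class"] = [self.ncrna_class.get(t, "") for t in df.index]
        return df.reset_index(drop=True)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TagTable":
        df = pd.read_csv(path, sep="\t", dtype={"tag": str}, keep_default_na=False)
        libs = [
            c for c in df.columns
            if c not in ("tag", "length", "hits", "ncrna_class")
        ]
        counts = df.set_index("tag")[libs].astype(int)
        hits: dict[str, list[tuple[str, int, str]]] = {}
        ncrna: dict[str, str] = {}
        for _, row in df.iterrows():
            if row.get("hits", ""):
                hits[row["tag"]] = [
                    (r, int(s), st)
                    for r, s, st in (h.split(":") for h in row["hits"].split(";"))
                ]
            elif "hits" in df.columns:
                hits[row["tag"]] = []
            if row.get("ncrna_class", ""):
                ncrna[row["tag"]] = row["ncrna_class"]
        return cls(counts=counts, hits=hits, ncrna_class=ncrna)


def length_filter_and_collapse(
    clean_reads: dict[str, list[tuple[str, str]]],
    min_len: int = 18,
    max_len: int = 32,
) -> tuple[TagTable, dict[str, int]]:
    """Keep reads of ``min_len``-``max_len`` nt and collapse identical
    sequences into per-library counts.

    ``clean_reads`` maps library id -> trimmed (read id, sequence) records.
    Returns the tag table plus per-library length-discard counts.
    """
    libraries = list(clean_reads)
    tally: dict[str, dict[str, int]] = {}
    discards = {lib: 0 for lib in libraries}
    for lib, records in clean_reads.items():
        for _, seq in records:
            if not min_len <= len(seq) <= max_len:
                discards[lib] += 1
                continue
            tally.setdefault(seq, dict.fromkeys(libraries, 0))[lib] += 1
    counts = pd.DataFrame(
        [[tally[t].get(lib, 0) for lib in libraries] for t in sorted(tally)],
        index=sorted(tally),
        columns=libraries,
        dtype=int,
    )
    return TagTable(counts=counts), discards


def _seed_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        index.setdefault(sequence[i:i + k], []).append(i)
    return index


def map_tags(table: TagTable, genome: dict[str, str]) -> TagTable:
    """Exact full-length matching of every tag to both genome strands.

    All hit positions are reported as (reference, 0-based start on the
    forward strand, strand); minus-strand hits are positions where the
    reverse complement of the tag occurs in the forward sequence.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    indexes = {ref: _seed_index(seq, _SEED_LEN) for ref, seq in genome.items()}
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for tag in table.counts.index:
        tag_hits: list[tuple[str, int, str]] = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            for ref, seq in genome.items():
                if len(query) >= _SEED_LEN:
                    for pos in indexes[ref].get(query[:_SEED_LEN], []):
                        if seq.startswith(query, pos):
                            tag_hits.append((ref, pos, strand))
                else:  # short queries: direct scan
                    start = 0
                    while (pos := seq.find(query, start)) >= 0:
                        tag_hits.append((ref, pos, strand))
                        start = pos + 1
        hits[tag] = sorted(set(tag_hits))
    return TagTable(counts=table.counts.copy(), hits=hits,
                    ncrna_class=dict(table.ncrna_class))


def remove_ncrna(
    table: TagTable,
    ncrna_reference: list[tuple[str, str]],
) -> tuple[TagTable, pd.DataFrame]:
    """Screen tags against the ncRNA reference by substring containment.

    A tag matching (as an exact substring) any reference entry is removed
    and attributed to that entry's class; survivors are the candidate miRNA
    tags.  Reference headers carry ``class=<rRNA|tRNA|snRNA|snoRNA|cis-reg>``.
    Returns the filtered table and a per-class x library removed-read
    report.  The operation is idempotent.
    """
    ref_classes: list[tuple[str, str]] = []  # (class, sequence)
    for header, seq in ncrna_reference:
        cls = None
        for tok in header.split():
            if tok.startswith("class="):
                cls = tok.split("=", 1)[1]
        if cls is None:
            raise ValueError(f"ncRNA reference entry lacks class=: {header!r}")
        if cls not in NCRNA_ALLOWED_CLASSES:
            raise ValueError(f"unknown ncRNA class {cls!r} in {header!r}")
        ref_classes.append((cls, seq))

    removed: dict[str, str] = {}
    for tag in table.counts.index:
        for cls, seq in ref_classes:
            if tag in seq:
                removed[tag] = cls
                break
    keep = [t for t in table.counts.index if t not in removed]
    report_rows = []
    for cls in sorted({c for c, _ in ref_classes}):
        cls_tags = [t for t, c in removed.items() if c == cls]
        row: dict[str, object] = {"ncrna_class": cls}
        sub = table.counts.loc[cls_tags]
        for lib in table.libraries:
            row[lib] = int(sub[lib].sum())
        row["n_tags"] = len(cls_tags)
        report_rows.append(row)
    report = pd.DataFrame(
        report_rows, columns=["ncrna_class", *table.libraries, "n_tags"]
    )
    filtered = table.subset(keep)
    filtered.ncrna_class = {}
    return filtered, report


def length_distribution(
    table: TagTable,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Read-weighted length distribution per library.

    Returns a length x library fraction table (columns sum to 1 for
    non-empty libraries) plus the aggregate fraction of reads at 20-24 nt
    per library (None for empty libraries).
    """
    if table.counts.empty:
        raise ValueError("empty tag table")
    lengths = pd.Series([len(t) for t in table.counts.index],
                        index=table.counts.index)
    by_len = table.counts.groupby(lengths).sum()
    totals = by_len.sum(axis=0)
    fractions = by_len / totals.replace(0, np.nan)
    fraction_20_24: dict[str, float | None] = {}
    for lib in table.libraries:
        if totals[lib] == 0:
            fraction_20_24[lib] = None
        else:
            in_window = by_len.loc[(by_len.index >= 20) & (by_len.index <= 24), lib]
            fraction_20_24[lib] = float(in_window.sum() / totals[lib])
    fractions.index.name = "length"
    return fractions, fraction_20_24
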