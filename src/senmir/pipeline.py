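"""End-to-end orchestration: simulate -> process -> annotate -> contrast ->
degradome -> wet-lab quantification, with a machine-readable run report.

A single :class:`RunConfig` (YAML-serializable) drives every stage; all
randomness flows from its seed.  The report echoes every threshold, carries
per-stage read accounting that sums back to the raw depth, and scores
recovery against the planted truth when the inputs are synthetic.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import degradome as deg
from . import expression as expr
from . import reads as rd
from . import simulate as sm
from . import wetlab as wl
from .util import iter_fastq, read_fasta, read_fasta_with_descriptions


@dataclass
class RunConfig:
    """All stage parameters plus the synthetic-study configuration."""

    seed: int = 0
    outdir: str = "senmir_run"
    sim: sm.SimConfig = field(default_factory=sm.SimConfig)
    min_len: int = 18
    max_len: int = 32
    min_mean_quality: float = 20.0
    rpm_floor: float = 5.0
    fc_threshold: float = 1.5
    pseudocount: float = 1.0
    max_target_score: float = 4.0
    novel: ann.NovelCriteria = field(default_factory=ann.NovelCriteria)
    calibrator: str = "ELS-1_20DAP"
    reference_gene: str = sm.REFERENCE_GENE

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.validate()

    def validate(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("length window must satisfy 0 < min_len <= max_len")
        if self.rpm_floor < 0 or self.pseudocount <= 0 or self.fc_threshold < 0:
            raise ValueError("floor/threshold must be >= 0 and pseudocount > 0")
        self.sim.validate()

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["sim"] = sm.SimConfig(**raw.get("sim", {}))
        raw["novel"] = ann.NovelCriteria(**raw.get("novel", {}))
        return cls(**raw)


def load_table1_fixture(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load the packaged novel-miRNA abundance table (164 records).

    Columns: mirna_id, length_nt, sequence and the four per-library
    normalized abundances.  Each sequence must have exactly ``length_nt``
    bases and abundances must be nonnegative; violations fail with the
    offending row id.
    """
    if path is None:
        from importlib.resources import files

        path = files("senmir.data").joinpath("novel_mirna_abundance.tsv")
    df = pd.read_csv(str(path), sep="\t")
    expected = ["mirna_id", "length_nt", "sequence",
                "ELS-1_20DAP", "ELS-1_30DAP", "Yu87-1_20DAP", "Yu87-1_30DAP"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"fixture missing columns: {missing}")
    for _, row in df.iterrows():
        if len(row["sequence"]) != int(row["length_nt"]):
            raise ValueError(
                f"length mismatch for {row['mirna_id']}: "
                f"{len(row['sequence'])} != {row['length_nt']}"
            )
        if any(row[lib] < 0 for lib in expected[3:]):
            raise ValueError(f"negative abundance for {row['mirna_id']}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report.

    Inputs are generated by the synthetic module under ``outdir/inputs``
    and re-read from disk so the file formats are exercised end to end.
    Any stage failure aborts with the stage named in the exception.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": _jsonable(dataclasses.asdict(config))}

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # --- simulate ---------------------------------------------------------
    study = _stage("simulate")(sm.generate_toy_genome, config.sim)
    inputs = _stage("simulate")(sm.write_study, study, os.path.join(outdir, "inputs"))
    truth = study.truth

    # --- process ----------------------------------------------------------
    genome = read_fasta(inputs["genome.fa"])
    ncrna_ref = [
        (f"{rid} {desc}", seq2)
        for rid, desc, seq2 in read_fasta_with_descriptions(
            inputs["ncrna_reference.fa"]
        )
    ]
    clean: dict[str, list[tuple[str, str]]] = {}
    accounting: dict[str, dict[str, int]] = {}
    for lib in truth.libraries:
        records = iter_fastq(inputs[f"{lib}.fastq"])
        kept, stats = _stage("process")(
            rd.trim_and_quality_filter,
            records, config.sim.adapter, config.min_mean_quality,
        )
        clean[lib] = kept
        accounting[lib] = {
            "raw": stats["input"],
            "discard_quality": stats["low_quality"] + stats["contains_n"],
        }
    table, length_discards = _stage("process")(
        rd.length_filter_and_collapse, clean, config.min_len, config.max_len
    )
    table = _stage("process")(rd.map_tags, table, genome)
    mapped_tags = [t for t in table.tags if table.hits.get(t)]
    mapped = table.subset(mapped_tags)
    candidates, ncrna_report = _stage("process")(rd.remove_ncrna, mapped, ncrna_ref)
    lengths, frac_20_24 = _stage("process")(rd.length_distribution, table)
    for lib in truth.libraries:
        acc = accounting[lib]
        acc["discard_length"] = length_discards[lib]
        acc["unmapped"] = int(
            table.counts[lib].sum() - mapped.counts[lib].sum()
        )
        acc["ncrna_removed"] = int(
            mapped.counts[lib].sum() - candidates.counts[lib].sum()
        )
        acc["candidate_reads"] = int(candidates.counts[lib].sum())
        acc["identity_ok"] = acc["raw"] == (
            acc["discard_quality"] + acc["discard_length"] + acc["unmapped"]
            + acc["ncrna_removed"] + acc["candidate_reads"]
        )
    candidates.to_tsv(os.path.join(outdir, "tag_table.tsv"))
    ncrna_report.to_csv(os.path.join(outdir, "ncrna_removal.tsv"),
                        sep="\t", index=False)
    report["read_accounting"] = accounting
    report["fraction_20_24nt"] = frac_20_24

    # --- annotate ---------------------------------------------------------
    mature_ref = [
        (f"{rid} {desc}", seq2)
        for rid, desc, seq2 in read_fasta_with_descriptions(
            inputs["mature_reference.fa"]
        )
    ]
    known, assignment = _stage("annotate")(
        ann.annotate_known, candidates, mature_ref
    )
    unassigned = candidates.subset(
        [t for t in candidates.tags if t not in assignment]
    )
    novel = _stage("annotate")(
        ann.call_novel_mirnas, unassigned, genome, config.novel
    )
    records = known + novel
    ann.records_to_frame(records).to_csv(
        os.path.join(outdir, "mirna_records.tsv"), sep="\t", index=False
    )
    report["n_known_detected"] = len(known)
    report["n_novel_called"] = len(novel)

    # --- contrast ---------------------------------------------------------
    counts = pd.DataFrame(
        {r.mirna_id: r.counts for r in records}
    ).T.reindex(columns=list(truth.libraries)).fillna(0).astype(int)
    totals = candidates.library_totals()
    rpm = _stage("contrast")(expr.compute_rpm, counts, totals)
    for r in records:
        r.rpm = rpm.loc[r.mirna_id].to_dict()
    floored = _stage("contrast")(expr.apply_floor, rpm, config.rpm_floor)
    families = {r.mirna_id: r.family for r in records}
    contrast = _stage("contrast")(
        expr.select_sa_mirnas, floored, config.fc_threshold,
        config.pseudocount, families,
    )
    n_families, family_table = expr.summarize_families(contrast)
    sensitivity = expr.pseudocount_sensitivity(floored, config.fc_threshold)
    contrast.to_csv(os.path.join(outdir, "contrast.tsv"), sep="\t", index=False)
    report["contrast"] = {
        "n_retained_after_floor": int(len(floored)),
        "n_sa_candidates": int(contrast["sa_candidate"].sum()),
        "n_sa_families": n_families,
        "families": _jsonable(family_table),
        "pseudocount_sensitivity": _jsonable(sensitivity),
        "candidates": _jsonable(
            contrast[contrast["sa_candidate"]][
                ["mirna_id", "family", "log2fc_els", "log2fc_yu", "direction"]
            ]
        ),
    }

    # --- degradome --------------------------------------------------------
    transcripts = read_fasta(inputs["transcripts.fa"])
    annotation = pd.read_csv(inputs["transcript_annotation.tsv"], sep="\t")
    deg_tags = [seq2 for _, seq2, _ in iter_fastq(inputs["degradome.fastq"])]
    profiles = _stage("degradome")(deg.build_tag_profile, deg_tags, transcripts)
    sa_ids = list(contrast.loc[contrast["sa_candidate"], "mirna_id"])
    query_ids = sorted(set(sa_ids) | {r.mirna_id for r in novel})
    mature_by_id = {r.mirna_id: r.mature for r in records}
    alignments: list[deg.TargetAlignment] = []
    for mid in query_ids:
        alignments.extend(
            _stage("degradome")(
                deg.find_target_sites, mid, mature_by_id[mid], transcripts,
                config.max_target_score,
            )
        )
    hits = _stage("degradome")(deg.degradome_hits, alignments, profiles)
    function_pct = (
        deg.classify_target_function(hits, annotation)
        if not hits.empty else pd.DataFrame(
            columns=["functional_class", "percentage"]
        )
    )
    hits.to_csv(os.path.join(outdir, "degradome_hits.tsv"), sep="\t", index=False)
    report["degradome"] = {
        "n_hits": int(len(hits)),
        "n_category0": int((hits["category"] == 0).sum()) if len(hits) else 0,
        "function_percentages": _jsonable(function_pct),
    }

    # --- wet-lab quantification ------------------------------------------
    absorbance = pd.read_csv(inputs["absorbance.tsv"], sep="\t")
    chlorophyll = _stage("quantify")(wl.chlorophyll_table, absorbance)
    decline, early_genotype = _stage("quantify")(
        wl.senescence_contrast, chlorophyll
    )
    ct = pd.read_csv(inputs["qpcr_ct.tsv"], sep="\t")
    rq = _stage("quantify")(wl.delta_delta_ct, ct, config.calibrator)
    concordance = _stage("quantify")(wl.direction_concordance, rq, contrast)
    chlorophyll.to_csv(os.path.join(outdir, "chlorophyll.tsv"),
                       sep="\t", index=False)
    rq.to_csv(os.path.join(outdir, "relative_expression.tsv"),
              sep="\t", index=False)
    report["wetlab"] = {
        "chlorophyll": _jsonable(chlorophyll),
        "early_senescing_genotype": early_genotype,
        "decline_rates": _jsonable(decline),
        "qpcr_concordant_fraction": (
            float(concordance["agree"].mean()) if len(concordance) else None
        ),
    }

    # --- recovery vs planted truth ---------------------------------------
    report["recovery"] = _recovery_metrics(truth, contrast, novel, hits)

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report


def _recovery_metrics(
    truth: sm.PlantedTruth,
    contrast: pd.DataFrame,
    novel: list[ann.MiRNARecord],
    hits: pd.DataFrame,
) -> dict:
    """Precision/recall of SA candidates, novel calls and cleavage sites."""
    planted_novel = {
        m.mature: m for m in truth.mirnas if m.status == "novel"
    }
    novel_alias: dict[str, str] = {}  # called id -> planted id
    novel_matched = 0
    for r in novel:
        m = planted_novel.get(r.mature)
        if m is not None and r.locus == (
            "chr1", m.mature_start, m.mature_end, m.strand
        ):
            novel_matched += 1
            novel_alias[r.mirna_id] = m.mirna_id
    novel_precision = novel_matched / len(novel) if novel else None
    novel_recall = (
        novel_matched / len(planted_novel) if planted_novel else None
    )

    called = {
        novel_alias.get(mid, mid)
        for mid in contrast.loc[contrast["sa_candidate"], "mirna_id"]
    }
    planted_sa = {mid for mid, f in truth.sa_flags.items() if f}
    tp = len(called & planted_sa)
    sa_precision = tp / len(called) if called else None
    sa_recall = tp / len(planted_sa) if planted_sa else None

    site_rows = []
    if len(hits):
        hit_alias = hits.assign(
            planted_id=[novel_alias.get(m, m) for m in hits["mirna_id"]]
        )
    for mid, tx_id, pos in truth.cleavage_sites:
        if len(hits):
            match = hit_alias[
                (hit_alias["planted_id"] == mid)
                & (hit_alias["transcript_id"] == tx_id)
                & (hit_alias["cleavage_pos"] == pos)
            ]
        else:
            match = pd.DataFrame()
        site_rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tx_id,
                "cleavage_pos": pos,
                "recovered": bool(len(match)),
                "score": float(match["score"].iloc[0]) if len(match) else None,
                "category": int(match["category"].iloc[0]) if len(match) else None,
            }
        )
    n_sites = len(site_rows)
    recovered = [r for r in site_rows if r["recovered"]]
    return {
        "sa_precision": sa_precision,
        "sa_recall": sa_recall,
        "novel_precision": novel_precision,
        "novel_recall": novel_recall,
        "cleavage_recall": len(recovered) / n_sites if n_sites else None,
        "cleavage_all_category0_s0": bool(
            n_sites
            and len(recovered) == n_sites
            and all(r["category"] == 0 and r["score"] == 0.0 for r in recovered)
        ),
        "cleavage_sites": site_rows,
    }
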