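"""RPM normalization and the two-genotype senescence-candidate contrast.

Expression is reads per million mapped candidate reads (RPM).  A miRNA is a
senescence-associated (SA) candidate when its |log2 fold change| between
20 and 30 DAP exceeds the threshold (default 1.5, strict inequality) in the
early-senescing line ELS-1 but not in the stay-green control Yu87-1.  Rows
must first pass an abundance floor (default 5 RPM in at least one library).
Fold changes are pseudocount-adjusted (default 1 RPM) so zero entries stay
finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ELS_20, ELS_30 = "ELS-1_20DAP", "ELS-1_30DAP"
YU_20, YU_30 = "Yu87-1_20DAP", "Yu87-1_30DAP"
REQUIRED_LIBRARIES = (ELS_20, ELS_30, YU_20, YU_30)


def compute_rpm(
    counts: pd.DataFrame, library_totals: pd.Series | dict[str, float]
) -> pd.DataFrame:
    """RPM = count / mapped-candidate total x 10^6, per library column."""
    totals = pd.Series(library_totals)
    bad = [lib for lib in counts.columns if totals.get(lib, 0) <= 0]
    if bad:
        raise ValueError(f"non-positive library totals for: {bad}")
    return counts / totals[counts.columns] * 1e6


def apply_floor(matrix: pd.DataFrame, floor: float = 5.0) -> pd.DataFrame:
    """Keep rows whose maximum over libraries reaches the floor
    ("at least one sample" rule)."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    return matrix[matrix.max(axis=1) >= floor].copy()


def log2_fold_change(rpm_t2, rpm_t1, pseudocount: float = 1.0):
    """log2((rpm_t2 + c) / (rpm_t1 + c)); finite for all nonnegative input."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    t2 = np.asarray(rpm_t2, dtype=float)
    t1 = np.asarray(rpm_t1, dtype=float)
    if (t2 < 0).any() or (t1 < 0).any():
        raise ValueError("RPM values must be nonnegative")
    out = np.log2((t2 + pseudocount) / (t1 + pseudocount))
    return float(out) if out.ndim == 0 else out


def select_sa_mirnas(
    matrix: pd.DataFrame,
    threshold: float = 1.5,
    pseudocount: float = 1.0,
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the two-genotype selection rule to a floored RPM matrix.

    Returns one row per miRNA: both log2 fold changes (30 vs 20 DAP),
    ``de_in_els`` (|log2FC| > threshold in ELS-1), ``removed_by_yu``
    (|log2FC| > threshold in Yu87-1 as well), ``sa_candidate`` (DE in ELS-1
    and not removed), and the ELS-1 direction.
    """
    missing = [lib for lib in REQUIRED_LIBRARIES if lib not in matrix.columns]
    if missing:
        raise ValueError(f"expression matrix missing library columns: {missing}")
    fc_els = log2_fold_change(matrix[ELS_30], matrix[ELS_20], pseudocount)
    fc_yu = log2_fold_change(matrix[YU_30], matrix[YU_20], pseudocount)
    de_els = np.abs(fc_els) > threshold
    rem_yu = np.abs(fc_yu) > threshold
    fams = families or {}
    out = pd.DataFrame(
        {
            "mirna_id": matrix.index,
            "family": [fams.get(m, m) for m in matrix.index],
            "log2fc_els": np.asarray(fc_els),
            "log2fc_yu": np.asarray(fc_yu),
            "passed_floor": True,
            "de_in_els": np.asarray(de_els),
            "removed_by_yu": np.asarray(rem_yu),
            "sa_candidate": np.asarray(de_els) & ~np.asarray(rem_yu),
        }
    )
    out["direction"] = np.where(
        out["log2fc_els"] > 0, "up", np.where(out["log2fc_els"] < 0, "down", "flat")
    )
    return out.reset_index(drop=True)


def summarize_families(contrast: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Distinct families among SA candidates, with sorted membership."""
    cand = contrast[contrast["sa_candidate"]]
    groups = (
        cand.groupby("family")["mirna_id"]
        .apply(lambda s: ",".join(sorted(s)))
        .reset_index()
        .rename(columns={"mirna_id": "members"})
        .sort_values("family", ignore_index=True)
    )
    return len(groups), groups


def pseudocount_sensitivity(
    matrix: pd.DataFrame,
    threshold: float = 1.5,
    pseudocounts: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> pd.DataFrame:
    """Candidate sets under alternative pseudocounts, for the run report.

    The zero-handling convention is not uniquely determined by the selection
    rule, so the report carries the candidate count and membership for each
    pseudocount in the sweep.
    """
    rows = []
    for c in pseudocounts:
        sel = select_sa_mirnas(matrix, threshold=threshold, pseudocount=c)
        cand = sorted(sel.loc[sel["sa_candidate"], "mirna_id"])
        rows.append((c, len(cand), ",".join(cand)))
    return pd.DataFrame(rows, columns=["pseudocount", "n_candidates", "candidates"])
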