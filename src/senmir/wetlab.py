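"""Chlorophyll spectrophotometry and qRT-PCR relative quantification.

Chlorophyll concentrations come from Arnon-type linear combinations of the
645 nm and 663 nm absorbances of an 80% organic-solvent leaf extract:

    Ca   = 12.7*A663 - 2.69*A645     (mg/L)
    Cb   = 22.9*A645 - 4.68*A663
    Ctot = 20.2*A645 + 8.02*A663

The coefficient set is configurable so alternative solvent calibrations can
be swapped in.  Relative transcript abundance uses the 2^-ddCt model with
replicate Ct values averaged before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ChlorophyllCoefficients:
    """Linear coefficients: C = c663 * A663 + c645 * A645 for a, b, total."""

    ca_663: float = 12.7
    ca_645: float = -2.69
    cb_663: float = -4.68
    cb_645: float = 22.9
    ct_663: float = 8.02
    ct_645: float = 20.2


CHL_COEFFICIENTS = ChlorophyllCoefficients()


def chlorophyll_concentrations(
    a645: float,
    a663: float,
    coefficients: ChlorophyllCoefficients = CHL_COEFFICIENTS,
    clip_negative: bool = True,
) -> tuple[float, float, float]:
    """(Ca, Cb, Ctot) in mg/L from the two absorbances.

    Absorbances must be nonnegative.  Slightly negative computed
    concentrations (possible for extreme absorbance ratios) are clipped to
    zero when ``clip_negative`` is set.
    """
    if a645 < 0 or a663 < 0:
        raise ValueError(f"negative absorbance: A645={a645}, A663={a663}")
    c = coefficients
    ca = c.ca_663 * a663 + c.ca_645 * a645
    cb = c.cb_663 * a663 + c.cb_645 * a645
    ct = c.ct_663 * a663 + c.ct_645 * a645
    if clip_negative:
        ca, cb, ct = max(ca, 0.0), max(cb, 0.0), max(ct, 0.0)
    return ca, cb, ct


def absorbance_for_concentrations(
    ca: float,
    cb: float,
    coefficients: ChlorophyllCoefficients = CHL_COEFFICIENTS,
) -> tuple[float, float]:
    """Invert the chlorophyll equations: (A645, A663) giving (Ca, Cb)."""
    c = coefficients
    mat = np.array([[c.ca_645, c.ca_663], [c.cb_645, c.cb_663]])
    a645, a663 = np.linalg.solve(mat, np.array([ca, cb]))
    return float(a645), float(a663)


def chlorophyll_table(
    absorbance: pd.DataFrame,
    coefficients: ChlorophyllCoefficients = CHL_COEFFICIENTS,
    dilution_ml: float = 20.0,
    fresh_mass_g: float = 0.2,
) -> pd.DataFrame:
    """Per-sample concentrations from an absorbance table.

    Expects columns genotype, dap, replicate, A645, A663; replicates are
    averaged.  Reports both mg/L of extract and mg per gram fresh mass
    (mg/L x dilution volume / fresh mass), since the assay records a 0.2 g
    sample extracted into 20 mL.
    """
    required = {"genotype", "dap", "A645", "A663"}
    missing = required - set(absorbance.columns)
    if missing:
        raise ValueError(f"absorbance table missing columns: {sorted(missing)}")
    grouped = (
        absorbance.groupby(["genotype", "dap"], as_index=False)[["A645", "A663"]]
        .mean()
        .sort_values(["genotype", "dap"])
    )
    rows = []
    for _, r in grouped.iterrows():
        ca, cb, ct = chlorophyll_concentrations(r["A645"], r["A663"], coefficients)
        per_g = dilution_ml / 1000.0 / fresh_mass_g
        rows.append(
            (r["genotype"], int(r["dap"]), r["A645"], r["A663"], ca, cb, ct,
             ca * per_g, cb * per_g, ct * per_g)
        )
    return pd.DataFrame(
        rows,
        columns=["genotype", "dap", "A645", "A663", "chl_a", "chl_b", "chl_total",
                 "chl_a_mg_per_g", "chl_b_mg_per_g", "chl_total_mg_per_g"],
    )


def senescence_contrast(
    concentrations: pd.DataFrame,
    value_column: str = "chl_total",
    ratio_threshold: float = 2.0,
) -> tuple[pd.DataFrame, str | None]:
    """Per-interval chlorophyll decline rates and the early-senescing flag.

    ``concentrations`` needs columns genotype, dap and ``value_column`` with
    >= 2 timepoints per genotype on a shared DAP grid.  Returns the decline
    rates (mg/L per day, positive = decline) and the genotype whose maximum
    decline rate exceeds every other genotype's by ``ratio_threshold``
    (None when no genotype stands out).
    """
    genotypes = sorted(concentrations["genotype"].unique())
    daps = None
    rows = []
    max_decline: dict[str, float] = {}
    for g in genotypes:
        sub = concentrations[concentrations["genotype"] == g].sort_values("dap")
        g_daps = tuple(sub["dap"])
        if len(g_daps) < 2:
            raise ValueError(f"genotype {g} has fewer than 2 timepoints")
        if daps is None:
            daps = g_daps
        elif g_daps != daps:
            raise ValueError(
                f"unmatched timepoints: {g} has {g_daps}, expected {daps}"
            )
        values = sub[value_column].to_numpy(dtype=float)
        dap_arr = np.asarray(g_daps, dtype=float)
        rates = -(np.diff(values) / np.diff(dap_arr))
        for (d0, d1), rate in zip(zip(dap_arr[:-1], dap_arr[1:]), rates):
            rows.append((g, int(d0), int(d1), rate))
        max_decline[g] = float(rates.max())
    rates_df = pd.DataFrame(
        rows, columns=["genotype", "dap_from", "dap_to", "decline_rate"]
    )
    flagged: str | None = None
    for g in genotypes:
        others = [max_decline[o] for o in genotypes if o != g]
        if others and max_decline[g] > ratio_threshold * max(max(others), 1e-12):
            flagged = g
    return rates_df, flagged


def delta_delta_ct(
    records: pd.DataFrame,
    calibrator: str,
) -> pd.DataFrame:
    """Relative expression (RQ = 2^-ddCt) per sample x gene.

    ``records`` needs columns sample_id, gene, replicate, ct_target,
    ct_reference.  Replicate Ct values are averaged per (sample, gene)
    before differencing; dCt = mean(Ct_target) - mean(Ct_reference),
    ddCt = dCt_sample - dCt_calibrator, RQ = 2^-ddCt (RQ of the calibrator
    is identically 1).
    """
    required = {"sample_id", "gene", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if records["ct_reference"].isna().any():
        bad = records.loc[records["ct_reference"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing reference-gene Ct for sample {bad}")
    means = records.groupby(["sample_id", "gene"], as_index=False)[
        ["ct_target", "ct_reference"]
    ].mean()
    means["delta_ct"] = means["ct_target"] - means["ct_reference"]
    out_rows = []
    for gene, sub in means.groupby("gene"):
        cal = sub[sub["sample_id"] == calibrator]
        if cal.empty:
            raise ValueError(f"calibrator sample {calibrator!r} missing for {gene}")
        cal_dct = float(cal["delta_ct"].iloc[0])
        for _, r in sub.iterrows():
            ddct = r["delta_ct"] - cal_dct
            out_rows.append((r["sample_id"], gene, r["delta_ct"], ddct, 2.0 ** -ddct))
    return pd.DataFrame(
        out_rows, columns=["sample_id", "gene", "delta_ct", "delta_delta_ct", "rq"]
    ).sort_values(["gene", "sample_id"], ignore_index=True)


def direction_concordance(
    rq: pd.DataFrame,
    contrast: pd.DataFrame,
    genotype: str = "ELS-1",
) -> pd.DataFrame:
    """Does the qPCR 20->30 DAP trend match the sequencing log2 fold change?

    ``rq`` is the delta_delta_ct output with sample ids like
    "ELS-1_20DAP"; ``contrast`` needs mirna_id and log2fc_els columns.
    A zero trend on either side agrees with any sign.
    """
    s20, s30 = f"{genotype}_20DAP", f"{genotype}_30DAP"
    rows = []
    for gene, sub in rq.groupby("gene"):
        if gene not in set(contrast["mirna_id"]):
            continue
        pivot = sub.set_index("sample_id")["rq"]
        if s20 not in pivot.index or s30 not in pivot.index:
            raise ValueError(f"gene {gene}: RQ series must cover 20 and 30 DAP")
        qpcr_trend = float(np.log2(pivot[s30] / pivot[s20]))
        seq_fc = float(
            contrast.loc[contrast["mirna_id"] == gene, "log2fc_els"].iloc[0]
        )
        agree = (
            qpcr_trend == 0.0 or seq_fc == 0.0
            or np.sign(qpcr_trend) == np.sign(seq_fc)
        )
        rows.append((gene, qpcr_trend, seq_fc, bool(agree)))
    return pd.DataFrame(
        rows, columns=["mirna_id", "qpcr_log2_trend", "seq_log2fc", "agree"]
    )
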