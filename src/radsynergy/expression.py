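"""Relative qPCR quantification (2^-ddCt) and the Welch t-test.

Fold changes assume perfect amplification efficiency (a doubling per
cycle), as in standard TaqMan relative quantification: each target Ct is
first normalised to a reference gene within the same sample (dCt), then
to the untreated non-irradiated control of the same timepoint (ddCt),
and ``fold = 2 ** -ddCt``.

The Welch (unequal-variance) t-test is applied to mortality data in two
comparison families: each irradiated condition against its non-irradiated
counterpart (starred ``*``), and each nanomaterial dose on irradiated
cells against the irradiated no-NM control (hashed ``#``).  No
multiple-testing correction is applied by default; a Benjamini-Hochberg
option exists for sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "delta_delta_ct",
    "fold_changes",
    "welch_t",
    "comparison_suite",
    "significance_stars",
]


@dataclass(frozen=True)
class WelchResult:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p value."""

    t: float
    df: float
    p: float


def delta_delta_ct(
    target_ct: float, ref_ct: float, target_ct_ctrl: float, ref_ct_ctrl: float
) -> float:
    """Fold change ``2 ** -ddCt`` relative to the control condition.

    ``ddCt = (target_ct - ref_ct) - (target_ct_ctrl - ref_ct_ctrl)``;
    lower target Ct than expected means more transcript, hence a fold
    change above 1.
    """
    for v in (target_ct, ref_ct, target_ct_ctrl, ref_ct_ctrl):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (target_ct - ref_ct) - (target_ct_ctrl - ref_ct_ctrl)
    return 2.0 ** (-ddct)


def fold_changes(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_query: str = "dose_surface == 0 and not irradiated",
) -> pd.DataFrame:
    """Per-condition fold changes for every non-reference gene.

    ``ct_table`` is tidy with columns gene, dose_surface, irradiated,
    timepoint_h, replicate, ct.  Replicate Cts are averaged per
    (gene, condition) before the ddCt; the normaliser is the untreated
    non-irradiated control *of the same timepoint*.  The control's own
    fold change is 1 by construction.
    """
    cond_cols = ["dose_surface", "irradiated", "timepoint_h"]
    if "nm_type" in ct_table.columns:
        cond_cols = ["nm_type"] + cond_cols
    mean_ct = (
        ct_table.groupby(["gene"] + cond_cols, as_index=False)["ct"].mean()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    rows = []
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    for t_h, group in targets.groupby("timepoint_h"):
        ctrl = mean_ct.query(control_query + " and timepoint_h == @t_h")
        for gene in group["gene"].unique():
            t_ctrl = ctrl[ctrl["gene"] == gene]
            r_ctrl = ctrl[ctrl["gene"] == reference_gene]
            if t_ctrl.empty or r_ctrl.empty:
                raise ValueError(
                    f"no control records for gene {gene!r} at {t_h} h"
                )
            for _, rec in group[group["gene"] == gene].iterrows():
                r = ref.loc[
                    (ref[cond_cols] == rec[cond_cols]).all(axis=1), "ct"
                ]
                if r.empty:
                    raise ValueError(
                        f"missing reference-gene record for condition {rec[cond_cols].to_dict()}"
                    )
                fc = delta_delta_ct(
                    rec["ct"], float(r.iloc[0]),
                    float(t_ctrl["ct"].iloc[0]), float(r_ctrl["ct"].iloc[0]),
                )
                row = {"gene": gene, **rec[cond_cols].to_dict(), "fold_change": fc}
                rows.append(row)
    return pd.DataFrame(rows)


def welch_t(group_a, group_b) -> WelchResult:
    """Two-sample Welch t-test (unequal variances), two-sided.

    Computed from the textbook formulas; each group needs >= 2 values
    and the pooled standard error must be nonzero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("degenerate: both groups have zero variance")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def significance_stars(p: float, symbol: str = "*") -> str:
    """Convention: p<0.05 one symbol, p<0.01 two, p<0.001 three."""
    if p < 0.001:
        return symbol * 3
    if p < 0.01:
        return symbol * 2
    if p < 0.05:
        return symbol
    return "ns"


def comparison_suite(
    death_table: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """The two Welch-test families applied to a tidy mortality table.

    Family ``ir_vs_ni`` (symbol ``*``): each irradiated condition against
    the non-irradiated condition at the same nanomaterial dose and
    timepoint.  Family ``nm_vs_ir_ctrl`` (symbol ``#``): each nonzero
    nanomaterial dose on irradiated cells against the irradiated dose-0
    control.  Conditions lacking >= 2 replicates are skipped with a
    warning.  ``bh_correct`` optionally applies Benjamini-Hochberg within
    each family (off by default, matching the uncorrected convention).
    """
    required = {"dose_surface", "irradiated", "timepoint_h", "replicate", "mortality"}
    missing = required - set(death_table.columns)
    if missing:
        raise ValueError(f"death table missing columns: {sorted(missing)}")

    def values(dose, irradiated, t_h):
        sel = death_table[
            (death_table["dose_surface"] == dose)
            & (death_table["irradiated"] == irradiated)
            & (death_table["timepoint_h"] == t_h)
        ]
        return sel["mortality"].to_numpy()

    rows = []
    for t_h in sorted(death_table["timepoint_h"].unique()):
        doses = sorted(death_table["dose_surface"].unique())
        ir_ctrl = values(0.0, True, t_h)
        for d in doses:
            ir_vals = values(d, True, t_h)
            ni_vals = values(d, False, t_h)
            for family, a, b, symbol in (
                ("ir_vs_ni", ir_vals, ni_vals, "*"),
                ("nm_vs_ir_ctrl", ir_vals, ir_ctrl, "#"),
            ):
                if family == "nm_vs_ir_ctrl" and d == 0.0:
                    continue
                if a.size < 2 or b.size < 2:
                    warnings.warn(
                        f"skipping {family} at dose {d}, t={t_h} h: "
                        "fewer than two replicates"
                    )
                    continue
                try:
                    res = welch_t(a, b)
                except ValueError as err:
                    warnings.warn(f"skipping {family} at dose {d}, t={t_h} h: {err}")
                    continue
                rows.append({
                    "family": family, "dose_surface": d, "timepoint_h": t_h,
                    "t": res.t, "df": res.df, "p": res.p,
                    "stars": significance_stars(res.p, symbol),
                    "significant": res.p < alpha,
                })
    out = pd.DataFrame(rows)
    if bh_correct and not out.empty:
        for family in out["family"].unique():
            mask = out["family"] == family
            p_adj = stats.false_discovery_control(out.loc[mask, "p"], method="bh")
            out.loc[mask, "p_adjusted"] = p_adj
            out.loc[mask, "significant"] = p_adj < alpha
    return out
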