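"""Normalization, per-chemical statistics, Wnt Score, hit calling and QC.

The analysis mirrors a plate-based dual-luciferase screen:

1. Per plate, the reporter ratio (firefly / Renilla) is median-centered
   to remove multiplicative plate effects ("Wnt luciferase ratio"), and
   the raw Renilla channel is median-centered the same way ("Cell
   Health" — a viability proxy, since Renilla is driven by a constitutive
   promoter).
2. Per well, a log2 fold change is taken against the plate's vehicle
   wells.
3. Replicate days are averaged per chemical x concentration (plates
   within a day first), with a two-sided Welch t-test against the
   matched vehicle wells.
4. Per chemical, metrics are averaged (unweighted) over concentrations
   and combined into the toxicity-penalized Wnt Score
   (mean log2FC x mean Cell Health by default; a variant additionally
   multiplies by the concentration-response slope).
5. Hits are chemicals passing p < alpha, |log2FC| > 1 and
   |Wnt Score| > 0.4; concentration-dependent toxicity is flagged from
   the Cell Health log2FC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling cutoffs for the screen."""

    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_abs_wnt_score: float = 0.4
    toxicity_log2fc_cutoff: float = -1.0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_abs_log2fc <= 0 or self.min_abs_wnt_score <= 0:
            raise ValueError("magnitude thresholds must be positive")


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize the wells of one (plate_id, replicate_day).

    Adds raw_ratio (firefly/Renilla), wnt_ratio and cell_health (each
    median-centered so the plate median is exactly 1), and per-well log2
    fold changes of both metrics against the mean (log scale) of the
    plate's vehicle wells.  Wells with Renilla = 0 are flagged dead and
    excluded with a warning.
    """
    if wells["plate_id"].nunique() > 1 or wells["replicate_day"].nunique() > 1:
        raise ValueError("normalize_plate expects wells of a single plate/day")
    dead = wells["renilla"] <= 0
    if dead.any():
        logger.warning(
            "excluding %d dead well(s) (renilla = 0) on plate %s day %s",
            int(dead.sum()), wells["plate_id"].iat[0],
            wells["replicate_day"].iat[0],
        )
        wells = wells[~dead]
    n_vehicle = int((wells["role"] == "vehicle").sum())
    if n_vehicle == 0:
        raise ValueError(
            "plate has no vehicle wells: log2 fold-change reference undefined"
        )

    out = wells.copy()
    out["raw_ratio"] = out["firefly"] / out["renilla"]
    out["wnt_ratio"] = out["raw_ratio"] / out["raw_ratio"].median()
    out["cell_health"] = out["renilla"] / out["renilla"].median()

    veh = out["role"] == "vehicle"
    veh_log_ratio = np.log2(out.loc[veh, "wnt_ratio"]).mean()
    veh_log_health = np.log2(out.loc[veh, "cell_health"]).mean()
    out["log2fc"] = np.log2(out["wnt_ratio"]) - veh_log_ratio
    out["ch_log2fc"] = np.log2(out["cell_health"]) - veh_log_health
    return out


def normalize_screen(wells: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_plate` to every (plate_id, replicate_day)."""
    groups = [
        normalize_plate(g)
        for _, g in wells.groupby(["plate_id", "replicate_day"], sort=True)
    ]
    return pd.concat(groups, ignore_index=True)


def vehicle_comparison_test(test_values, vehicle_values) -> float:
    """Two-sided unpaired Welch t-test p-value; NaN when degenerate.

    Degenerate cases (fewer than two values in either group, or zero
    pooled variance with zero mean difference handled by the test itself)
    report NaN rather than a fabricated p-value.
    """
    a = np.asarray(test_values, dtype=float)
    b = np.asarray(vehicle_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else float("nan")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def response_slope(values, concentrations) -> float:
    """OLS slope of a metric against log10(concentration in µM).

    Used for both the reporter log2FC (response slope) and Cell Health
    (toxicity slope).  Returns NaN when fewer than two distinct positive
    concentrations are available.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    keep = np.isfinite(v) & (c > 0)
    v, c = v[keep], c[keep]
    if len(np.unique(c)) < 2:
        return float("nan")
    x = np.log10(c)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (v - v.mean()))
    return float(sxy / sxx)


def wnt_score(
    mean_log2fc: float,
    mean_cell_health: float,
    slope: float | None = None,
    variant: str = "legend",
) -> float:
    """Toxicity-penalized activity score.

    ``legend`` (default): mean log2FC over concentrations times mean Cell
    Health over concentrations — loss of viability (Cell Health < 1)
    shrinks the score toward zero.  ``slope`` additionally multiplies by
    the concentration-response slope of the log2FC.
    """
    if variant == "legend":
        return float(mean_log2fc * mean_cell_health)
    if variant == "slope":
        if slope is None or not np.isfinite(slope):
            return float("nan")
        return float(mean_log2fc * slope * mean_cell_health)
    raise ValueError(f"unknown wnt_score variant {variant!r}")


def summarize_screen(
    normalized: pd.DataFrame,
    wnt_score_variant: str = "legend",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per chemical x concentration summaries and per-chemical scores.

    Averaging order follows the replicate design: when one chemical x
    concentration appears on multiple plates within a day, plate values
    are averaged first; replicate days are then averaged.  p-values
    compare the per-day log2FC values against the log2FC of the vehicle
    wells on the plates that carried the chemical (Welch, two-sided).
    Chemical-level fields are unweighted means over concentrations.
    """
    test = normalized[~normalized["role"].isin(["vehicle"])]
    veh = normalized[normalized["role"] == "vehicle"]
    veh_by_plate = veh.groupby(["plate_id"])

    summaries = []
    for (cid, conc), g in test.groupby(["chemical_id", "concentration_uM"],
                                       sort=True):
        per_day = g.groupby("replicate_day")[["log2fc", "cell_health",
                                              "ch_log2fc"]].mean()
        plates = g["plate_id"].unique()
        veh_vals = veh[veh["plate_id"].isin(plates)]
        p = vehicle_comparison_test(per_day["log2fc"], veh_vals["log2fc"])
        p_ch = vehicle_comparison_test(per_day["ch_log2fc"],
                                       veh_vals["ch_log2fc"])
        summaries.append((
            cid, conc,
            per_day["log2fc"].mean(), per_day["cell_health"].mean(),
            per_day["ch_log2fc"].mean(), p, p_ch, len(per_day),
        ))
    summary_df = pd.DataFrame(summaries, columns=[
        "chemical_id", "concentration_uM", "mean_log2fc", "mean_cell_health",
        "mean_ch_log2fc", "p_value", "p_value_cell_health", "n_replicates",
    ])

    scores = []
    for cid, g in summary_df.groupby("chemical_id", sort=True):
        mean_l2fc = g["mean_log2fc"].mean()
        mean_ch = g["mean_cell_health"].mean()
        mean_chl2 = g["mean_ch_log2fc"].mean()
        r_slope = response_slope(g["mean_log2fc"], g["concentration_uM"])
        t_slope = response_slope(g["mean_cell_health"], g["concentration_uM"])
        score = wnt_score(mean_l2fc, mean_ch, r_slope, wnt_score_variant)
        min_p = g["p_value"].min()
        min_p_ch = g["p_value_cell_health"].min()
        scores.append((cid, mean_l2fc, mean_ch, mean_chl2, r_slope, t_slope,
                       score, min_p, min_p_ch))
    score_df = pd.DataFrame(scores, columns=[
        "chemical_id", "mean_log2fc_all_conc", "mean_cell_health_all_conc",
        "mean_ch_log2fc_all_conc", "response_slope", "toxicity_slope",
        "wnt_score", "min_p", "min_p_cell_health",
    ])
    score_df.attrs["wnt_score_variant"] = wnt_score_variant
    return summary_df, score_df


def call_hits(
    scores: pd.DataFrame,
    thresholds: HitThresholds = HitThresholds(),
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Classify chemicals as activator / inhibitor / toxic / none.

    Activators need p < alpha, mean log2FC above +min_abs_log2fc and
    |Wnt Score| above min_abs_wnt_score; inhibitors the mirrored log2FC
    rule.  Concentration-dependent toxicity (Cell Health log2FC below the
    cutoff with p < alpha) takes precedence in hit_class, but the
    activator/inhibitor facts are retained as boolean columns.  With
    ``bh_correction``, Benjamini-Hochberg q-values are reported as an
    extra column (an extension; classification still uses raw p).
    """
    out = scores.copy()
    sig = out["min_p"] < thresholds.alpha
    out["is_activator"] = (
        sig
        & (out["mean_log2fc_all_conc"] > thresholds.min_abs_log2fc)
        & (out["wnt_score"].abs() > thresholds.min_abs_wnt_score)
    )
    out["is_inhibitor"] = (
        sig
        & (out["mean_log2fc_all_conc"] < -thresholds.min_abs_log2fc)
        & (out["wnt_score"].abs() > thresholds.min_abs_wnt_score)
    )
    out["is_toxic"] = (
        (out["min_p_cell_health"] < thresholds.alpha)
        & (out["mean_ch_log2fc_all_conc"] < thresholds.toxicity_log2fc_cutoff)
    )
    hit_class = np.select(
        [out["is_toxic"], out["is_activator"], out["is_inhibitor"]],
        ["toxic", "activator", "inhibitor"],
        default="none",
    )
    out["hit_class"] = hit_class
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        mask = out["min_p"].notna()
        out["q_value_bh"] = np.nan
        if mask.any():
            out.loc[mask, "q_value_bh"] = multipletests(
                out.loc[mask, "min_p"], method="fdr_bh"
            )[1]
    for name, value in (("alpha", thresholds.alpha),
                        ("min_abs_log2fc", thresholds.min_abs_log2fc),
                        ("min_abs_wnt_score", thresholds.min_abs_wnt_score),
                        ("toxicity_log2fc_cutoff",
                         thresholds.toxicity_log2fc_cutoff)):
        logger.info("hit threshold %s = %g", name, value)
        out.attrs[name] = value
    return out


def z_factor(positive, negative) -> float:
    """Assay-quality Z-factor: 1 − 3(σp + σn)/|μp − μn| (sample sd).

    Always ≤ 1; equal group means give the −inf sentinel (QC failure).
    """
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if len(p) < 2 or len(n) < 2:
        raise ValueError("z_factor needs at least two values per group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        return NEG_INF
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def qc_screen(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-plate QC: control Z-factors, control sign checks, vehicle CV.

    Activator (inhibitor) controls must show positive (negative) mean
    log2FC; a sign violation flags a potential plate swap.  Plates
    without control wells are flagged missing_controls rather than
    failing hard.
    """
    rows = []
    for (plate, day), g in normalized.groupby(["plate_id", "replicate_day"],
                                              sort=True):
        veh = g.loc[g["role"] == "vehicle", "log2fc"]
        act = g.loc[g["role"] == "control_activator", "log2fc"]
        inh = g.loc[g["role"] == "control_inhibitor", "log2fc"]
        veh_ratio = g.loc[g["role"] == "vehicle", "raw_ratio"]
        vehicle_cv = (float(veh_ratio.std(ddof=1) / veh_ratio.mean())
                      if len(veh_ratio) >= 2 else float("nan"))
        missing = act.empty or inh.empty
        z_act = z_factor(act, veh) if len(act) >= 2 and len(veh) >= 2 else float("nan")
        z_inh = z_factor(inh, veh) if len(inh) >= 2 and len(veh) >= 2 else float("nan")
        act_pass = bool(len(act) and act.mean() > 0)
        inh_pass = bool(len(inh) and inh.mean() < 0)
        rows.append((plate, day, z_act, z_inh, act_pass, inh_pass,
                     vehicle_cv, missing))
        if missing:
            logger.warning("plate %s day %s lacks control wells", plate, day)
        elif not (act_pass and inh_pass):
            logger.warning(
                "plate %s day %s control sign check failed "
                "(possible plate swap)", plate, day,
            )
    return pd.DataFrame(rows, columns=[
        "plate_id", "replicate_day", "z_factor_activators",
        "z_factor_inhibitors", "activators_pass_sign",
        "inhibitors_pass_sign", "vehicle_cv", "missing_controls",
    ])


def compare_context_toxicity(
    context_a: pd.DataFrame,
    context_b: pd.DataFrame,
    value_col: str = "toxicity",
    labels: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Compare per-chemical toxicity between two cellular contexts.

    Each table needs chemical_id and a toxicity value column (replicate
    or concentration rows are averaged per chemical first).  Values are
    median-centered across chemicals within each context (divided by the
    median, so 1 = typical health in that context), then joined; the
    output is ranked by |difference| to surface context-specific
    toxicants.
    """
    def centered(df: pd.DataFrame) -> pd.Series:
        if value_col not in df.columns:
            raise ValueError(f"missing column {value_col!r}")
        per_chem = df.groupby("chemical_id")[value_col].mean()
        return per_chem / per_chem.median()

    a = centered(context_a)
    b = centered(context_b)
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    if dropped:
        logger.info("dropping %d chemicals absent from one context", dropped)
    if common.empty:
        raise ValueError("no overlapping chemical ids between contexts")
    la, lb = labels
    out = pd.DataFrame({
        "chemical_id": common,
        f"centered_{la}": a.loc[common].values,
        f"centered_{lb}": b.loc[common].values,
    })
    out["difference"] = out[f"centered_{la}"] - out[f"centered_{lb}"]
    out = out.reindex(
        out["difference"].abs().sort_values(ascending=False, kind="mergesort").index
    )
    return out.reset_index(drop=True)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str = "EIF4A2",
    control_condition: str = "vehicle",
) -> pd.DataFrame:
    """Relative qPCR quantification by the ΔΔCt method.

    ΔCt = Ct_target − Ct_reference per (condition, replicate); ΔΔCt =
    mean ΔCt_treated − mean ΔCt_control; fold change = 2^(−ΔΔCt).
    Returns one row per (gene, non-control condition) with the fold
    change and the per-replicate fold changes (2^−(ΔCt_rep − mean
    ΔCt_control)) for downstream testing.
    """
    genes = ct_table["gene"].unique()
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    if control_condition not in ct_table["condition"].unique():
        raise ValueError(
            f"control condition {control_condition!r} absent from table"
        )
    ref = ct_table[ct_table["gene"] == reference_gene].set_index(
        ["condition", "replicate"]
    )["ct"]
    rows = []
    for gene in genes:
        sub = ct_table[ct_table["gene"] == gene]
        dct = (
            sub.set_index(["condition", "replicate"])["ct"] - ref
        ).rename("dct").reset_index()
        ctrl_mean = dct.loc[dct["condition"] == control_condition, "dct"].mean()
        for cond, g in dct.groupby("condition"):
            if cond == control_condition:
                continue
            ddct = g["dct"].mean() - ctrl_mean
            per_rep = 2.0 ** (-(g["dct"] - ctrl_mean))
            rows.append((gene, cond, ddct, 2.0 ** (-ddct),
                         per_rep.tolist()))
    return pd.DataFrame(rows, columns=[
        "gene", "condition", "delta_delta_ct", "fold_change",
        "replicate_fold_changes",
    ])
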