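"""Prioritization of screen hits by predicted human exposure.

Predicted exposure tables give a modeled intake (mg per kg bodyweight
per day, upper bound of the 95% CI by default) per chemical and
demographic — e.g. reproductive-age females (16-49), the demographic
most representative of maternal/fetal exposure.  Hits from the screen
are joined to these estimates and ranked so high-exposure modulators
surface first for follow-up.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

EXPOSURE_COL = "exposure_mgkgday_upper95"
MEDIAN_COL = "exposure_mgkgday_median"


def load_exposure_table(path, demographic: str,
                        exposure_col: str = EXPOSURE_COL) -> pd.DataFrame:
    """Load exposure records for one demographic.

    The CSV needs columns chemical_id, demographic and the exposure
    column (upper 95% CI by default; the median column is carried along
    when present).  An unknown demographic raises with the available
    labels listed.
    """
    df = pd.read_csv(path)
    for col in ("chemical_id", "demographic", exposure_col):
        if col not in df.columns:
            raise ValueError(f"exposure table missing column {col!r}")
    available = sorted(df["demographic"].unique())
    sub = df[df["demographic"] == demographic].copy()
    if sub.empty:
        raise ValueError(
            f"demographic {demographic!r} not found; available: {available}"
        )
    vals = pd.to_numeric(sub[exposure_col], errors="coerce")
    bad = vals.isna() | (vals < 0)
    if bad.any():
        raise ValueError(
            f"malformed exposure values at rows {sub.index[bad].tolist()}"
        )
    sub[exposure_col] = vals.astype(float)
    keep = ["chemical_id", "demographic", exposure_col]
    if MEDIAN_COL in sub.columns and exposure_col != MEDIAN_COL:
        keep.append(MEDIAN_COL)
    return sub[keep].reset_index(drop=True)


def exposure_percentiles(records: pd.DataFrame,
                         exposure_col: str = EXPOSURE_COL) -> pd.DataFrame:
    """Add a percentile column: 100 x mean-rank(exposure) / n.

    Ties receive the mean rank, so the percentile is invariant under any
    monotone transform of the exposures.
    """
    if records.empty:
        raise ValueError("no exposure records")
    out = records.copy()
    ranks = rankdata(out[exposure_col], method="average")
    out["percentile"] = 100.0 * ranks / len(out)
    return out


def prioritize(
    scores: pd.DataFrame,
    exposures: pd.DataFrame,
    exposure_col: str = EXPOSURE_COL,
    join_key: str = "chemical_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank screened chemicals by predicted exposure within hit class.

    Inner-joins scores with exposure records on ``join_key``; returns
    (ranked table, no-exposure annex).  Hits sort above non-hits, and
    within each class rows sort by exposure descending.  Hit chemicals
    lacking an exposure record go to the annex rather than being
    silently dropped.
    """
    exp = exposure_percentiles(exposures, exposure_col=exposure_col)
    joined = scores.merge(exp, on=join_key, how="inner")
    if joined.empty:
        raise ValueError("no chemicals shared between scores and exposures")
    if "hit_class" in joined.columns:
        joined["is_hit"] = joined["hit_class"].isin(["activator", "inhibitor"])
    else:
        joined["is_hit"] = False
    joined = joined.sort_values(
        ["is_hit", exposure_col, join_key],
        ascending=[False, False, True], kind="mergesort",
    ).reset_index(drop=True)

    missing = scores[~scores[join_key].isin(exp[join_key])].copy()
    if "hit_class" in missing.columns:
        annex = missing[missing["hit_class"] != "none"].reset_index(drop=True)
    else:
        annex = missing.reset_index(drop=True)
    logger.info("%d scored chemicals lack exposure records "
                "(%d of them hits)", len(missing), len(annex))
    return joined, annex


def simulate_exposure_table(
    chemical_ids,
    demographic: str = "females_16_49",
    mu: float = -6.0,
    sigma: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic exposure table (lognormal mg/kg-bw/day), seeded.

    Stands in for external exposure predictions in tests and demos: real
    modeled intakes span orders of magnitude and are right-skewed, which
    a lognormal reproduces.  The upper-95% column is the median times a
    fixed uncertainty factor.
    """
    rng = np.random.default_rng(seed)
    ids = list(chemical_ids)
    median = np.exp(rng.normal(mu, sigma, size=len(ids)))
    return pd.DataFrame({
        "chemical_id": ids,
        "demographic": demographic,
        EXPOSURE_COL: median * 3.0,
        MEDIAN_COL: median,
    })
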