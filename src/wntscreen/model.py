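"""Model/Results interface over the screen analysis.

`WntScreen` is constructed from a well-level measurement table (see
:mod:`wntscreen.data`); its :meth:`~WntScreen.fit` runs plate
normalization, replicate summarization, Wnt scoring, hit calling and
plate QC, returning a :class:`ScreenResults` that carries the estimate
tables, diagnostics and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import metrics
from .data import validate_wells
from .metrics import HitThresholds


class WntScreen:
    """Dual-luciferase Wnt reporter screen model.

    Parameters
    ----------
    wells : DataFrame
        One row per well with the canonical measurement columns
        (plate_id, well, chemical_id, concentration_uM, firefly,
        renilla, replicate_day, role).
    chemicals : DataFrame, optional
        Chemical annotations (chemical_id, name, casrn, smiles) used to
        decorate results.
    """

    def __init__(self, wells: pd.DataFrame, chemicals: pd.DataFrame | None = None):
        self.wells = validate_wells(wells.copy())
        self.chemicals = chemicals

    @classmethod
    def from_dataframe(cls, wells: pd.DataFrame,
                       chemicals: pd.DataFrame | None = None) -> "WntScreen":
        return cls(wells, chemicals)

    def fit(
        self,
        thresholds: HitThresholds = HitThresholds(),
        wnt_score_variant: str = "legend",
        bh_correction: bool = False,
    ) -> "ScreenResults":
        """Run the full analysis and return a :class:`ScreenResults`."""
        normalized = metrics.normalize_screen(self.wells)
        summaries, scores = metrics.summarize_screen(
            normalized, wnt_score_variant=wnt_score_variant
        )
        scores = metrics.call_hits(scores, thresholds,
                                   bh_correction=bh_correction)
        qc = metrics.qc_screen(normalized)
        if self.chemicals is not None:
            scores = scores.merge(
                self.chemicals[["chemical_id", "name"]],
                on="chemical_id", how="left",
            )
        return ScreenResults(
            model=self,
            normalized=normalized,
            summaries=summaries,
            scores=scores,
            qc=qc,
            thresholds=thresholds,
            wnt_score_variant=wnt_score_variant,
        )


@dataclass
class ScreenResults:
    """Fitted screen: normalized wells, summaries, scores and QC."""

    model: WntScreen
    normalized: pd.DataFrame
    summaries: pd.DataFrame
    scores: pd.DataFrame
    qc: pd.DataFrame
    thresholds: HitThresholds
    wnt_score_variant: str = "legend"

    @property
    def hits(self) -> pd.DataFrame:
        """Chemicals classified activator or inhibitor (non-toxic hits)."""
        return self.scores[self.scores["hit_class"].isin(
            ["activator", "inhibitor"])]

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the fitted screen."""
        s = self.scores
        counts = s["hit_class"].value_counts()
        lines = [
            "Wnt reporter screen summary",
            "===========================",
            f"wells: {len(self.model.wells)}   chemicals: {len(s)}   "
            f"plates x days: {len(self.qc)}",
            f"wnt score variant: {self.wnt_score_variant}",
            (f"thresholds: alpha={self.thresholds.alpha}, "
             f"|log2FC|>{self.thresholds.min_abs_log2fc}, "
             f"|WntScore|>{self.thresholds.min_abs_wnt_score}, "
             f"toxic CH log2FC<{self.thresholds.toxicity_log2fc_cutoff}"),
            ("hit classes: "
             + ", ".join(f"{k}={counts.get(k, 0)}"
                         for k in ("activator", "inhibitor", "toxic", "none"))),
            "",
            f"top {top} chemicals by |Wnt Score|:",
        ]
        cols = ["chemical_id", "mean_log2fc_all_conc",
                "mean_cell_health_all_conc", "wnt_score", "min_p",
                "hit_class"]
        ranked = s.reindex(
            s["wnt_score"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(ranked[cols].to_string(index=False,
                                            float_format="%.4g".__mod__))
        zq = self.qc[["z_factor_activators", "z_factor_inhibitors"]]
        lines += [
            "",
            (f"median plate Z-factor: activators "
             f"{zq['z_factor_activators'].median():.3f}, inhibitors "
             f"{zq['z_factor_inhibitors'].median():.3f}"),
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        from .plots import plot_volcano

        return plot_volcano(self, ax=ax)

    def plot_health_vs_activity(self, ax=None):
        from .plots import plot_health_vs_activity

        return plot_health_vs_activity(self, ax=ax)
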