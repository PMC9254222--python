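"""End-to-end pipeline: simulate → normalize → score → qc → cluster →
prioritize, with a checksummed run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import read_chemical_table, read_plate_table, write_results
from .exposure import EXPOSURE_COL, load_exposure_table, prioritize
from .metrics import HitThresholds
from .model import WntScreen
from .plots import plot_summary
from .simulate import ScreenConfig, simulate_screen
from .similarity import cluster_chemicals

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    out_dir: str = "results"
    plate_table: str | None = None
    chemical_table: str | None = None
    exposure_table: str | None = None
    exposure_demographic: str = "females_16_49"
    simulate: bool = False
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    wnt_score_variant: str = "legend"
    bh_correction: bool = False
    cluster_linkage: str = "average"
    cluster_cut_k: int | None = None
    cluster_max_dist: int = 7
    seed: int = 0
    make_plots: bool = True
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = asdict(self)
        d["screen"] = json.loads(self.screen.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "screen" in d:
            d["screen"] = ScreenConfig.from_json(json.dumps(d["screen"]))
        if "thresholds" in d:
            d["thresholds"] = HitThresholds(**d["thresholds"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage where it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write tables, figures and a manifest.

    Reruns with the same config (including seed) reproduce byte-identical
    result tables; the manifest records the config hash, package version
    and a sha256 checksum per output file so any post-hoc edit is
    detectable.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    stage = "input"
    try:
        if config.simulate:
            stage = "simulate"
            screen_cfg = config.screen
            screen_cfg.seed = config.seed
            wells, truth = simulate_screen(screen_cfg)
            tables["wells"] = wells
            tables["ground_truth"] = truth
        else:
            if not config.plate_table:
                raise FileNotFoundError(
                    "no plate table given and --simulate not requested"
                )
            wells = read_plate_table(config.plate_table)

        chemicals = None
        if config.chemical_table:
            stage = "chemicals"
            chemicals = read_chemical_table(config.chemical_table)

        stage = "normalize/score"
        results = WntScreen.from_dataframe(wells, chemicals).fit(
            thresholds=config.thresholds,
            wnt_score_variant=config.wnt_score_variant,
            bh_correction=config.bh_correction,
        )
        tables["normalized_wells"] = results.normalized
        tables["summaries"] = results.summaries
        tables["scores"] = results.scores.drop(
            columns=["replicate_fold_changes"], errors="ignore"
        )
        stage = "qc"
        tables["qc"] = results.qc

        prioritized = None
        if (chemicals is not None and "smiles" in chemicals.columns
                and chemicals["smiles"].notna().sum() >= 2):
            stage = "cluster"
            dist, clusters = cluster_chemicals(
                chemicals,
                max_dist=config.cluster_max_dist,
                linkage=config.cluster_linkage,
                cut_k=config.cluster_cut_k,
            )
            tables["distance_matrix"] = dist.reset_index(names="chemical_id")
            if clusters.flat is not None:
                tables["clusters"] = clusters.flat.rename_axis(
                    "chemical_id").reset_index()
            if clusters.embedding is not None:
                tables["mds_embedding"] = clusters.embedding.reset_index(
                    names="chemical_id")

        if config.exposure_table:
            stage = "prioritize"
            exposures = load_exposure_table(
                config.exposure_table, config.exposure_demographic
            )
            prioritized, annex = prioritize(tables["scores"], exposures)
            tables["prioritized"] = prioritized.drop(
                columns=["name"], errors="ignore")
            tables["prioritized_no_exposure"] = annex

        stage = "write"
        written = write_results(tables, out_dir)

        figures: list[Path] = []
        if config.make_plots:
            stage = "plot"
            figures = plot_summary(results, out_dir / "figures",
                                   prioritized=prioritized)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "tables": {name: file_checksum(p) for name, p in sorted(written.items())},
        "figures": [str(p) for p in figures],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote %d tables and manifest to %s", len(written), out_dir)
    return manifest


def verify_manifest(out_dir) -> bool:
    """True iff every table checksum in the manifest still matches."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(
        file_checksum(out_dir / f"{name}.tsv") == digest
        for name, digest in manifest["tables"].items()
    )
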