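"""Synthetic dual-luciferase screen generator with known ground truth.

Emulates a 384-well reporter screen: each test chemical is dosed over an
ascending concentration series on four replicate days (one well per
chemical per concentration per day), with solvent-only vehicle wells and
six spiked control chemicals (three reporter activators, three
inhibitors) placed at seeded-random positions on every plate.

The generative model per well is

    renilla = baseline_renilla * plate_effect * viability(c) * eps_r
    firefly = baseline_firefly * plate_effect * activity(c) * viability(c) * eps_f

where activity and viability are Hill curves parameterized by the
chemical's ground truth, plate_effect is a single lognormal multiplicative
scalar shared by both channels of one (plate, day), and eps are per-well
lognormal noise terms.  Because the reporter ratio divides firefly by
Renilla, viability and the plate effect cancel in the ratio while the
Renilla channel alone carries the toxicity signal — exactly the structure
the plate-median normalization downstream is designed to exploit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import VEHICLE, WELL_COLUMNS, validate_wells, well_name

PLATE_ROWS, PLATE_COLS = 16, 24
PLATE_CAPACITY = PLATE_ROWS * PLATE_COLS


@dataclass(frozen=True)
class ChemicalTruth:
    """Ground-truth concentration-response parameters for one chemical.

    emax is the maximal fold-activation of the reporter (1 = inactive,
    > 1 activator, < 1 inhibitor); ec50 the half-maximal activation
    concentration in µM; tc50 the concentration at which viability drops
    to 0.5 (math.inf = nontoxic); hill_n / hill_t the Hill coefficients.
    """

    chemical_id: str
    emax: float = 1.0
    ec50: float = 1.0
    hill_n: float = 1.0
    tc50: float = math.inf
    hill_t: float = 1.0

    def __post_init__(self):
        if self.emax <= 0 or self.ec50 <= 0 or self.tc50 <= 0:
            raise ValueError("emax, ec50 and tc50 must be positive")
        if self.hill_n <= 0 or self.hill_t <= 0:
            raise ValueError("Hill coefficients must be positive")


def default_controls() -> list[ChemicalTruth]:
    """Six spiked control chemicals: three activators, three inhibitors."""
    acts = [
        ChemicalTruth(f"CTRL_ACT_{i}", emax=8.0, ec50=0.5, hill_n=1.5)
        for i in (1, 2, 3)
    ]
    inhs = [
        ChemicalTruth(f"CTRL_INH_{i}", emax=0.125, ec50=0.5, hill_n=1.5)
        for i in (1, 2, 3)
    ]
    return acts + inhs


#: Conventional half-log dosing series, µM.
DEFAULT_CONCENTRATIONS = (0.1, 0.316, 1.0, 3.16, 10.0, 31.6)


@dataclass
class ScreenConfig:
    """Layout and noise parameters of a simulated screen."""

    n_test_chemicals: int = 80
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    n_replicate_days: int = 4
    n_vehicle_wells_per_plate: int = 16
    control_chemicals: Sequence[ChemicalTruth] = field(default_factory=default_controls)
    control_concentration_uM: float = 10.0
    control_replicates_per_plate: int = 2
    plate_effect_sigma: float = 0.15
    noise_sigma: float = 0.2
    channel_corr: float = 0.0
    baseline_firefly: float = 10_000.0
    baseline_renilla: float = 5_000.0
    seed: int = 0

    def __post_init__(self):
        self.concentrations = tuple(self.concentrations)
        self.control_chemicals = tuple(self.control_chemicals)
        conc = list(self.concentrations)
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.control_chemicals) != 6:
            raise ValueError("exactly six control chemicals are required")
        if not (-1.0 <= self.channel_corr <= 1.0):
            raise ValueError("channel_corr must be in [-1, 1]")

    def to_json(self) -> str:
        d = asdict(self)
        d["concentrations"] = list(self.concentrations)
        d["control_chemicals"] = [
            {k: (None if v == math.inf else v) for k, v in asdict(t).items()}
            for t in self.control_chemicals
        ]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScreenConfig":
        d = json.loads(text)
        if "control_chemicals" in d:
            d["control_chemicals"] = [
                ChemicalTruth(**{k: (math.inf if v is None else v)
                                 for k, v in t.items()})
                for t in d["control_chemicals"]
            ]
        return cls(**d)


def activity(c: float, truth: ChemicalTruth) -> float:
    """Hill fold-activation of the reporter at concentration c (µM).

    Returns 1 + (emax − 1) c^n / (c^n + ec50^n); 1 at c = 0, monotone in
    c, saturating at emax.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0:
        return 1.0
    cn = c ** truth.hill_n
    return 1.0 + (truth.emax - 1.0) * cn / (cn + truth.ec50 ** truth.hill_n)


def viability(c: float, truth: ChemicalTruth) -> float:
    """Hill viability fraction at concentration c: 1 / (1 + (c/tc50)^h)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c == 0 or math.isinf(truth.tc50):
        return 1.0
    return 1.0 / (1.0 + (c / truth.tc50) ** truth.hill_t)


def default_truths(config: ScreenConfig, rng: np.random.Generator | None = None,
                   null: bool = True) -> list[ChemicalTruth]:
    """Inactive (emax = 1), nontoxic truths for every test chemical."""
    return [ChemicalTruth(f"CHEM_{i:04d}") for i in range(1, config.n_test_chemicals + 1)]


class PlateLayoutError(ValueError):
    pass


def simulate_screen(
    config: ScreenConfig,
    truths: Sequence[ChemicalTruth] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen; returns (wells DataFrame, ground-truth table).

    One well per (test chemical, concentration, replicate day).  Test
    chemical x concentration pairs are packed onto as many plates as
    needed; every plate additionally carries the vehicle wells and the six
    control chemicals at seeded-random positions, re-randomized per plate
    as in a real spike-in design.  Fully reproducible from config.seed.
    """
    if truths is None:
        truths = default_truths(config)
    truth_by_id = {t.chemical_id: t for t in truths}
    for ctrl in config.control_chemicals:
        truth_by_id.setdefault(ctrl.chemical_id, ctrl)
    if len(truths) < config.n_test_chemicals:
        raise ValueError("truths must cover all test chemicals")

    test_ids = [t.chemical_id for t in truths[: config.n_test_chemicals]]
    concs = list(config.concentrations)
    pairs = [(cid, c) for cid in test_ids for c in concs]

    n_control_wells = len(config.control_chemicals) * config.control_replicates_per_plate
    fixed = config.n_vehicle_wells_per_plate + n_control_wells
    capacity = PLATE_CAPACITY - fixed
    if capacity <= 0:
        raise PlateLayoutError(
            "vehicle + control wells exceed plate capacity; reduce them"
        )
    n_plates = math.ceil(len(pairs) / capacity)

    rng = np.random.default_rng(config.seed)
    sigma = config.noise_sigma
    rho = config.channel_corr
    records: list[tuple] = []
    truth_rows = []
    for t in list(truths[: config.n_test_chemicals]) + list(config.control_chemicals):
        truth_rows.append((t.chemical_id, t.emax, t.ec50, t.hill_n, t.tc50, t.hill_t))

    for day in range(1, config.n_replicate_days + 1):
        for p in range(n_plates):
            plate_id = f"P{p + 1:02d}"
            plate_pairs = pairs[p * capacity: (p + 1) * capacity]
            n_wells = len(plate_pairs) + fixed
            # seeded-random well positions for everything on this plate
            positions = rng.permutation(PLATE_CAPACITY)[:n_wells]
            plate_effect = (
                float(rng.lognormal(0.0, config.plate_effect_sigma))
                if config.plate_effect_sigma > 0 else 1.0
            )

            entries: list[tuple[str, float, str]] = []
            entries += [(VEHICLE, 0.0, "vehicle")] * config.n_vehicle_wells_per_plate
            for ctrl in config.control_chemicals:
                ctrl_role = ("control_activator" if ctrl.emax > 1
                             else "control_inhibitor")
                entries += [(ctrl.chemical_id, config.control_concentration_uM,
                             ctrl_role)] * config.control_replicates_per_plate
            entries += [(cid, c, "test") for cid, c in plate_pairs]

            for pos, (cid, conc, role) in zip(positions, entries):
                truth = truth_by_id.get(cid)
                if role == "vehicle":
                    act = via = 1.0
                else:
                    act = activity(conc, truth)
                    via = viability(conc, truth)
                if sigma > 0:
                    z = rng.standard_normal(2)
                    zf = z[0]
                    zr = rho * z[0] + math.sqrt(1.0 - rho * rho) * z[1]
                    eps_f = math.exp(sigma * zf)
                    eps_r = math.exp(sigma * zr)
                else:
                    eps_f = eps_r = 1.0
                renilla = config.baseline_renilla * plate_effect * via * eps_r
                firefly = (config.baseline_firefly * plate_effect * act * via
                           * eps_f)
                records.append((
                    plate_id, well_name(pos // PLATE_COLS, pos % PLATE_COLS),
                    cid, conc, firefly, renilla, day, role,
                ))

    wells = pd.DataFrame(records, columns=WELL_COLUMNS)
    wells = validate_wells(wells)
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["chemical_id", "emax", "ec50", "hill_n", "tc50", "hill_t"],
    )
    return wells, truth_df


def simulate_qpcr(
    fold_changes: dict[str, float],
    reference_gene: str = "EIF4A2",
    ct_ref: float = 20.0,
    conditions: tuple[str, str] = ("vehicle", "treated"),
    n_replicates: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a tidy Ct table with planted fold changes.

    For each target gene the treated-condition Ct is lowered by
    log2(fold_change) relative to vehicle (one PCR cycle per 2-fold, with
    amplification efficiency 2); the reference gene's Ct is constant
    across conditions.  Returns columns gene, condition, replicate, ct.
    """
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    control, treated = conditions
    rows = []
    genes = dict(fold_changes)
    genes.setdefault(reference_gene, 1.0)
    for gene, fc in genes.items():
        base = ct_ref if gene == reference_gene else ct_ref + 4.0
        for cond in conditions:
            shift = 0.0
            if cond == treated and gene != reference_gene:
                shift = -math.log2(fc)
            for rep in range(1, n_replicates + 1):
                ct = base + shift
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((gene, cond, rep, ct))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
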