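"""Seeded generators for every input the analysis consumes.

Initial-velocity datasets are generated from the MM forward model on the
published assay design (1–80 mM substrate, 0.1–1 µM enzyme, three
biological replicates) with multiplicative Gaussian noise; plate
readings from the linear fluorescence model FP = I*(OD − OD_bg) + FP_bg.
Every generator records its ground truth and seed so parameter-recovery
tests can close the loop.  The measured kcat/Km panel of phosphatase
BT4131 and its variants ships as a packaged fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError
from .kinetics import KineticPanel, KineticParameters, PlateReading, VelocityDataset, mm_velocity
from .pathway import VariantRatioTable

__all__ = [
    "AssayDesign",
    "GroundTruth",
    "PlateTruth",
    "generate_velocity_data",
    "generate_plate_data",
    "bt4131_panel",
    "default_ratio_table",
    "DEFAULT_SUBSTRATE_GRID",
]

#: Published assay grid (mM) spanning the 1–80 mM range.
DEFAULT_SUBSTRATE_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0)

_ASSAY_RANGE = (1.0, 80.0)
_ENZYME_RANGE = (0.1, 1.0)


@dataclass
class AssayDesign:
    """Initial-velocity assay layout.

    ``noise_cv`` is the coefficient of variation of multiplicative
    Gaussian noise (use ``noise_sd`` for an additive absolute-SD model
    instead); the default 5% CV sits at the low end of the replicate
    scatter seen in the measured panel.
    """

    substrate_grid: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID
    replicates: int = 3
    enzyme_conc: float = 0.5
    noise_cv: float | None = 0.05
    noise_sd: float | None = None
    seed: int = 0
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        grid = tuple(float(s) for s in self.substrate_grid)
        if len(grid) < 1:
            raise ConfigError("substrate grid must be non-empty")
        if not self.allow_out_of_range and (
            min(grid) < _ASSAY_RANGE[0] or max(grid) > _ASSAY_RANGE[1]
        ):
            raise ConfigError(
                f"substrate grid must lie within {_ASSAY_RANGE} mM "
                "(set allow_out_of_range=True to override)"
            )
        self.substrate_grid = grid
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not (_ENZYME_RANGE[0] <= self.enzyme_conc <= _ENZYME_RANGE[1]):
            raise ConfigError(f"enzyme_conc must lie within {_ENZYME_RANGE} µM")
        if self.noise_cv is not None and self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generating kinetic parameters for one (variant, substrate) pair."""

    vmax: float
    km: float
    variant_id: str = ""
    substrate_id: str = ""

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.km > 0):
            raise InvalidInputError("generating vmax and Km must be > 0")


@dataclass
class PlateTruth:
    """Generating parameters for a fluorescence plate."""

    intensity: float  # true normalized fluorescence (a.u. per OD)
    od: float = 1.0
    od_bg: float = 0.1
    fp_bg: float = 100.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity < 0 or self.noise_sd < 0:
            raise InvalidInputError("intensity and noise_sd must be >= 0")
        if not (self.od > self.od_bg >= 0):
            raise InvalidInputError("need OD > OD_bg >= 0")


def generate_velocity_data(
    truth: GroundTruth, design: AssayDesign
) -> tuple[VelocityDataset, dict]:
    """Generate a seeded initial-velocity dataset from the MM forward model.

    Returns the dataset and a provenance dict (ground truth, seed,
    truncation count).  Zero noise reproduces the rate law exactly;
    noisy velocities are truncated at zero and the truncations counted.
    """
    rng = np.random.default_rng(design.seed)
    params = KineticParameters(truth.vmax, truth.km)
    grid = np.asarray(design.substrate_grid)
    s = np.tile(grid, design.replicates)
    rep = np.repeat(np.arange(design.replicates), grid.size)
    v_true = mm_velocity(params, s)
    if design.noise_cv:
        v = v_true * (1.0 + design.noise_cv * rng.standard_normal(s.size))
    elif design.noise_sd:
        v = v_true + design.noise_sd * rng.standard_normal(s.size)
    else:
        v = v_true.copy()
    truncated = int(np.sum(v < 0))
    v = np.maximum(v, 0.0)
    data = VelocityDataset(
        substrate_conc=s,
        velocity=v,
        replicate=rep,
        substrate_id=truth.substrate_id,
        variant_id=truth.variant_id,
    )
    provenance = {
        "vmax": truth.vmax,
        "km": truth.km,
        "enzyme_conc": design.enzyme_conc,
        "seed": design.seed,
        "noise_cv": design.noise_cv,
        "noise_sd": design.noise_sd,
        "n_truncated": truncated,
    }
    return data, provenance


def generate_plate_data(
    truth: PlateTruth, wells: int, seed: int = 0
) -> list[PlateReading]:
    """Generate background-inclusive plate readings.

    FP = intensity*(OD − OD_bg) + FP_bg + Gaussian noise; on noiseless
    wells the background correction recovers the true intensity exactly.
    """
    if wells < 1:
        raise ConfigError("wells must be >= 1")
    rng = np.random.default_rng(seed)
    fp_clean = truth.intensity * (truth.od - truth.od_bg) + truth.fp_bg
    noise = truth.noise_sd * rng.standard_normal(wells) if truth.noise_sd else np.zeros(wells)
    return [
        PlateReading(fp=float(fp_clean + noise[i]), od=truth.od,
                     fp_bg=truth.fp_bg, od_bg=truth.od_bg)
        for i in range(wells)
    ]


def bt4131_panel() -> KineticPanel:
    """The measured kcat/Km panel (mM^-1 min^-1): WT and mutants M1–M4
    of phosphatase BT4131 over the four phosphosugar substrates.

    M4 was not tested on Fru6P and GlcN6P; those entries carry
    ``measured=False``.
    """
    path = files("phoskin.data").joinpath("bt4131_panel.csv")
    with path.open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return KineticPanel(frame)


def default_ratio_table(panel: KineticPanel | None = None) -> VariantRatioTable:
    """Phosphatase scaling ratios derived from the measured panel.

    vmax_ratio(variant, substrate) = kcat/Km(variant, substrate) divided
    by kcat/Km(WT, Glc6P); Km_ratio = 1 — the entire measured preference
    is carried by vmax, since kcat/Km is the only published per-pair
    quantity.  Untested pairs are absent (no silent imputation).
    """
    panel = panel if panel is not None else bt4131_panel()
    anchor = panel.efficiency("WT", "Glc6P")
    rows = []
    for variant in panel.variants:
        for substrate in panel.substrates:
            if not panel.is_measured(variant, substrate):
                continue
            rows.append(
                {
                    "variant": variant,
                    "substrate": substrate,
                    "vmax_ratio": panel.efficiency(variant, substrate) / anchor,
                    "km_ratio": 1.0,
                    "provenance": "measured",
                }
            )
    return VariantRatioTable(pd.DataFrame(rows))
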