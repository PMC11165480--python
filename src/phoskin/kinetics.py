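"""Michaelis–Menten kinetics, catalytic-efficiency analytics and plate
fluorescence normalization.

The central quantities are the MM rate law

    v0 = vmax * s / (Km + s)

the turnover number kcat = vmax / [E], and the catalytic efficiency
kcat/Km (mM^-1 min^-1) used as the substrate-preference readout for the
BT4131 phosphatase variant panel.  Fold changes between variants are
reported in three conventions simultaneously (plain ratio, ratio - 1,
signed percent change) because published comparisons mix them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DataError,
    FitFailureError,
    InsufficientDesignError,
    InvalidInputError,
    UndefinedCorrectionError,
)

__all__ = [
    "KineticParameters",
    "VelocityDataset",
    "KineticPanel",
    "FoldChange",
    "PlateReading",
    "MichaelisMentenFit",
    "mm_velocity",
    "fit_michaelis_menten",
    "kcat_from_vmax",
    "fold_change",
    "preference_report",
    "corrected_fluorescence",
    "efficiency_um_s_to_mm_min",
    "round_half_up",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameters:
    """Steady-state kinetic parameters of one enzyme/substrate pair.

    Parameters
    ----------
    vmax : float
        Maximum velocity, in the assay's velocity units (concentration/time).
    km : float
        Michaelis constant, mM.
    enzyme_conc : float, optional
        Enzyme subunit concentration, µM.  When given, ``kcat`` and
        ``efficiency`` are defined.
    """

    vmax: float
    km: float
    enzyme_conc: float | None = None

    def __post_init__(self) -> None:
        if not (self.vmax > 0):
            raise InvalidInputError(f"vmax must be > 0, got {self.vmax}")
        if not (self.km > 0):
            raise InvalidInputError(f"Km must be > 0, got {self.km}")
        if self.enzyme_conc is not None and not (self.enzyme_conc > 0):
            raise InvalidInputError(
                f"enzyme_conc must be > 0, got {self.enzyme_conc}"
            )

    @property
    def kcat(self) -> float | None:
        """Turnover number vmax/[E] (min^-1), or None without [E]."""
        if self.enzyme_conc is None:
            return None
        return kcat_from_vmax(self.vmax, self.enzyme_conc)

    @property
    def efficiency(self) -> float | None:
        """Catalytic efficiency kcat/Km (mM^-1 min^-1), or None without [E]."""
        k = self.kcat
        if k is None:
            return None
        return k / self.km


@dataclass
class VelocityDataset:
    """Initial-velocity observations on a substrate grid.

    Concentrations are mM; velocities are in assay units.  ``replicate``
    indexes biological replicates at the same concentration.
    """

    substrate_conc: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray
    substrate_id: str = ""
    variant_id: str = ""

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n = self.substrate_conc.size
        if self.velocity.size != n or self.replicate.size != n:
            raise DataError("substrate_conc, velocity, replicate must align")
        if np.any(self.substrate_conc < 0):
            raise InvalidInputError("substrate concentrations must be >= 0")

    @property
    def n_concentrations(self) -> int:
        return np.unique(self.substrate_conc).size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_id,
                "substrate": self.substrate_id,
                "substrate_conc_mM": self.substrate_conc,
                "velocity": self.velocity,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VelocityDataset":
        variant = str(frame["variant"].iloc[0]) if "variant" in frame else ""
        substrate = str(frame["substrate"].iloc[0]) if "substrate" in frame else ""
        return cls(
            substrate_conc=frame["substrate_conc_mM"].to_numpy(),
            velocity=frame["velocity"].to_numpy(),
            replicate=frame["replicate"].to_numpy(),
            substrate_id=substrate,
            variant_id=variant,
        )


class KineticPanel:
    """A variants x substrates table of catalytic efficiencies (kcat/Km).

    Entries carry a value +/- SD (mM^-1 min^-1) and a ``measured`` flag;
    untested pairs have ``measured=False`` and no value.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"variant", "substrate", "kcat_km", "sd", "measured"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"panel missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["measured"] = frame["measured"].astype(bool)
        bad = frame[frame["measured"] & ~(frame["kcat_km"] > 0)]
        if len(bad):
            raise DataError(
                "measured panel entries must have kcat_km > 0: "
                + ", ".join(f"({r.variant}, {r.substrate})" for r in bad.itertuples())
            )
        self._frame = frame.reset_index(drop=True)
        self._index = {
            (r.variant, r.substrate): r for r in self._frame.itertuples()
        }

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def variants(self) -> list[str]:
        return list(dict.fromkeys(self._frame["variant"]))

    @property
    def substrates(self) -> list[str]:
        return list(dict.fromkeys(self._frame["substrate"]))

    def is_measured(self, variant: str, substrate: str) -> bool:
        row = self._index.get((variant, substrate))
        return bool(row is not None and row.measured)

    def efficiency(self, variant: str, substrate: str) -> float:
        row = self._index.get((variant, substrate))
        if row is None or not row.measured:
            raise DataError(f"no measured entry for ({variant}, {substrate})")
        return float(row.kcat_km)

    def sd(self, variant: str, substrate: str) -> float | None:
        row = self._index.get((variant, substrate))
        if row is None or not row.measured:
            raise DataError(f"no measured entry for ({variant}, {substrate})")
        return None if pd.isna(row.sd) else float(row.sd)


@dataclass(frozen=True)
class FoldChange:
    """A value/reference comparison in the three common conventions.

    ``ratio`` is value/reference, ``excess`` is ratio - 1 ("an N-fold
    increase" in the ratio-minus-one reading), ``percent_change`` is
    100*(ratio - 1).  The identity percent_change == 100*excess holds
    exactly.
    """

    ratio: float
    excess: float
    percent_change: float


@dataclass(frozen=True)
class PlateReading:
    """One fluorescence well plus its background wells.

    FP and FP_bg are fluorescence (a.u.); OD and OD_bg optical densities
    at 600 nm.
    """

    fp: float
    od: float
    fp_bg: float = 0.0
    od_bg: float = 0.0


@dataclass(frozen=True)
class MichaelisMentenFit:
    """Result of a nonlinear least-squares MM fit."""

    params: KineticParameters
    vmax_stderr: float
    km_stderr: float
    rss: float
    n_obs: int
    converged: bool = True

    @property
    def dof(self) -> int:
        return self.n_obs - 2


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def mm_velocity(params: KineticParameters, substrate_conc) -> float | np.ndarray:
    """Michaelis–Menten initial velocity vmax*s/(Km+s).

    Accepts a scalar or array of substrate concentrations (mM, >= 0).
    Strictly increasing in s, bounded above by vmax.
    """
    s = np.asarray(substrate_conc, dtype=float)
    if np.any(s < 0):
        raise InvalidInputError("substrate concentration must be >= 0")
    v = params.vmax * s / (params.km + s)
    return float(v) if np.ndim(substrate_conc) == 0 else v


def kcat_from_vmax(vmax: float, enzyme_conc: float) -> float:
    """Turnover number kcat = vmax/[E] (min^-1 when vmax is µM/min, [E] µM)."""
    if not (enzyme_conc > 0):
        raise InvalidInputError(f"enzyme concentration must be > 0, got {enzyme_conc}")
    if vmax < 0:
        raise InvalidInputError(f"vmax must be >= 0, got {vmax}")
    return vmax / enzyme_conc


def fit_michaelis_menten(
    data: VelocityDataset,
    weighting: str = "none",
    enzyme_conc: float | None = None,
) -> MichaelisMentenFit:
    """Fit vmax and Km to initial-velocity data by nonlinear least squares.

    Initial guesses: vmax0 = max observed velocity; Km0 = the substrate
    concentration whose mean velocity is nearest vmax0/2.  ``weighting``
    is ``"none"`` (unweighted, default) or ``"1/v2"`` (relative-error
    weighting).  Raises :class:`InsufficientDesignError` with fewer than
    three distinct concentrations and :class:`FitFailureError` on
    degenerate data or non-convergence.
    """
    s = data.substrate_conc
    v = data.velocity
    if not np.all(np.isfinite(v)):
        raise DataError("velocities must be finite")
    if data.n_concentrations < 3:
        raise InsufficientDesignError(
            f"need >= 3 distinct substrate concentrations, got {data.n_concentrations}"
            + (f" for ({data.variant_id}, {data.substrate_id})" if data.variant_id else "")
        )
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise FitFailureError("all velocities are <= 0; no saturation curve to fit")

    # Km0: grid point whose mean velocity is closest to half vmax0
    grid = np.unique(s)
    mean_v = np.array([v[s == g].mean() for g in grid])
    km0 = float(grid[np.argmin(np.abs(mean_v - vmax0 / 2.0))])
    km0 = max(km0, 1e-6)

    if weighting == "1/v2":
        sigma = np.maximum(np.abs(v), 1e-12 * vmax0)
    elif weighting == "none":
        sigma = None
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    def model(x, vmax, km):
        return vmax * x / (km + x)

    try:
        popt, pcov = curve_fit(
            model,
            s,
            v,
            p0=(vmax0, km0),
            sigma=sigma,
            absolute_sigma=False,
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=10000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"MM fit did not converge: {exc}") from exc

    vmax_hat, km_hat = (float(popt[0]), float(popt[1]))
    resid = v - model(s, *popt)
    rss = float(resid @ resid)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return MichaelisMentenFit(
        params=KineticParameters(vmax_hat, km_hat, enzyme_conc=enzyme_conc),
        vmax_stderr=float(stderr[0]),
        km_stderr=float(stderr[1]),
        rss=rss,
        n_obs=int(v.size),
    )


def fold_change(value: float, reference: float) -> FoldChange:
    """Compare a catalytic efficiency against a reference.

    Returns all three conventions; the caller chooses which to quote.
    """
    if not (reference > 0):
        raise InvalidInputError(f"reference must be > 0, got {reference}")
    ratio = value / reference
    return FoldChange(ratio=ratio, excess=ratio - 1.0, percent_change=100.0 * (ratio - 1.0))


def corrected_fluorescence(reading: PlateReading) -> float:
    """Background-corrected, OD-normalized fluorescence.

    (FP - FP_bg) / (OD - OD_bg); requires OD > OD_bg.
    """
    denom = reading.od - reading.od_bg
    if denom <= 0:
        raise UndefinedCorrectionError(
            f"OD ({reading.od}) must exceed background OD ({reading.od_bg})"
        )
    return (reading.fp - reading.fp_bg) / denom


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with halves away from zero (display convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def efficiency_um_s_to_mm_min(value: float) -> float:
    """Convert kcat/Km from µM^-1 s^-1 to the panel's mM^-1 min^-1."""
    return value * 1000.0 * 60.0


def preference_report(
    panel: KineticPanel,
    reference_variant: str,
    substrates: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Substrate-preference comparison of every variant against a reference.

    For each measured (variant, substrate) pair with a measured reference
    entry for the same substrate, emits ratio, excess and percent_change
    plus display-rounded columns (fold to 1 decimal, percent to 1 decimal).
    Unmeasured pairs appear with ``measured=False`` and NaN statistics —
    they are flagged, never imputed.
    """
    if reference_variant not in panel.variants:
        raise DataError(f"reference variant {reference_variant!r} not in panel")
    substrates = list(substrates) if substrates is not None else panel.substrates
    for sub in substrates:
        if not panel.is_measured(reference_variant, sub):
            raise DataError(
                f"reference entry missing for ({reference_variant}, {sub})"
            )
    rows = []
    for variant in panel.variants:
        for sub in substrates:
            if not panel.is_measured(variant, sub):
                rows.append(
                    {
                        "variant": variant,
                        "substrate": sub,
                        "reference": reference_variant,
                        "measured": False,
                        "ratio": np.nan,
                        "excess": np.nan,
                        "percent_change": np.nan,
                        "ratio_display": np.nan,
                        "excess_display": np.nan,
                        "percent_display": np.nan,
                    }
                )
                continue
            fc = fold_change(
                panel.efficiency(variant, sub),
                panel.efficiency(reference_variant, sub),
            )
            rows.append(
                {
                    "variant": variant,
                    "substrate": sub,
                    "reference": reference_variant,
                    "measured": True,
                    "ratio": fc.ratio,
                    "excess": fc.excess,
                    "percent_change": fc.percent_change,
                    "ratio_display": round_half_up(fc.ratio, 1),
                    "excess_display": round_half_up(fc.excess, 1),
                    "percent_display": round_half_up(fc.percent_change, 1),
                }
            )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable text table of a preference report."""
    lines = [
        f"{'variant':<8}{'substrate':<10}{'vs':<6}{'ratio':>8}{'excess':>8}{'%change':>9}"
    ]
    for r in report.itertuples():
        if not r.measured:
            lines.append(
                f"{r.variant:<8}{r.substrate:<10}{r.reference:<6}{'—':>8}{'—':>8}{'not tested':>11}"
            )
        else:
            lines.append(
                f"{r.variant:<8}{r.substrate:<10}{r.reference:<6}"
                f"{r.ratio:>8.2f}{r.excess:>8.2f}{r.percent_change:>9.1f}"
            )
    return "\n".join(lines)
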