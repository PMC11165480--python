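"""Dynamic model of the GlcNAc biosynthesis pathway.

Eight relative metabolite concentrations (glucose, Glc6P, Fru6P, GlcN6P,
fructose, glucosamine, GlcNAc6P, GlcNAc) are coupled through twelve
reaction rates: glucose uptake v1 (a constant flux, optionally inhibited
by phosphosugar pressure), Michaelis–Menten steps v2..v12, and — in the
regulated model — a GlcNAc6P-responsive biosensor that modulates the four
phosphatase reactions (v5: Glc6P, v6: Fru6P, v7: GlcN6P, v11: GlcNAc6P)
through a Hill activation term:

    v_r = (p_r + v_rmax * x7^n / (Ka^n + x7^n)) * s/(Km_r + s)
    v1  = v1max * Ki^nt / (Ki^nt + (x2+x3+x4+x7)^nt)

All states, rates and parameters are dimensionless (relative units).

One printed rate law is self-inconsistent with the mass balances: the
GNA1 step v10 moves mass from GlcN6P (x4) to GlcNAc6P (x7), yet its
printed saturation argument is the terminal product x8.  The default
``v10_substrate="x4"`` keeps the step mass-consistent; ``"x8"`` keeps
the literal printed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, DataError, IntegrationError, InvalidInputError

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "N_REACTIONS",
    "REGULATED_REACTIONS",
    "PHOSPHATASE_SUBSTRATES",
    "STOICHIOMETRY",
    "PathwayParameters",
    "VariantRatioTable",
    "Trajectory",
    "core_rates",
    "regulated_rates",
    "mass_balance",
    "simulate",
    "build_variant_params",
]

#: State identities x1..x8 (relative concentrations).
STATE_NAMES = (
    "glucose",
    "glc6p",
    "fru6p",
    "glcn6p",
    "fructose",
    "glucosamine",
    "glcnac6p",
    "glcnac",
)
N_STATES = 8
N_REACTIONS = 12

#: Biosensor-regulated phosphatase reactions (1-based reaction ids).
REGULATED_REACTIONS = (5, 6, 7, 11)

#: Panel substrate handled by each phosphatase reaction.
PHOSPHATASE_SUBSTRATES: Mapping[str, int] = {
    "Glc6P": 5,
    "Fru6P": 6,
    "GlcN6P": 7,
    "GlcNAc6P": 11,
}

# Mass balances:
#   dx1 = v1 - v2 + v5        dx5 = v6 - v12
#   dx2 = v2 - v3 - v5        dx6 = v7
#   dx3 = v3 - v4 - v6 + v9 + v12
#   dx4 = v4 - v7 + v8 - v9 - v10
#   dx7 = v10 - v8 - v11      dx8 = v11
STOICHIOMETRY = np.zeros((N_STATES, N_REACTIONS))
for _state, _terms in {
    0: {1: +1, 2: -1, 5: +1},
    1: {2: +1, 3: -1, 5: -1},
    2: {3: +1, 4: -1, 6: -1, 9: +1, 12: +1},
    3: {4: +1, 7: -1, 8: +1, 9: -1, 10: -1},
    4: {6: +1, 12: -1},
    5: {7: +1},
    6: {10: +1, 8: -1, 11: -1},
    7: {11: +1},
}.items():
    for _rxn, _sign in _terms.items():
        STOICHIOMETRY[_state, _rxn - 1] = _sign

# Saturation substrate (0-based state index) for v2..v12; v10 is mode-dependent.
_MM_SUBSTRATE = {2: 0, 3: 1, 4: 2, 5: 1, 6: 2, 7: 3, 8: 6, 9: 3, 11: 6, 12: 4}


@dataclass
class PathwayParameters:
    """Full parameterization of the pathway model.

    ``vmax`` and ``km`` are length-12 arrays indexed by reaction-1
    (``km[0]`` is unused: v1 has no saturation).  Regulation arrays are
    length-4, ordered as :data:`REGULATED_REACTIONS`; ``reg_basal`` is
    the leaky expression p_r, ``reg_n``/``reg_ka`` the Hill activation
    parameters.  ``ki``/``transport_n`` shape the phosphosugar-pressure
    inhibition of uptake.
    """

    vmax: np.ndarray
    km: np.ndarray
    reg_basal: np.ndarray
    reg_n: np.ndarray
    reg_ka: np.ndarray
    ki: float = 1.0
    transport_n: float = 1.0
    v10_substrate: str = "x4"

    def __post_init__(self) -> None:
        self.vmax = np.asarray(self.vmax, dtype=float)
        self.km = np.asarray(self.km, dtype=float)
        self.reg_basal = np.asarray(self.reg_basal, dtype=float)
        self.reg_n = np.asarray(self.reg_n, dtype=float)
        self.reg_ka = np.asarray(self.reg_ka, dtype=float)
        if self.vmax.shape != (N_REACTIONS,) or self.km.shape != (N_REACTIONS,):
            raise ConfigError("vmax and km must have length 12")
        if any(a.shape != (4,) for a in (self.reg_basal, self.reg_n, self.reg_ka)):
            raise ConfigError("regulation arrays must have length 4")
        if np.any(self.vmax < 0):
            raise ConfigError("all vmax must be >= 0")
        if np.any(self.km[1:] <= 0):
            raise ConfigError("all Km (reactions 2..12) must be > 0")
        if np.any(self.reg_n < 0) or np.any(self.reg_n > 4):
            raise ConfigError("Hill coefficients must lie in [0, 4]")
        if np.any(self.reg_ka <= 0) or np.any(self.reg_ka > 1):
            raise ConfigError("Ka must lie in (0, 1]")
        if not (0 < self.ki <= 1):
            raise ConfigError("Ki must lie in (0, 1]")
        if not (0 <= self.transport_n <= 4):
            raise ConfigError("transport Hill coefficient must lie in [0, 4]")
        if np.any(self.reg_basal < 0):
            raise ConfigError("basal rates p must be >= 0")
        if self.v10_substrate not in ("x4", "x8"):
            raise ConfigError("v10_substrate must be 'x4' or 'x8'")

    def copy(self) -> "PathwayParameters":
        return replace(
            self,
            vmax=self.vmax.copy(),
            km=self.km.copy(),
            reg_basal=self.reg_basal.copy(),
            reg_n=self.reg_n.copy(),
            reg_ka=self.reg_ka.copy(),
        )


@dataclass
class Trajectory:
    """A simulated time course: states (n_times x 8), optional rates."""

    times: np.ndarray
    states: np.ndarray
    rates: np.ndarray | None = None
    variant: str = ""
    draw: int = -1
    seed: int | None = None

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def final(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        n = self.times.size
        return pd.DataFrame(
            {
                "variant": np.repeat(self.variant, n * N_STATES),
                "draw": np.repeat(self.draw, n * N_STATES),
                "time": np.tile(self.times, N_STATES),
                "state": np.repeat(STATE_NAMES, n),
                "value": self.states.T.ravel(),
            }
        )


class VariantRatioTable:
    """Phosphatase vmax/Km scaling ratios, relative to WT on Glc6P.

    Rows: variant, substrate, vmax_ratio, km_ratio, provenance
    (``measured`` or ``imputed``).  The WT/Glc6P row must be exactly 1.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"variant", "substrate", "vmax_ratio", "km_ratio", "provenance"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"ratio table missing columns: {sorted(missing)}")
        self._frame = frame.reset_index(drop=True)
        if np.any(self._frame["vmax_ratio"] <= 0) or np.any(self._frame["km_ratio"] <= 0):
            raise DataError("all ratios must be > 0")
        self._index = {
            (r.variant, r.substrate): (float(r.vmax_ratio), float(r.km_ratio))
            for r in self._frame.itertuples()
        }
        wt = self._index.get(("WT", "Glc6P"))
        if wt is not None and wt != (1.0, 1.0):
            raise DataError("WT/Glc6P ratios must be exactly 1")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def variants(self) -> list[str]:
        return list(dict.fromkeys(self._frame["variant"]))

    def has(self, variant: str, substrate: str) -> bool:
        return (variant, substrate) in self._index

    def get(self, variant: str, substrate: str) -> tuple[float, float]:
        try:
            return self._index[(variant, substrate)]
        except KeyError:
            raise DataError(f"no ratio entry for ({variant}, {substrate})") from None


# ---------------------------------------------------------------------------
# Rate laws and mass balance
# ---------------------------------------------------------------------------


def _check_state(state: np.ndarray) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (N_STATES,):
        raise InvalidInputError(f"state must have length {N_STATES}")
    if np.any(x < 0):
        raise InvalidInputError("state components must be >= 0")
    return x


def _mm_rates(x: np.ndarray, params: PathwayParameters) -> np.ndarray:
    """Unregulated saturation rates; v1 = v1max constant."""
    v = np.empty(N_REACTIONS)
    v[0] = params.vmax[0]
    for rxn, idx in _MM_SUBSTRATE.items():
        s = x[idx]
        v[rxn - 1] = params.vmax[rxn - 1] * s / (params.km[rxn - 1] + s)
    idx10 = 3 if params.v10_substrate == "x4" else 7
    s10 = x[idx10]
    v[9] = params.vmax[9] * s10 / (params.km[9] + s10)
    return v


def core_rates(state, params: PathwayParameters) -> np.ndarray:
    """The twelve reaction rates without biosensor feedback.

    v1 = v1max; v_i = vmax_i * s/(Km_i + s) for i = 2..12.
    """
    return _mm_rates(_check_state(state), params)


def _hill_activation(x7: float, n: np.ndarray, ka: np.ndarray) -> np.ndarray:
    """x7^n / (Ka^n + x7^n) per regulated reaction; n == 0 gives 1/2.

    The n = 0 limit is defined by continuity of the x7 > 0 case
    (x7^0/(Ka^0 + x7^0) = 1/2), including at x7 = 0.
    """
    n = np.asarray(n, dtype=float)
    ka = np.asarray(ka, dtype=float)
    act = np.empty_like(n)
    zero_n = n == 0
    act[zero_n] = 0.5
    nz = ~zero_n
    if np.any(nz):
        x7n = x7 ** n[nz]
        act[nz] = x7n / (ka[nz] ** n[nz] + x7n)
    return act


def regulated_rates(state, params: PathwayParameters) -> np.ndarray:
    """Reaction rates with biosensor feedback and phosphosugar pressure.

    The four phosphatase rates gain the Hill prefactor
    p_r + v_rmax * x7^n/(Ka^n + x7^n); glucose uptake becomes
    v1max * Ki^nt/(Ki^nt + P^nt) with P = x2 + x3 + x4 + x7.
    """
    x = _check_state(state)
    v = _mm_rates(x, params)
    x7 = x[6]
    act = _hill_activation(x7, params.reg_n, params.reg_ka)
    for k, rxn in enumerate(REGULATED_REACTIONS):
        i = rxn - 1
        s = x[_MM_SUBSTRATE[rxn]]
        sat = s / (params.km[i] + s)  # bare saturation fraction s/(Km+s)
        v[i] = (params.reg_basal[k] + params.vmax[i] * act[k]) * sat
    pressure = x[1] + x[2] + x[3] + x[6]
    nt = params.transport_n
    if nt == 0:
        v[0] = params.vmax[0] / 2.0
    else:
        kin = params.ki**nt
        v[0] = params.vmax[0] * kin / (kin + pressure**nt)
    return v


def mass_balance(rates) -> np.ndarray:
    """State derivative from reaction rates via the stoichiometry matrix."""
    v = np.asarray(rates, dtype=float)
    if v.shape != (N_REACTIONS,):
        raise InvalidInputError(f"rates must have length {N_REACTIONS}")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("rates must be finite")
    return STOICHIOMETRY @ v


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate(
    params: PathwayParameters,
    initial=None,
    horizon: float = 200.0,
    n_points: int = 1000,
    regulated: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    store_rates: bool = True,
    variant: str = "",
    draw: int = -1,
) -> Trajectory:
    """Integrate the pathway ODEs on a dense time grid.

    States are clipped at zero inside the right-hand side (the rate laws
    are only defined for non-negative concentrations; solver round-off
    may dip infinitesimally below) and in the returned trajectory.
    Raises :class:`IntegrationError` on solver failure.
    """
    if not (horizon > 0):
        raise ConfigError(f"horizon must be > 0, got {horizon}")
    x0 = np.zeros(N_STATES) if initial is None else np.asarray(initial, dtype=float)
    if x0.shape != (N_STATES,):
        raise ConfigError(f"initial state must have length {N_STATES}")
    if np.any(x0 < 0):
        raise ConfigError("initial state must be non-negative")

    rate_fn = regulated_rates if regulated else core_rates

    def rhs(_t, x):
        return STOICHIOMETRY @ rate_fn(np.maximum(x, 0.0), params)

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    rates = None
    if store_rates:
        rates = np.vstack([rate_fn(states[i], params) for i in range(n_points)])
    return Trajectory(times=t_eval, states=states, rates=rates, variant=variant, draw=draw)


# ---------------------------------------------------------------------------
# Variant parameterization
# ---------------------------------------------------------------------------


def build_variant_params(
    ratios: VariantRatioTable,
    base_draw: "PathwayParameters | object",
    variant: str,
    p_multiplier: float = 1.0,
    v10_substrate: str = "x4",
) -> PathwayParameters:
    """Assemble the full parameter set for one phosphatase variant.

    ``base_draw`` supplies the non-phosphatase parameters (a
    :class:`~phoskin.ensemble.BaseDraw`).  Phosphatase maxima are
    v_rmax = 0.5 * vmax_ratio(variant, substrate) (the WT/Glc6P anchor is
    0.5); phosphatase Km_r = Km(WT, Glc6P) * km_ratio.  The basal
    expression p_r defaults to the variant-scaled v_rmax
    (``p_multiplier`` rescales it).  Missing ratio entries raise a
    :class:`~phoskin.errors.DataError` naming every absent pair.
    """
    missing = [
        (variant, sub) for sub in PHOSPHATASE_SUBSTRATES if not ratios.has(variant, sub)
    ]
    if missing:
        raise DataError(
            "no ratio entries (and no imputation policy) for: "
            + ", ".join(f"({v}, {s})" for v, s in missing)
        )

    vmax = np.empty(N_REACTIONS)
    km = np.empty(N_REACTIONS)
    vmax[0] = base_draw.v1max
    km[0] = np.nan
    for rxn in base_draw.NONPHOSPHATASE_REACTIONS:
        vmax[rxn - 1] = base_draw.vmax_nonphos[rxn]
        km[rxn - 1] = base_draw.km_nonphos[rxn]
    for sub, rxn in PHOSPHATASE_SUBSTRATES.items():
        vr, kr = ratios.get(variant, sub)
        vmax[rxn - 1] = base_draw.vmax_glc6p_wt * vr
        km[rxn - 1] = base_draw.km_wt_glc6p * kr

    reg_basal = p_multiplier * np.array(
        [vmax[rxn - 1] for rxn in REGULATED_REACTIONS]
    )
    return PathwayParameters(
        vmax=vmax,
        km=km,
        reg_basal=reg_basal,
        reg_n=np.full(4, base_draw.hill_n) if np.ndim(base_draw.hill_n) == 0
        else np.asarray(base_draw.hill_n, dtype=float),
        reg_ka=np.full(4, base_draw.ka) if np.ndim(base_draw.ka) == 0
        else np.asarray(base_draw.ka, dtype=float),
        ki=base_draw.ki,
        transport_n=base_draw.transport_n,
        v10_substrate=v10_substrate,
    )
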