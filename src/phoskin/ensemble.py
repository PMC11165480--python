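"""Randomized parameter sampling and Monte-Carlo variant comparison.

Non-phosphatase kinetic parameters are drawn uniformly from published
ranges (Km in [0.5, 2.0], vmax in [0.6, 1.0], Hill coefficients in
[0, 4], Ka and Ki in (0, 1]); the uptake flux v1max and the WT/Glc6P
phosphatase anchor vmax are fixed at 0.5.  Each draw index owns an
independent RNG stream, and the same base draw is shared by every
variant at that index, so mutant comparisons are paired: differences
between variants within a draw are due to the phosphatase ratios alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, EnsembleQualityError, IntegrationError
from .pathway import (
    VariantRatioTable,
    build_variant_params,
    simulate,
)

__all__ = [
    "SamplingSpec",
    "BaseDraw",
    "VariantSummary",
    "EnsembleResult",
    "sample_parameters",
    "run_ensemble",
    "compare_variants",
    "SUMMARY_COLUMNS",
]

#: Reactions whose vmax/Km are sampled rather than ratio-scaled.
NONPHOSPHATASE_REACTIONS = (2, 3, 4, 8, 9, 10, 12)

#: Hill exponents below this are lifted to it to avoid the 0^0 ambiguity
#: inside the solver; exact n = 0 remains available via allow_zero_hill.
_MIN_HILL_N = 1e-6


def _interval(value, name: str, lo: float, hi: float) -> tuple[float, float]:
    a, b = float(value[0]), float(value[1])
    if not (lo <= a <= b <= hi):
        raise ConfigError(f"{name} must be a non-empty interval within [{lo}, {hi}], got {value}")
    return a, b


@dataclass
class SamplingSpec:
    """Configuration of the random parameter ensemble.

    Ranges default to the published sampling ranges; ``ka_range`` and
    ``ki_range`` start at 0.01 rather than 0 to keep the Hill terms
    well-conditioned.
    """

    km_nonphos_range: tuple[float, float] = (0.5, 2.0)
    km_wt_glc6p_range: tuple[float, float] = (0.5, 2.0)
    vmax_nonphos_range: tuple[float, float] = (0.6, 1.0)
    vmax_glc6p_wt: float = 0.5
    v1max: float = 0.5
    hill_n_range: tuple[float, float] = (0.0, 4.0)
    ka_range: tuple[float, float] = (0.01, 1.0)
    ki_range: tuple[float, float] = (0.01, 1.0)
    n_draws: int = 200
    seed: int = 0
    shared_hill: bool = True
    allow_zero_hill: bool = False

    def __post_init__(self) -> None:
        self.km_nonphos_range = _interval(self.km_nonphos_range, "km_nonphos_range", 0, np.inf)
        self.km_wt_glc6p_range = _interval(self.km_wt_glc6p_range, "km_wt_glc6p_range", 0, np.inf)
        self.vmax_nonphos_range = _interval(self.vmax_nonphos_range, "vmax_nonphos_range", 0, np.inf)
        self.hill_n_range = _interval(self.hill_n_range, "hill_n_range", 0, 4)
        self.ka_range = _interval(self.ka_range, "ka_range", 0, 1)
        self.ki_range = _interval(self.ki_range, "ki_range", 0, 1)
        if self.ka_range[0] <= 0 or self.ki_range[0] <= 0:
            raise ConfigError("Ka and Ki ranges must exclude 0")
        if self.n_draws < 1:
            raise ConfigError("n_draws must be >= 1")
        if not (self.vmax_glc6p_wt > 0 and self.v1max > 0):
            raise ConfigError("vmax constants must be > 0")


@dataclass
class BaseDraw:
    """One sampled set of non-variant-specific parameters.

    ``vmax_nonphos``/``km_nonphos`` map reaction id -> value for the
    seven non-phosphatase MM reactions; ``km_wt_glc6p`` anchors the
    phosphatase Km values; ``hill_n``/``ka`` may be scalars (shared
    across the four regulated reactions) or length-4 arrays.
    """

    draw: int
    v1max: float
    vmax_glc6p_wt: float
    vmax_nonphos: dict[int, float]
    km_nonphos: dict[int, float]
    km_wt_glc6p: float
    hill_n: float | np.ndarray
    transport_n: float
    ka: float | np.ndarray
    ki: float

    NONPHOSPHATASE_REACTIONS = NONPHOSPHATASE_REACTIONS


def sample_parameters(spec: SamplingSpec, draw_index: int) -> BaseDraw:
    """Draw the shared (non-variant) parameters for one ensemble index.

    Each index uses its own counter-based RNG stream seeded by
    ``(spec.seed, draw_index)``, so draw i is identical regardless of
    n_draws or execution order — the reproducibility contract behind
    paired variant comparisons.
    """
    if draw_index < 0:
        raise ConfigError("draw_index must be >= 0")
    rng = np.random.default_rng([spec.seed, draw_index])
    km_np = {r: rng.uniform(*spec.km_nonphos_range) for r in NONPHOSPHATASE_REACTIONS}
    vmax_np = {r: rng.uniform(*spec.vmax_nonphos_range) for r in NONPHOSPHATASE_REACTIONS}
    km_wt = rng.uniform(*spec.km_wt_glc6p_range)
    floor = 0.0 if spec.allow_zero_hill else _MIN_HILL_N
    if spec.shared_hill:
        hill_n = max(rng.uniform(*spec.hill_n_range), floor)
    else:
        hill_n = np.maximum(rng.uniform(*spec.hill_n_range, size=4), floor)
    transport_n = max(rng.uniform(*spec.hill_n_range), floor)
    ka = rng.uniform(*spec.ka_range)
    ki = rng.uniform(*spec.ki_range)
    return BaseDraw(
        draw=draw_index,
        v1max=spec.v1max,
        vmax_glc6p_wt=spec.vmax_glc6p_wt,
        vmax_nonphos=vmax_np,
        km_nonphos=km_np,
        km_wt_glc6p=km_wt,
        hill_n=hill_n,
        transport_n=transport_n,
        ka=ka,
        ki=ki,
    )


@dataclass(frozen=True)
class VariantSummary:
    """Per-trajectory summary statistics used in variant comparisons."""

    variant: str
    draw: int
    final_product: float
    min_glc6p: float
    final_fructose: float
    final_glucosamine: float
    mean_glcnac6p: float
    max_glcnac6p: float
    status: str = "ok"


SUMMARY_COLUMNS = (
    "variant",
    "draw",
    "final_product",
    "min_glc6p",
    "final_fructose",
    "final_glucosamine",
    "mean_glcnac6p",
    "max_glcnac6p",
    "status",
)


def summarize_trajectory(traj) -> VariantSummary:
    """Reduce a trajectory to the comparison statistics.

    ``min_glc6p`` is the minimum of Glc6P over the operating window
    (the second half of the horizon): trajectories start from an empty
    pathway, so the all-time minimum is trivially the initial zero and
    carries no information about how deeply a variant represses Glc6P
    once the pathway is running.
    """
    window = traj.times >= (traj.times[0] + traj.times[-1]) / 2.0
    return VariantSummary(
        variant=traj.variant,
        draw=traj.draw,
        final_product=float(traj.state("glcnac")[-1]),
        min_glc6p=float(traj.state("glc6p")[window].min()),
        final_fructose=float(traj.state("fructose")[-1]),
        final_glucosamine=float(traj.state("glucosamine")[-1]),
        mean_glcnac6p=float(np.trapezoid(traj.state("glcnac6p"), traj.times) / (traj.times[-1] - traj.times[0])),
        max_glcnac6p=float(traj.state("glcnac6p").max()),
    )


@dataclass
class EnsembleResult:
    """Summaries (and optionally trajectories) of a full ensemble run."""

    spec: SamplingSpec
    variants: tuple[str, ...]
    summaries: pd.DataFrame
    trajectories: list | None = None
    n_failures: int = 0

    def provenance(self) -> dict:
        from . import __version__

        return {
            "seed": self.spec.seed,
            "n_draws": self.spec.n_draws,
            "variants": list(self.variants),
            "n_failures": self.n_failures,
            "package_version": __version__,
        }


def run_ensemble(
    spec: SamplingSpec,
    variants: Sequence[str],
    ratios: VariantRatioTable,
    horizon: float = 200.0,
    n_points: int = 1000,
    v10_substrate: str = "x4",
    p_multiplier: float = 1.0,
    keep_trajectories: bool = False,
    max_failure_fraction: float = 0.1,
) -> EnsembleResult:
    """Simulate every variant under every parameter draw and summarize.

    Integration failures are recorded per (variant, draw) with
    ``status="failed"`` and NaN statistics; if more than
    ``max_failure_fraction`` of runs fail the whole ensemble is rejected
    with an :class:`~phoskin.errors.EnsembleQualityError`.
    """
    variants = tuple(variants)
    for var in variants:
        missing = [s for s in ("Glc6P", "Fru6P", "GlcN6P", "GlcNAc6P") if not ratios.has(var, s)]
        if missing:
            raise DataError(f"variant {var!r} missing ratio entries for {missing}")

    rows: list[VariantSummary] = []
    kept = [] if keep_trajectories else None
    failures = 0
    for draw in range(spec.n_draws):
        base = sample_parameters(spec, draw)
        for var in variants:
            params = build_variant_params(
                ratios, base, var, p_multiplier=p_multiplier, v10_substrate=v10_substrate
            )
            try:
                traj = simulate(
                    params,
                    horizon=horizon,
                    n_points=n_points,
                    store_rates=False,
                    variant=var,
                    draw=draw,
                )
            except IntegrationError:
                failures += 1
                rows.append(
                    VariantSummary(var, draw, *([float("nan")] * 6), status="failed")
                )
                continue
            rows.append(summarize_trajectory(traj))
            if kept is not None:
                kept.append(traj)

    total = spec.n_draws * len(variants)
    if failures > max_failure_fraction * total:
        raise EnsembleQualityError(
            f"{failures}/{total} integrations failed (limit {max_failure_fraction:.0%})"
        )
    summaries = pd.DataFrame([s.__dict__ for s in rows], columns=SUMMARY_COLUMNS)
    return EnsembleResult(
        spec=spec, variants=variants, summaries=summaries,
        trajectories=kept, n_failures=failures,
    )


def compare_variants(
    result: EnsembleResult,
    reference: str,
    accumulation_fraction: float = 0.05,
) -> pd.DataFrame:
    """Paired comparison of every variant against a reference variant.

    Statistics are computed on shared base draws: ``win_fraction`` is the
    fraction of draws where the variant's final GlcNAc exceeds the
    reference's (exact ties count 1/2); medians are across draws.  The
    accumulation flags mark variants whose median final fructose or
    glucosamine exceeds ``accumulation_fraction`` of their own median
    final product.
    """
    if reference not in result.variants:
        raise DataError(f"reference {reference!r} not in ensemble variants")
    df = result.summaries[result.summaries["status"] == "ok"]
    ref = df[df["variant"] == reference].set_index("draw")
    rows = []
    for var in result.variants:
        sub = df[df["variant"] == var].set_index("draw")
        common = sub.index.intersection(ref.index)
        a = sub.loc[common, "final_product"].to_numpy()
        b = ref.loc[common, "final_product"].to_numpy()
        med_prod = float(np.median(sub["final_product"]))
        wins = float(np.mean(np.where(a > b, 1.0, np.where(a < b, 0.0, 0.5)))) if len(common) else np.nan
        med_fru = float(np.median(sub["final_fructose"]))
        med_gln = float(np.median(sub["final_glucosamine"]))
        rows.append(
            {
                "variant": var,
                "reference": reference,
                "n_draws": int(len(sub)),
                "median_final_product": med_prod,
                "median_paired_diff": float(np.median(a - b)) if len(common) else np.nan,
                "win_fraction": wins,
                "median_min_glc6p": float(np.median(sub["min_glc6p"])),
                "median_final_fructose": med_fru,
                "median_final_glucosamine": med_gln,
                "median_max_glcnac6p": float(np.median(sub["max_glcnac6p"])),
                "fructose_accumulation": med_fru > accumulation_fraction * med_prod,
                "glucosamine_accumulation": med_gln > accumulation_fraction * med_prod,
            }
        )
    return pd.DataFrame(rows)
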