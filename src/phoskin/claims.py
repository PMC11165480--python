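"""The printed substrate-preference comparisons for the BT4131 variant panel.

Each claim pins the printed number, the convention it was quoted in
(``ratio``, ``excess`` = ratio − 1, or signed ``percent`` change) and the
precision at which it was printed.  The published wording mixes the
ratio and ratio−1 conventions — e.g. M1's "1.4-fold increase" on GlcNAc6P
is 31.88/13.28 − 1, while M4's "9.5-fold increase" is the plain ratio
126.27/13.28 — so every claim carries its own arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import KineticPanel, fold_change, round_half_up

__all__ = ["Claim", "PUBLISHED_COMPARISONS", "evaluate_claim", "check_claims"]


@dataclass(frozen=True)
class Claim:
    variant: str
    substrate: str
    reference: str
    convention: str  # "ratio" | "excess" | "percent"
    printed: float
    decimals: int

    @property
    def label(self) -> str:
        conv = {"ratio": "fold (ratio)", "excess": "fold (increase)", "percent": "%"}
        return (
            f"{self.variant}/{self.substrate} vs {self.reference}: "
            f"{self.printed:g} {conv[self.convention]}"
        )


#: The ten printed comparisons over the kcat/Km panel.
PUBLISHED_COMPARISONS: tuple[Claim, ...] = (
    Claim("M1", "GlcNAc6P", "WT", "excess", 1.4, 1),
    Claim("M1", "Glc6P", "WT", "percent", -63.5, 1),
    Claim("M1", "Fru6P", "WT", "percent", -73.1, 1),
    Claim("M2", "GlcNAc6P", "WT", "excess", 4.1, 1),
    Claim("M2", "Glc6P", "M1", "excess", 3.1, 1),
    Claim("M2", "Glc6P", "WT", "percent", 49.7, 1),
    Claim("M3", "GlcNAc6P", "WT", "excess", 4.6, 1),
    Claim("M3", "Glc6P", "WT", "percent", -60.6, 1),
    Claim("M4", "GlcNAc6P", "WT", "ratio", 9.5, 1),
    Claim("M4", "Glc6P", "WT", "percent", -59.0, 0),
)


def evaluate_claim(panel: KineticPanel, claim: Claim) -> tuple[float, float]:
    """Return (raw value in the claim's convention, display-rounded value)."""
    fc = fold_change(
        panel.efficiency(claim.variant, claim.substrate),
        panel.efficiency(claim.reference, claim.substrate),
    )
    raw = {"ratio": fc.ratio, "excess": fc.excess, "percent": fc.percent_change}[
        claim.convention
    ]
    return raw, round_half_up(raw, claim.decimals)


def check_claims(panel: KineticPanel) -> list[tuple[Claim, float, float, bool]]:
    """Evaluate every published comparison against a panel.

    Returns (claim, raw, rounded, matches-at-printed-precision) tuples.
    """
    out = []
    for claim in PUBLISHED_COMPARISONS:
        raw, rounded = evaluate_claim(panel, claim)
        out.append((claim, raw, rounded, rounded == claim.printed))
    return out
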