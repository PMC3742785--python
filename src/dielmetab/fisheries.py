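"""Carbon accounting: GPP → aNPP conversion and primary production
required (PPR) by a fishery.

Gross O₂ production converts to net carbon fixation assuming autotrophic
respiration is 40% of GPP (net = 60% of gross) and a photosynthetic
quotient of 1.2 mol O₂ per mol C, with the O₂→C mass ratio 12.011/31.998:

    aNPP [g C] = GPP [g O2] × 0.6 / 1.2 × (12.011/31.998)   (≈ 0.1877 × GPP)

Catch converts to carbon with a wet:dry mass ratio of 4 and 44.6% carbon
content of dry mass. The primary production required to sustain a catch
back-calculates trophic losses at transfer efficiency Q over TL − 1
trophic steps (the Pauly–Christensen formulation):

    PPR = B_C × (1/Q)^(TL−1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConversionConstants",
    "FisheryScenario",
    "gpp_to_anpp",
    "catch_to_carbon",
    "ppr",
    "scenario_grid",
]

#: molecular masses, g mol-1
_M_C = 12.011
_M_O2 = 31.998


@dataclass(frozen=True)
class ConversionConstants:
    npp_fraction: float = 0.6            # net = 60% of gross
    photosynthetic_quotient: float = 1.2  # mol O2 per mol C
    c_per_o2_mass: float = _M_C / _M_O2
    wet_to_dry: float = 4.0
    carbon_content: float = 0.446

    def __post_init__(self) -> None:
        vals = (self.npp_fraction, self.photosynthetic_quotient,
                self.c_per_o2_mass, self.wet_to_dry, self.carbon_content)
        if any(v <= 0 for v in vals):
            raise ValueError("all conversion constants must be > 0")
        if self.npp_fraction >= 1:
            raise ValueError("npp_fraction must be < 1")

    @property
    def gpp_to_anpp_factor(self) -> float:
        return self.npp_fraction / self.photosynthetic_quotient * self.c_per_o2_mass


@dataclass(frozen=True)
class FisheryScenario:
    """One trophic scenario against a reference whole-lake aNPP."""

    catch_tonnes_fw: float      # tonnes fresh weight per year
    Q: float                    # trophic transfer efficiency
    TL: float                   # mean trophic level of the catch
    anpp_tonnesC: float         # reference aquatic NPP, tonnes C per year

    def __post_init__(self) -> None:
        if not 0 < self.Q < 1:
            raise ValueError("Q must be in (0, 1)")
        if self.TL < 1:
            raise ValueError("TL must be >= 1")
        if self.catch_tonnes_fw < 0 or self.anpp_tonnesC <= 0:
            raise ValueError("catch must be >= 0 and aNPP > 0")


def gpp_to_anpp(gpp_o2, consts: ConversionConstants = ConversionConstants()):
    """Convert gross O₂ production to net carbon fixation (same volume/time units)."""
    g = np.asarray(gpp_o2, dtype=float)
    if np.any(g < 0):
        raise ValueError("GPP must be >= 0")
    out = g * consts.gpp_to_anpp_factor
    return float(out) if np.isscalar(gpp_o2) else out


def catch_to_carbon(catch_tonnes_fw, consts: ConversionConstants = ConversionConstants()):
    """Fresh-weight catch (tonnes) → carbon (tonnes C)."""
    b = np.asarray(catch_tonnes_fw, dtype=float)
    if np.any(b < 0):
        raise ValueError("catch must be >= 0")
    out = b / consts.wet_to_dry * consts.carbon_content
    return float(out) if np.isscalar(catch_tonnes_fw) else out


def ppr(scenario: FisheryScenario,
        consts: ConversionConstants = ConversionConstants()) -> tuple[float, float]:
    """Primary production required by the catch.

    Returns ``(ppr_tonnesC, percent_of_anpp)`` with
    ``PPR = B_C · (1/Q)^(TL−1)``.
    """
    bc = catch_to_carbon(scenario.catch_tonnes_fw, consts)
    p = bc * (1.0 / scenario.Q) ** (scenario.TL - 1.0)
    return p, 100.0 * p / scenario.anpp_tonnesC


def scenario_grid(yields, Qs, TLs, anpp_tonnesC: float,
                  consts: ConversionConstants = ConversionConstants()) -> pd.DataFrame:
    """PPR over every (yield, Q, TL) combination.

    Returns a DataFrame with columns ``catch_tonnes_fw``, ``Q``, ``TL``,
    ``ppr_tonnesC``, ``pct_of_anpp`` and ``pct_rounded`` (nearest
    integer, the reporting convention).
    """
    rows = []
    for b in np.atleast_1d(yields):
        for q in sorted(set(Qs)):
            for tl in sorted(set(TLs)):
                p, pct = ppr(FisheryScenario(float(b), float(q), float(tl),
                                             anpp_tonnesC), consts)
                rows.append({"catch_tonnes_fw": float(b), "Q": float(q),
                             "TL": float(tl), "ppr_tonnesC": p,
                             "pct_of_anpp": pct,
                             "pct_rounded": int(round(pct))})
    return pd.DataFrame(rows)
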