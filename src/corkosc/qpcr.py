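"""Efficiency-corrected RT-qPCR quantification and GC-FID internal-standard math.

Primer amplification efficiency E is estimated from a standard curve: an
OLS fit of Ct against log10(relative template amount) over a dilution
series (typically 5-fold steps) gives slope m, and E = 10^(-1/m); perfect
doubling per cycle corresponds to m = -1/log10(2) = -3.32 and E = 2.

Relative transcript abundance follows the efficiency-corrected ratio

    RTA = E_target ^ dCt_target / E_reference ^ dCt_reference,

with dCt = Ct(control) - Ct(sample) for each gene.  The sign convention is
fixed as control minus sample; reversing it inverts fold changes, so the
control sample is an explicit argument throughout.

GC-FID amounts are computed against a spiked internal standard:
amount_i = area_i / IS_area * IS_amount / tissue_mass (micrograms per mg
dry tissue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "RtaInput",
    "FidSample",
    "efficiency_from_dilutions",
    "rta",
    "rta_from_ct",
    "fid_quantify",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10 template amount; efficiency = 10^(-1/slope)."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)


def efficiency_from_dilutions(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a standard curve to (log10 relative amount, Ct) points.

    Requires >= 3 points with distinct x; a non-negative slope (Ct not
    increasing with dilution) is rejected as an invalid curve.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError("a standard curve needs at least 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(np.unique(x)) < 2:
        raise ValueError("dilution points must span distinct template amounts")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"invalid standard curve: slope {fit.slope:.3g} >= 0 "
            "(Ct must decrease with template amount)"
        )
    return StandardCurve(
        points=tuple(pts),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class RtaInput:
    """Efficiencies and control-minus-sample dCt for target and reference."""

    e_target: float
    e_reference: float
    dct_target: float
    dct_reference: float

    def __post_init__(self) -> None:
        if self.e_target <= 0 or self.e_reference <= 0:
            raise ValueError("amplification efficiencies must be positive")


def rta(inp: RtaInput) -> float:
    """Relative transcript abundance, E_t^dCt_t / E_r^dCt_r."""
    return float(inp.e_target**inp.dct_target / inp.e_reference**inp.dct_reference)


def rta_from_ct(
    e_target: float,
    e_reference: float,
    ct_target_control: float,
    ct_target_sample: float,
    ct_reference_control: float,
    ct_reference_sample: float,
) -> float:
    """RTA straight from the four Ct values (dCt = control - sample)."""
    return rta(
        RtaInput(
            e_target=e_target,
            e_reference=e_reference,
            dct_target=ct_target_control - ct_target_sample,
            dct_reference=ct_reference_control - ct_reference_sample,
        )
    )


@dataclass(frozen=True)
class FidSample:
    """One GC-FID run: compound peak areas, internal standard, tissue mass."""

    peaks: tuple[tuple[str, float], ...]
    internal_standard_area: float
    internal_standard_amount_ug: float = 10.0
    tissue_mass_mg: float = 60.0

    def __post_init__(self) -> None:
        if self.internal_standard_area <= 0:
            raise ValueError("internal standard peak area must be positive")
        if self.tissue_mass_mg <= 0:
            raise ValueError("tissue mass must be positive")
        if any(a < 0 for _, a in self.peaks):
            raise ValueError("peak areas must be non-negative")


def fid_quantify(sample: FidSample) -> list[tuple[str, float]]:
    """Compound amounts in micrograms per mg dry tissue."""
    scale = sample.internal_standard_amount_ug / (
        sample.internal_standard_area * sample.tissue_mass_mg
    )
    return [(name, area * scale) for name, area in sample.peaks]
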