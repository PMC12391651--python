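"""Diffusion-limited analyte capture in the laminar flow channel.

How many analyte molecules land on the imaged footprint during an assay
is estimated with the classical Lévêque solution for mass transfer to a
perfectly absorbing wall under a linear shear flow: in the
thin-concentration-boundary-layer regime the local capture flux decays
as ``x^(-1/3)`` downstream of the leading edge of the capture-active
surface, and the total number of molecules collected on a strip from
``x0`` to ``x0 + L`` of width ``W`` over time ``t`` is

.. math::

   N = \\frac{3^{1/3}}{2\\,\\Gamma(4/3)}\\; c_n\\, D^{2/3} \\gamma^{1/3}
       \\left[(x_0+L)^{2/3} - x_0^{2/3}\\right] W\\, t

with ``c_n`` the inlet number concentration, ``D`` the diffusivity and
``gamma = 6Q/(h^2 w)`` the wall shear rate of the parallel-plate
channel.  The prefactor ``3^(1/3) / (2 Gamma(4/3)) ~= 0.8075`` follows
from integrating the Lévêque flux ``c D (gamma / 9 D x)^{1/3} /
Gamma(4/3)`` along the strip.

The fully-absorbing-wall assumption is exactly the "diffusion-limited"
idealisation: every molecule reaching the surface is captured, so the
estimate is an upper bound that ignores finite binding kinetics.  The
upstream offset ``x0`` of the footprint is not fixed by the instrument
description; the default of 5 mm reproduces the order of magnitude of
the reference capture estimates and is carried in the config so every
estimate reports the value it used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.constants import Avogadro, Boltzmann
from scipy.special import gamma as _gamma_fn

__all__ = [
    "FlowCellAssay",
    "CaptureEstimate",
    "SiteLimitation",
    "LEVEQUE_COEFF",
    "wall_shear",
    "captured_count",
    "diffusivity_dsdna",
    "diffusivity_stokes_einstein",
    "site_limitation_ratio",
]

#: Lévêque strip-integral prefactor, 3^(1/3) / (2 * Gamma(4/3)).
LEVEQUE_COEFF = 3.0 ** (1.0 / 3.0) / (2.0 * _gamma_fn(4.0 / 3.0))


@dataclass(frozen=True)
class FlowCellAssay:
    """Flow-cell geometry and assay conditions.

    Units follow the bench convention: channel dimensions and footprint
    in um, flow rate in uL/min, duration in s, concentration in mol/L,
    diffusivity in m^2/s.
    """

    channel_width_um: float = 1000.0
    channel_height_um: float = 50.0
    flow_rate_ul_min: float = 10.0
    x0_um: float = 5000.0
    footprint_len_um: float = 100.0
    footprint_width_um: float = 100.0
    duration_s: float = 1800.0
    concentration_mol_l: float = 0.0
    diffusivity_m2_s: float = 1e-10

    def __post_init__(self) -> None:
        for name in (
            "channel_width_um",
            "channel_height_um",
            "flow_rate_ul_min",
            "footprint_len_um",
            "footprint_width_um",
            "duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.x0_um < 0:
            raise ValueError("x0 must be >= 0")
        if self.concentration_mol_l < 0:
            raise ValueError("concentration must be >= 0")
        if self.diffusivity_m2_s <= 0:
            raise ValueError("diffusivity must be > 0")

    def with_concentration(self, c_mol_l: float) -> "FlowCellAssay":
        return replace(self, concentration_mol_l=c_mol_l)


@dataclass(frozen=True)
class CaptureEstimate:
    """Result of a diffusion-limited capture calculation."""

    captured_count: float
    wall_shear_per_s: float
    boundary_layer_m: float
    thin_boundary_layer: bool
    x0_um: float
    site_ratio: float | None = None


class SiteLimitation(NamedTuple):
    ratio: float
    flagged: bool


def wall_shear(assay: FlowCellAssay) -> float:
    """Wall shear rate ``6Q / (h^2 w)`` of the parallel-plate channel, 1/s."""
    q = assay.flow_rate_ul_min * 1e-9 / 60.0  # m^3/s
    h = assay.channel_height_um * 1e-6
    w = assay.channel_width_um * 1e-6
    return 6.0 * q / (h * h * w)


def captured_count(assay: FlowCellAssay) -> CaptureEstimate:
    """Molecules captured on the footprint during the assay (Lévêque).

    Linear in concentration and time, and scales as ``D^(2/3)`` and
    ``Q^(1/3)``.  Also reports the concentration-boundary-layer
    thickness ``(9 D x / gamma)^(1/3)`` at the downstream footprint edge
    and whether it stays below half the channel height (the regime in
    which neglecting depletion across the channel height is valid).
    """
    shear = wall_shear(assay)
    c_n = assay.concentration_mol_l * 1e3 * Avogadro  # molecules / m^3
    d = assay.diffusivity_m2_s
    x0 = assay.x0_um * 1e-6
    length = assay.footprint_len_um * 1e-6
    width = assay.footprint_width_um * 1e-6
    strip = (x0 + length) ** (2.0 / 3.0) - x0 ** (2.0 / 3.0)
    n = LEVEQUE_COEFF * c_n * d ** (2.0 / 3.0) * shear ** (1.0 / 3.0) * strip * width * assay.duration_s
    delta = (9.0 * d * (x0 + length) / shear) ** (1.0 / 3.0)
    return CaptureEstimate(
        captured_count=float(n),
        wall_shear_per_s=float(shear),
        boundary_layer_m=float(delta),
        thin_boundary_layer=bool(delta < assay.channel_height_um * 1e-6 / 2.0),
        x0_um=assay.x0_um,
    )


def diffusivity_dsdna(total_bp: int) -> float:
    """Diffusivity of double-stranded DNA of ``total_bp`` base pairs, m^2/s.

    Empirical power law D = 4.9e-10 * bp^(-0.72) m^2/s for linear dsDNA;
    used for the tether constructs and overridable in config.
    """
    if total_bp < 1:
        raise ValueError("total_bp must be >= 1")
    return 4.9e-10 * float(total_bp) ** (-0.72)


def diffusivity_stokes_einstein(
    hydrodynamic_radius_nm: float,
    temperature_k: float = 298.0,
    viscosity_pa_s: float = 8.9e-4,
) -> float:
    """Stokes-Einstein diffusivity kT / (6 pi eta R_h), m^2/s.

    Used for globular species (hairpins, proteins such as IL6 and
    antibodies) characterised by a hydrodynamic radius.
    """
    if hydrodynamic_radius_nm <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise ValueError("all arguments must be > 0")
    r = hydrodynamic_radius_nm * 1e-9
    return Boltzmann * temperature_k / (6.0 * np.pi * viscosity_pa_s * r)


def site_limitation_ratio(captured: float, available_sites: float) -> SiteLimitation:
    """Fraction of available binding sites consumed by capture.

    Above 10% occupancy the fully-absorbing (non-depleting) picture
    starts to break down, so the result carries a flag; at or below the
    boundary the flag stays off.
    """
    if available_sites <= 0:
        raise ValueError("available_sites must be > 0")
    if captured < 0:
        raise ValueError("captured must be >= 0")
    ratio = captured / available_sites
    return SiteLimitation(ratio=float(ratio), flagged=bool(ratio > 0.1))
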