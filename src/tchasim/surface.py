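"""Binding-site statistics of the neutravidin capture monolayer.

A surface-plasmon-resonance measurement of the sensor gives the surface
mass density of the immobilised neutravidin (NA) layer; dividing by the
molecular weight converts it to a molar and then a number density of
biotin-binding sites.  Tethers (FPL constructs) and filler hairpins
compete for these sites in proportion to their solution molar ratio, so
only a small molar fraction of sites carries a tether.  Multiplying the
site density by the imaged footprint area and that fraction yields the
expected number of tether anchors in view -- the ceiling on the number
of fluorescent spots a frame can show.

Anchor positions are realised as a homogeneous Poisson point process on
the footprint; at anchor fractions of 1e-5 the occupied sites are so
sparse that hard-disc exclusion between anchors is negligible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

__all__ = [
    "SurfaceLayer",
    "AnchorField",
    "site_density",
    "mean_spacing",
    "expected_anchor_count",
    "place_anchors",
]


def site_density(mass_density_ng_mm2: float, binder_mw_kda: float) -> float:
    """Binding-site number density in molecules per nm^2.

    Converts a surface mass density (ng/mm^2) to molecules/nm^2 via the
    binder molecular weight.  The measured 4.14 ng/mm^2 NA layer at
    60 kDa gives 4.16e-2 nm^-2, i.e. ~24.1 nm^2 per molecule -- close to
    a fully packed monolayer.
    """
    if binder_mw_kda <= 0:
        raise ValueError("binder molecular weight must be > 0")
    if mass_density_ng_mm2 < 0:
        raise ValueError("mass density must be >= 0")
    grams_per_mm2 = mass_density_ng_mm2 * 1e-9
    mol_per_mm2 = grams_per_mm2 / (binder_mw_kda * 1e3)
    return mol_per_mm2 * Avogadro / 1e12  # nm^2 per mm^2


def mean_spacing(density_per_nm2: float) -> float:
    """Mean distance between binding sites, nm (side of the area per site)."""
    if density_per_nm2 <= 0:
        raise ValueError("density must be > 0")
    return float(np.sqrt(1.0 / density_per_nm2))


@dataclass(frozen=True)
class SurfaceLayer:
    """Capture-monolayer parameters.

    ``anchor_fraction`` is the molar fraction of binding sites that carry
    a tether (set by the tether:filler solution ratio, e.g. 1e-5 for
    10 fM tether against 1 nM filler hairpin).
    """

    mass_density_ng_mm2: float = 4.14
    binder_mw_kda: float = 60.0
    anchor_fraction: float = 1e-5
    footprint_w_um: float = 100.0
    footprint_h_um: float = 100.0

    def __post_init__(self) -> None:
        if self.mass_density_ng_mm2 < 0:
            raise ValueError("mass density must be >= 0")
        if self.binder_mw_kda <= 0:
            raise ValueError("molecular weight must be > 0")
        if not 0.0 <= self.anchor_fraction <= 1.0:
            raise ValueError("anchor_fraction must be in [0, 1]")
        if self.footprint_w_um <= 0 or self.footprint_h_um <= 0:
            raise ValueError("footprint dimensions must be > 0")

    @property
    def site_density_per_nm2(self) -> float:
        return site_density(self.mass_density_ng_mm2, self.binder_mw_kda)

    @property
    def area_per_site_nm2(self) -> float:
        return 1.0 / self.site_density_per_nm2

    @property
    def footprint_area_nm2(self) -> float:
        return (self.footprint_w_um * 1e3) * (self.footprint_h_um * 1e3)


def expected_anchor_count(layer: SurfaceLayer) -> float:
    """Expected number of tether anchors on the imaged footprint.

    site density x footprint area x anchor fraction.  With the measured
    monolayer, a 100x100 um footprint and a 1e-5 fraction this is
    ~4.16e3 -- the upper bound on the number of fluorescent spots.
    """
    return layer.site_density_per_nm2 * layer.footprint_area_nm2 * layer.anchor_fraction


@dataclass
class AnchorField:
    """A spatial realisation of tether anchors on the footprint."""

    positions: np.ndarray  # (n, 2) array of (x, y) in um
    expected_count: float
    footprint_w_um: float
    footprint_h_um: float
    layer: SurfaceLayer | None = field(default=None, repr=False)

    @property
    def realized_count(self) -> int:
        return int(len(self.positions))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.positions, columns=["x_um", "y_um"]).to_csv(path, index=False)

    def sidecar_json(self) -> str:
        meta = {
            "expected_count": self.expected_count,
            "realized_count": self.realized_count,
            "footprint_w_um": self.footprint_w_um,
            "footprint_h_um": self.footprint_h_um,
        }
        if self.layer is not None:
            meta["layer"] = {
                "mass_density_ng_mm2": self.layer.mass_density_ng_mm2,
                "binder_mw_kda": self.layer.binder_mw_kda,
                "anchor_fraction": self.layer.anchor_fraction,
            }
        return json.dumps(meta, indent=2)


def place_anchors(
    expected_count: float,
    footprint_um: tuple[float, float] = (100.0, 100.0),
    seed=None,
    layer: SurfaceLayer | None = None,
) -> AnchorField:
    """Poisson-place anchors uniformly on the footprint.

    The realised count is Poisson(expected_count); positions are i.i.d.
    uniform.  Reproducible for a fixed seed (int or Generator).
    """
    if expected_count < 0:
        raise ValueError("expected_count must be >= 0")
    w, h = footprint_um
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(rng.poisson(expected_count))
    pos = np.column_stack([rng.uniform(0.0, w, n), rng.uniform(0.0, h, n)])
    return AnchorField(pos, float(expected_count), w, h, layer)
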