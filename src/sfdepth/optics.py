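"""Optical-property algebra and tissue presets.

A turbid medium is described by its absorption coefficient ``mua`` (mm^-1),
scattering coefficient ``mus`` (mm^-1), single-scattering anisotropy ``g``
(mean cosine of the scattering angle) and refractive index ``n``.  Diffuse
transport is governed by the derived quantities: the reduced scattering
coefficient mus' = mus*(1 - g), the transport mean free path
l* = 1/(mua + mus') and the ratio mus'/mua, which together set the depth
scale and shape of the detected-photon depth distribution.

Two embedded property sets are provided:

* :func:`tissue_presets` — literature optical properties for four tissue
  types at 731 and 851 nm, used for sampling-depth sweeps.
* :data:`LOOKUP_RATIOS` — the mus'/mua grid (1 to 1000, l* = 1 mm fixed)
  on which the dimensionless sampling-depth lookup table is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "OpticalProperties",
    "DerivedProperties",
    "derive",
    "from_ratio",
    "tissue_presets",
    "tissue_presets_frame",
    "lookup_grid_frame",
    "LOOKUP_RATIOS",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Per-layer optical properties.

    Parameters
    ----------
    mua : float
        Absorption coefficient (mm^-1), >= 0.
    mus : float
        Scattering coefficient (mm^-1), >= 0.  ``mua + mus`` must be > 0.
    g : float
        Single-scattering anisotropy, in (-1, 1).
    n : float
        Refractive index, >= 1.
    """

    mua: float
    mus: float
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        if not (self.mua >= 0.0):
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not (self.mus >= 0.0):
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if not (self.mua + self.mus > 0.0):
            raise ValueError("mua + mus must be > 0 (vacuum layer not allowed)")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"g must be in (-1, 1), got {self.g}")
        if not (self.n >= 1.0):
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mut(self) -> float:
        """Total attenuation coefficient mua + mus (mm^-1)."""
        return self.mua + self.mus

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mus/(mua + mus)."""
        return self.mus / (self.mua + self.mus)


@dataclass(frozen=True)
class DerivedProperties:
    """Transport quantities derived from :class:`OpticalProperties`.

    ``musp`` is the reduced scattering coefficient mus*(1-g) (mm^-1),
    ``lstar`` the transport mean free path 1/(mua+musp) (mm), ``albedo``
    the single-scattering albedo, and ``ratio`` = musp/mua
    (``math.inf`` when mua == 0).
    """

    musp: float
    lstar: float
    albedo: float
    ratio: float


def derive(props: OpticalProperties) -> DerivedProperties:
    """Compute reduced scattering, transport mean free path, albedo, ratio.

    Examples
    --------
    >>> d = derive(OpticalProperties(mua=0.00990099, mus=4.95049505, g=0.8))
    >>> round(d.musp, 8), round(d.lstar, 4), round(d.ratio, 2)
    (0.99009901, 1.0, 100.0)
    """
    musp = props.mus * (1.0 - props.g)
    lstar = 1.0 / (props.mua + musp)
    albedo = props.mus / (props.mua + props.mus)
    ratio = math.inf if props.mua == 0.0 else musp / props.mua
    return DerivedProperties(musp=musp, lstar=lstar, albedo=albedo, ratio=ratio)


def from_ratio(ratio: float, lstar: float, g: float = 0.8, n: float = 1.4) -> OpticalProperties:
    """Construct properties from (mus'/mua, l*) instead of (mua, mus).

    Solves ``musp/mua = ratio`` and ``1/(mua + musp) = lstar``:
    mua = 1/(lstar*(1+ratio)), musp = ratio*mua, mus = musp/(1-g).
    ``derive`` round-trips (ratio, lstar) to machine precision.

    Raises
    ------
    ValueError
        If ratio <= 0, lstar <= 0, or g == 1 (mus undefined).
    """
    if not ratio > 0.0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if not lstar > 0.0:
        raise ValueError(f"lstar must be > 0, got {lstar}")
    if g >= 1.0:
        raise ValueError("g must be < 1 (mus = musp/(1-g) undefined at g=1)")
    mua = 1.0 / (lstar * (1.0 + ratio))
    musp = ratio * mua
    mus = musp / (1.0 - g)
    return OpticalProperties(mua=mua, mus=mus, g=g, n=n)


# Literature tissue optical properties at 731 and 851 nm, stored at full
# printed precision.  Derived columns (musp, lstar, ratio) are always
# recomputed from these, never stored.
_TISSUE_TABLE: Mapping[tuple[str, int], OpticalProperties] = {
    ("human breast", 731): OpticalProperties(mua=0.0044, mus=37.51, g=0.97, n=1.4728),
    ("human breast", 851): OpticalProperties(mua=0.0066, mus=31.95, g=0.97, n=1.4728),
    ("human brain", 731): OpticalProperties(mua=0.0090, mus=16.41, g=0.92, n=1.4026),
    ("human brain", 851): OpticalProperties(mua=0.0124, mus=12.84, g=0.92, n=1.4026),
    ("mouse skin", 731): OpticalProperties(mua=0.0937, mus=7.73, g=0.9, n=1.4),
    ("mouse skin", 851): OpticalProperties(mua=0.1070, mus=6.17, g=0.9, n=1.4),
    ("human skin", 731): OpticalProperties(mua=0.2437, mus=16.32, g=0.8357, n=1.4637),
    ("human skin", 851): OpticalProperties(mua=0.1563, mus=16.71, g=0.8707, n=1.4637),
}

#: mus'/mua values of the lookup-table grid (l* = 1 mm, g = 0.8, n = 1.4).
LOOKUP_RATIOS: tuple[float, ...] = (
    1, 1.6, 2, 3, 4, 5, 8, 10, 16, 20, 30, 50, 80, 100, 160, 250, 300, 1000,
)


def tissue_presets() -> dict[tuple[str, int], OpticalProperties]:
    """Return the embedded (tissue, wavelength-nm) -> properties mapping."""
    return dict(_TISSUE_TABLE)


def tissue_preset(tissue: str, wavelength_nm: int) -> OpticalProperties:
    """Look up a single tissue preset; KeyError lists valid keys."""
    key = (tissue.lower().strip(), int(wavelength_nm))
    try:
        return _TISSUE_TABLE[key]
    except KeyError:
        valid = ", ".join(f"({t!r}, {w})" for t, w in _TISSUE_TABLE)
        raise KeyError(f"unknown tissue preset {key}; valid keys: {valid}") from None


def tissue_presets_frame():
    """Tissue presets as a DataFrame with recomputed derived columns.

    Columns mirror the conventional property-table layout:
    tissue, wavelength_nm, mua, mus, g, lstar, n, ratio, musp.
    """
    import pandas as pd

    rows = []
    for (tissue, wl), p in _TISSUE_TABLE.items():
        d = derive(p)
        rows.append(
            {
                "tissue": tissue,
                "wavelength_nm": wl,
                "mua (mm-1)": p.mua,
                "mus (mm-1)": p.mus,
                "g": p.g,
                "lstar (mm)": d.lstar,
                "n": p.n,
                "musp/mua": d.ratio,
                "musp (mm-1)": d.musp,
            }
        )
    return pd.DataFrame(rows)


def lookup_grid_frame():
    """The lookup-table property grid (l* = 1 mm) as a DataFrame."""
    import pandas as pd

    rows = []
    for r in LOOKUP_RATIOS:
        p = from_ratio(r, 1.0)
        d = derive(p)
        rows.append({"musp/mua": r, "mua (mm-1)": p.mua, "musp (mm-1)": d.musp})
    return pd.DataFrame(rows)
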