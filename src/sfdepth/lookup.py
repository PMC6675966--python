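"""Dimensionless sampling-depth lookup table and interpolation.

Diffuse transport in a homogeneous half-space at fixed (g, n) obeys a
similarity scaling: multiplying (mua, mus) by k and fx by k divides every
length — including the percentile sampling depths dX — by k.  Percentile
depths therefore collapse onto a two-parameter surface

    dX / l*  =  F_X( mus'/mua,  fx * l* )

where l* = 1/(mua + mus') is the transport mean free path.  The table is
built once by simulating media with l* = 1 mm, g = 0.8, n = 1.4 over a
grid of mus'/mua in [1, 1000] and dimensionless frequencies fx*l*; a query
for arbitrary (mua, mus') normalizes to (ratio, fx*l*), interpolates
bilinearly on (ln(mus'/mua), fx*l*), and rescales by l*.  Tissues whose g
and n differ from the table's fixed values rely on the same similarity
reduction; the residual error is quantified by
:func:`validate_against_direct`.

A prebuilt table is shipped with the package (``data/default_table.csv``)
so queries work without re-simulation; :func:`load_default_table` reads it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .depth_metrics import DEFAULT_FRACTIONS, depth_summary
from .optics import LOOKUP_RATIOS, OpticalProperties, derive, from_ratio
from .sfd_tally import DepthGrid
from .simulate import run_simulation
from .transport import LayerStack

__all__ = [
    "LookupTable",
    "build_table",
    "load_default_table",
    "validate_against_direct",
    "DEFAULT_FXL_GRID",
]

#: Default dimensionless frequency grid fx*l*.  The refinement nodes at
#: 0.15-0.4 cost nothing extra (every frequency is tallied in the same
#: run per ratio) and keep the bilinear interpolation error of the
#: convex d50(fx*l*) curve well below the node noise.
DEFAULT_FXL_GRID = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class LookupTable:
    """Percentile sampling depths dX/l* on a (mus'/mua, fx*l*) grid.

    ``values[X]`` is an ``[n_ratio, n_fxl]`` array of dX/l*;
    ``sigma[X]`` the per-node Monte Carlo 1-sigma (same units).
    Fixed build parameters: g = 0.8, n = 1.4, l* = 1 mm.
    """

    ratio_axis: np.ndarray
    fxl_axis: np.ndarray
    values: dict
    sigma: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.ratio_axis, dtype=float)
        f = np.asarray(self.fxl_axis, dtype=float)
        if r.ndim != 1 or np.any(np.diff(r) <= 0):
            raise ValueError("ratio_axis must be strictly increasing")
        if f.ndim != 1 or np.any(np.diff(f) <= 0):
            raise ValueError("fxl_axis must be strictly increasing")
        for X, v in self.values.items():
            v = np.asarray(v)
            if v.shape != (r.size, f.size):
                raise ValueError(f"values[{X}] has shape {v.shape}, expected {(r.size, f.size)}")
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"values[{X}] must be positive and finite")
        object.__setattr__(self, "ratio_axis", r)
        object.__setattr__(self, "fxl_axis", f)

    @property
    def fractions(self) -> tuple:
        return tuple(sorted(self.values))

    def _interpolator(self, X: float) -> RegularGridInterpolator:
        if X not in self.values:
            raise KeyError(f"fraction X={X} not tabulated; available: {self.fractions}")
        return RegularGridInterpolator(
            (np.log(self.ratio_axis), self.fxl_axis), np.asarray(self.values[X]),
            method="linear", bounds_error=True)

    def query(self, mua: float, musp: float, fx_list, X: float = 0.5) -> np.ndarray:
        """Percentile depths dX (mm) for a medium given only (mua, mus').

        Normalizes to (mus'/mua, fx*l*), interpolates bilinearly on
        (ln ratio, fx*l*), rescales by l*.  No extrapolation: ratio or
        fx*l* outside the table raises ValueError.
        """
        if not (mua > 0.0 and musp > 0.0):
            raise ValueError("mua and musp must be > 0")
        ratio = musp / mua
        lstar = 1.0 / (mua + musp)
        rmin, rmax = self.ratio_axis[0], self.ratio_axis[-1]
        if not (rmin <= ratio <= rmax):
            raise ValueError(
                f"mus'/mua = {ratio:.4g} outside the tabulated range [{rmin:g}, {rmax:g}]; "
                "no extrapolation is performed")
        fx = np.atleast_1d(np.asarray(fx_list, dtype=float))
        fxl = fx * lstar
        fmin, fmax = self.fxl_axis[0], self.fxl_axis[-1]
        if np.any(fxl < fmin) or np.any(fxl > fmax):
            raise ValueError(
                f"fx*l* values {fxl.tolist()} outside the tabulated range [{fmin:g}, {fmax:g}]")
        interp = self._interpolator(X)
        pts = np.column_stack([np.full(fxl.size, math.log(ratio)), fxl])
        return interp(pts) * lstar

    # ---- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for X in self.fractions:
            v = np.asarray(self.values[X])
            s = np.asarray(self.sigma.get(X, np.zeros_like(v)))
            for i, r in enumerate(self.ratio_axis):
                for j, f in enumerate(self.fxl_axis):
                    rows.append({"ratio": r, "fxl": f, "X": X,
                                 "d_over_lstar": v[i, j], "sigma": s[i, j]})
        return pd.DataFrame(rows)

    def save(self, csv_path, meta_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"schema": "sfdepth.lut.v1", **self.meta}, fh, indent=1)

    @staticmethod
    def from_frame(df: pd.DataFrame, meta: dict | None = None) -> "LookupTable":
        ratios = np.sort(df["ratio"].unique())
        fxls = np.sort(df["fxl"].unique())
        values, sigma = {}, {}
        for X, sub in df.groupby("X"):
            v = sub.pivot(index="ratio", columns="fxl", values="d_over_lstar")
            s = sub.pivot(index="ratio", columns="fxl", values="sigma")
            values[float(X)] = v.loc[ratios, fxls].to_numpy()
            sigma[float(X)] = s.loc[ratios, fxls].to_numpy()
        return LookupTable(ratio_axis=ratios, fxl_axis=fxls, values=values,
                           sigma=sigma, meta=meta or {})

    @staticmethod
    def load(csv_path, meta_path=None) -> "LookupTable":
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return LookupTable.from_frame(pd.read_csv(csv_path), meta)


def build_table(ratios=LOOKUP_RATIOS, fxl_grid=DEFAULT_FXL_GRID,
                n_packets: int = 100_000, seed: int = 0,
                fractions=DEFAULT_FRACTIONS, g: float = 0.8, n: float = 1.4,
                grid: DepthGrid = DepthGrid(), progress=None) -> LookupTable:
    """Build the dimensionless lookup table by direct simulation.

    One simulation per mus'/mua value (all fx*l* tallied in the same run)
    with l* = 1 mm, so fx = fx*l* numerically and depths are already in
    units of l*.  Percentile-depth node uncertainties are estimated by
    propagating the tally sigma through the local slope of the cumulative
    depth fraction.
    """
    ratios = sorted(float(r) for r in ratios)
    fxl = sorted(float(f) for f in fxl_grid)
    fractions = tuple(fractions)
    values = {X: np.empty((len(ratios), len(fxl))) for X in fractions}
    sigma = {X: np.empty((len(ratios), len(fxl))) for X in fractions}
    for i, ratio in enumerate(ratios):
        props = from_ratio(ratio, 1.0, g=g, n=n)
        stack = LayerStack.homogeneous(props)
        res = run_simulation(stack, fxl, n_packets, seed + i, grid)
        stats = depth_summary(res, fractions)
        for j, f in enumerate(fxl):
            pz = res.pzmax_row(f)
            rd = pz.sum()
            for X in fractions:
                dX = stats.d(f, X)
                values[X][i, j] = dX
                # sigma(dX) ~ sigma(P_V&D at dX) / (local density at dX)
                k = res.grid.bin_index(dX)
                dens = max(pz[min(k, res.grid.n_bins - 1)] / res.grid.dz, 1e-300)
                sig_pvd = res.sigma_re[res.fx_index(f), min(k, res.grid.n_bins)]
                sigma[X][i, j] = sig_pvd / dens if rd > 0 else np.nan
        if progress is not None:
            progress(i + 1, len(ratios), ratio)
    meta = {"g": g, "n": n, "lstar_mm": 1.0, "n_packets_per_node": n_packets,
            "seed": seed, "grid": {"dz": grid.dz, "z_cap": grid.z_cap}}
    return LookupTable(ratio_axis=np.asarray(ratios), fxl_axis=np.asarray(fxl),
                       values=values, sigma=sigma, meta=meta)


def load_default_table() -> LookupTable:
    """Load the prebuilt table shipped with the package."""
    data = resources.files("sfdepth").joinpath("data")
    with resources.as_file(data.joinpath("default_table.csv")) as csv_path, \
            resources.as_file(data.joinpath("default_table.json")) as meta_path:
        return LookupTable.load(csv_path, meta_path)


def validate_against_direct(table: LookupTable, props: OpticalProperties,
                            fx_list, n_packets: int = 1_000_000, seed: int = 0,
                            X: float = 0.5, grid: DepthGrid = DepthGrid(),
                            result=None) -> pd.DataFrame:
    """Lookup-table depths vs. a direct simulation at the true (g, n).

    Runs (or reuses) a direct simulation with the medium's actual
    anisotropy and refractive index and reports the per-frequency relative
    difference (d_table - d_MC)/d_MC.
    """
    d = derive(props)
    fx = np.atleast_1d(np.asarray(fx_list, dtype=float))
    d_table = table.query(props.mua, d.musp, fx, X)
    if result is None:
        result = run_simulation(LayerStack.homogeneous(props), fx, n_packets, seed, grid)
    stats = depth_summary(result, (X,))
    d_mc = np.array([stats.d(f, X) for f in fx])
    return pd.DataFrame({
        "fx": fx, "d_table": d_table, "d_direct": d_mc,
        "rel_diff": (d_table - d_mc) / d_mc,
    })
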