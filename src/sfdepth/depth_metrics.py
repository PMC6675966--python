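"""Sampling-depth summaries derived from the maximum-depth distribution.

Given the real part of a finalized ``P_zmax`` row (per-bin detected weight
over maximum visited depth, normalized per launched packet):

* ``total_reflectance``     Rd           = sum over all bins (incl. overflow)
* ``restricted_reflectance`` Pzmax(z<=d) = integral of P_zmax up to depth d
* ``sampling_fraction``     X(d)         = Pzmax(z<=d) / Rd
* ``percentile_depth``      dX           = inverse of X(d) at a given fraction

``dX`` is the depth above which a fraction X of the detected reflectance
is entirely contained: photons contributing that share of the signal never
travelled deeper than dX.  Percentiles interpolate linearly inside the
crossing bin, making the inverse well defined below the bin resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfd_tally import DepthGrid, SfdTallyResult

__all__ = [
    "total_reflectance",
    "restricted_reflectance",
    "sampling_fraction",
    "percentile_depth",
    "depth_summary",
    "DepthStatistics",
]

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 0.90)


def _row(pzmax_row) -> np.ndarray:
    a = np.asarray(pzmax_row)
    if np.iscomplexobj(a):
        a = a.real
    return np.asarray(a, dtype=float)


def total_reflectance(pzmax_row) -> float:
    """Rd: total detected weight per launched packet (overflow included)."""
    return float(_row(pzmax_row).sum())


def restricted_reflectance(pzmax_row, d: float, grid: DepthGrid) -> float:
    """Detected weight from packets whose maximum depth is <= d.

    The partially covered bin is pro-rated linearly; the overflow bin is
    counted only at d = inf.
    """
    if d < 0.0:
        raise ValueError(f"depth d must be >= 0, got {d}")
    row = _row(pzmax_row)
    if math.isinf(d):
        return float(row.sum())
    body = row[:-1]
    nb = body.size
    i = int(d / grid.dz)
    if i >= nb:
        return float(body.sum())
    full = float(body[:i].sum())
    frac = (d - i * grid.dz) / grid.dz
    return full + float(body[i]) * frac


def sampling_fraction(pzmax_row, d: float, grid: DepthGrid) -> float:
    """Fraction X of detected reflectance restricted to depths <= d."""
    rd = total_reflectance(pzmax_row)
    if rd <= 0.0:
        raise ValueError("sampling fraction undefined: Rd = 0")
    return restricted_reflectance(pzmax_row, d, grid) / rd


def percentile_depth(pzmax_row, X: float, grid: DepthGrid) -> float:
    """Smallest depth d with sampling_fraction(d) >= X.

    Linear interpolation inside the crossing bin.  Raises if X exceeds the
    fraction attainable within ``z_cap`` (mass in the overflow bin), with
    a message pointing at ``z_cap``.
    """
    if not (0.0 < X <= 1.0):
        raise ValueError(f"X must be in (0, 1], got {X}")
    row = _row(pzmax_row)
    rd = row.sum()
    if rd <= 0.0:
        raise ValueError("percentile depth undefined: Rd = 0")
    target = X * rd
    body = row[:-1]
    cum = np.cumsum(body)
    attainable = cum[-1] if cum.size else 0.0
    # tolerate float rounding at X = 1 with an empty overflow bin
    if target > attainable and not math.isclose(target, attainable, rel_tol=1e-12):
        raise ValueError(
            f"fraction X={X} is not attainable within z_cap={grid.z_cap} mm "
            f"(max attainable {attainable / rd:.6f}); re-run with a larger z_cap")
    idx = int(np.searchsorted(cum, target, side="left"))
    if idx >= body.size:
        idx = body.size - 1
    before = cum[idx - 1] if idx > 0 else 0.0
    binmass = body[idx]
    if binmass <= 0.0:
        return idx * grid.dz
    frac = min((target - before) / binmass, 1.0)
    return (idx + frac) * grid.dz


@dataclass(frozen=True)
class DepthStatistics:
    """Per-frequency reflectance and percentile sampling depths."""

    table: pd.DataFrame  # columns: fx, Rd, d10, d25, d50, ... per request

    def d(self, fx: float, X: float) -> float:
        col = f"d{int(round(X * 100))}"
        row = self.table.loc[np.isclose(self.table["fx"], fx)]
        if row.empty:
            raise KeyError(f"fx={fx} not in summary")
        return float(row.iloc[0][col])

    def rd(self, fx: float) -> float:
        row = self.table.loc[np.isclose(self.table["fx"], fx)]
        if row.empty:
            raise KeyError(f"fx={fx} not in summary")
        return float(row.iloc[0]["Rd"])

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def depth_summary(result: SfdTallyResult, fractions=DEFAULT_FRACTIONS) -> DepthStatistics:
    """Per-frequency Rd and percentile depths dX for each requested X."""
    fractions = tuple(fractions)
    rows = []
    for k, f in enumerate(result.fx):
        pz = result.pzmax[k].real
        rec = {"fx": float(f), "Rd": total_reflectance(pz)}
        for X in fractions:
            rec[f"d{int(round(X * 100))}"] = percentile_depth(pz, X, result.grid)
        rows.append(rec)
    return DepthStatistics(table=pd.DataFrame(rows))
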