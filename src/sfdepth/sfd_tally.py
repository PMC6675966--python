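"""Spatial-frequency-domain tally of detected packets over maximum depth.

Under illumination modulated along x at spatial frequency ``fx``, each
detected packet contributes the complex weight

    xi = W * exp(-2*pi*i * fx * (x_exit - x_entry))

whose sample mean over launched packets estimates the spatially modulated
diffuse reflectance.  Tallying xi into bins of the packet's maximum visited
depth ``z_max`` yields the distribution ``P_zmax(z)``; its reverse
cumulative sum is the visitation-and-detection probability ``P_V&D(z)`` —
the expected detected weight among packets whose trajectories reached
depth z.  The two are exact mutual inverses (successive differencing vs.
reverse cumulative sum), and ``P_V&D(0)`` equals the total diffuse
reflectance ``Rd(fx)``.

The accumulator stores per-bin complex first moments and real second
moments (of the real and imaginary parts separately) so that finalized
results carry 1-sigma Monte Carlo uncertainties.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DepthGrid",
    "SfdAccumulator",
    "SfdTallyResult",
    "sfd_weight",
    "pvd_from_pzmax",
    "pzmax_from_pvd",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DepthGrid:
    """Uniform depth binning: bin i covers [i*dz, (i+1)*dz).

    One overflow bin beyond ``z_cap`` collects packets that dove deeper
    than the tallied range; its mass still counts toward Rd.
    """

    dz: float = 0.01
    z_cap: float = 40.0

    def __post_init__(self):
        if not (self.dz > 0.0):
            raise ValueError(f"dz must be > 0, got {self.dz}")
        nb = self.z_cap / self.dz
        if not (self.z_cap > 0.0) or abs(nb - round(nb)) > 1e-9:
            raise ValueError(
                f"z_cap must be a positive multiple of dz, got z_cap={self.z_cap}, dz={self.dz}")

    @property
    def n_bins(self) -> int:
        """Number of regular bins (excluding the overflow bin)."""
        return int(round(self.z_cap / self.dz))

    @property
    def z_lower(self) -> np.ndarray:
        """Lower edges of the regular bins plus the overflow bin edge."""
        return np.arange(self.n_bins + 1) * self.dz

    def bin_index(self, z: float) -> int:
        """Bin containing depth z (overflow bin index is ``n_bins``)."""
        if z < 0.0:
            raise ValueError(f"negative depth {z}")
        return min(int(z / self.dz), self.n_bins)


def sfd_weight(W: float, fx: float, dx: float) -> complex:
    """Complex SFD tally xi = W * exp(-2*pi*i*fx*dx); |xi| = W."""
    ph = -_TWO_PI * fx * dx
    return complex(W * math.cos(ph), W * math.sin(ph))


def pvd_from_pzmax(pzmax: np.ndarray) -> np.ndarray:
    """Reverse cumulative sum along the last axis: P_V&D(z_i) = sum_{j>=i} P_zmax(z_j)."""
    a = np.asarray(pzmax)
    return np.flip(np.cumsum(np.flip(a, axis=-1), axis=-1), axis=-1)


def pzmax_from_pvd(pvd: np.ndarray) -> np.ndarray:
    """Successive differences along the last axis; the last entry is the tail."""
    a = np.asarray(pvd)
    out = np.empty_like(a)
    out[..., :-1] = a[..., :-1] - a[..., 1:]
    out[..., -1] = a[..., -1]
    return out


class SfdAccumulator:
    """Streaming accumulator for the per-zmax-bin complex tally.

    The numba production kernel writes into the same arrays directly;
    :meth:`tally_event` is the per-event Python path used by tests and
    small studies.  Both apply identical arithmetic per event.
    """

    def __init__(self, fx_list, grid: DepthGrid = DepthGrid()):
        self.fx = np.atleast_1d(np.asarray(fx_list, dtype=float))
        if self.fx.ndim != 1 or np.any(self.fx < 0.0):
            raise ValueError("fx_list must be a 1-D sequence of nonnegative frequencies")
        self.grid = grid
        shape = (self.fx.size, grid.n_bins + 1)
        self.sum_re = np.zeros(shape)
        self.sum_im = np.zeros(shape)
        self.m2_re = np.zeros(shape)
        self.m2_im = np.zeros(shape)
        self.counts = np.zeros(grid.n_bins + 1, dtype=np.int64)
        self.n_launched = 0
        self.n_detected = 0
        self.detected_weight = 0.0

    def tally_event(self, event) -> None:
        """Add one detection event to every spatial-frequency row."""
        if event.z_deepest < 0.0:
            raise ValueError("negative z_deepest (kernel bug)")
        b = self.grid.bin_index(event.z_deepest)
        for k, f in enumerate(self.fx):
            ph = -_TWO_PI * f * event.dx
            re = event.W * math.cos(ph)
            im = event.W * math.sin(ph)
            self.sum_re[k, b] += re
            self.sum_im[k, b] += im
            self.m2_re[k, b] += re * re
            self.m2_im[k, b] += im * im
        self.counts[b] += 1
        self.n_detected += 1
        self.detected_weight += event.W

    def finalize(self, n_launched: int | None = None, seed=None,
                 stack_description: dict | None = None) -> "SfdTallyResult":
        """Normalize by the number of *launched* packets and derive P_V&D."""
        N = self.n_launched if n_launched is None else int(n_launched)
        if N < 1:
            raise ValueError("cannot finalize a tally with N = 0 launched packets")
        pzmax = (self.sum_re + 1j * self.sum_im) / N
        pvd = pvd_from_pzmax(pzmax)
        # variance of the P_V&D estimator: reverse-accumulated moments
        s1_re = pvd_from_pzmax(self.sum_re)
        s1_im = pvd_from_pzmax(self.sum_im)
        s2_re = pvd_from_pzmax(self.m2_re)
        s2_im = pvd_from_pzmax(self.m2_im)
        var_re = np.maximum(s2_re / N - (s1_re / N) ** 2, 0.0) / N
        var_im = np.maximum(s2_im / N - (s1_im / N) ** 2, 0.0) / N
        return SfdTallyResult(
            fx=self.fx.copy(), grid=self.grid, pzmax=pzmax, pvd=pvd,
            sigma_re=np.sqrt(var_re), sigma_im=np.sqrt(var_im),
            N=N, seed=seed, n_detected=self.n_detected,
            detected_weight=self.detected_weight,
            counts=self.counts.copy(),
            stack_description=stack_description or {},
        )


@dataclass(frozen=True)
class SfdTallyResult:
    """Finalized per-frequency depth distributions.

    ``pzmax`` and ``pvd`` have shape ``[n_fx, n_bins + 1]`` (last column
    is the overflow bin / overflow tail); both are complex and normalized
    per launched packet.  ``sigma_re``/``sigma_im`` are 1-sigma Monte
    Carlo uncertainties of the real/imaginary parts of ``pvd``.
    """

    fx: np.ndarray
    grid: DepthGrid
    pzmax: np.ndarray
    pvd: np.ndarray
    sigma_re: np.ndarray
    sigma_im: np.ndarray
    N: int
    seed: object
    n_detected: int
    detected_weight: float
    counts: np.ndarray
    stack_description: dict = field(default_factory=dict)

    def fx_index(self, fx: float) -> int:
        k = np.where(np.isclose(self.fx, fx, rtol=0, atol=1e-12))[0]
        if k.size == 0:
            raise KeyError(f"fx={fx} not tallied; available: {self.fx.tolist()}")
        return int(k[0])

    def rd(self, fx: float | None = None):
        """Total diffuse reflectance Rd(fx) = P_V&D(0) (real part)."""
        if fx is None:
            return self.pvd[:, 0].real.copy()
        return float(self.pvd[self.fx_index(fx), 0].real)

    def pvd_at(self, fx: float, z: float) -> float:
        """Real part of P_V&D at the tally surface containing depth z."""
        k = self.fx_index(fx)
        i = min(int(round(z / self.grid.dz)), self.grid.n_bins)
        return float(self.pvd[k, i].real)

    def pzmax_row(self, fx: float) -> np.ndarray:
        """Real P_zmax row (including overflow bin) for one frequency."""
        return self.pzmax[self.fx_index(fx)].real.copy()

    # ---- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (fx, depth bin)."""
        nb = self.grid.n_bins + 1
        z_lower = np.concatenate([self.grid.z_lower[:-1], [self.grid.z_cap]])
        rows = {
            "fx": np.repeat(self.fx, nb),
            "z_bin_lower": np.tile(z_lower, self.fx.size),
            "pvd_re": self.pvd.real.ravel(),
            "pvd_im": self.pvd.imag.ravel(),
            "pvd_sigma": self.sigma_re.ravel(),
            "pzmax_re": self.pzmax.real.ravel(),
            "pzmax_im": self.pzmax.imag.ravel(),
        }
        return pd.DataFrame(rows)

    def sidecar(self) -> dict:
        try:
            from importlib.metadata import version

            pkg_version = version("sfdepth")
        except Exception:
            pkg_version = "unknown"
        return {
            "schema": "sfdepth.tally.v1",
            "version": pkg_version,
            "seed": self.seed,
            "N": self.N,
            "n_detected": self.n_detected,
            "fx": self.fx.tolist(),
            "grid": {"dz": self.grid.dz, "z_cap": self.grid.z_cap},
            "stack": self.stack_description,
        }

    def save(self, csv_path, sidecar_path=None) -> None:
        # %.17g makes the float round-trip exact
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.sidecar(), fh, indent=1)

    @staticmethod
    def load(csv_path, sidecar_path) -> "SfdTallyResult":
        """Rebuild a result from its CSV + JSON sidecar (lossless for the
        quantities depth metrics need; second moments are not stored)."""
        df = pd.read_csv(csv_path, float_precision="round_trip")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        fx = np.asarray(meta["fx"], dtype=float)
        grid = DepthGrid(**meta["grid"])
        nb = grid.n_bins + 1
        pvd = (df["pvd_re"].to_numpy() + 1j * df["pvd_im"].to_numpy()).reshape(fx.size, nb)
        pzmax = (df["pzmax_re"].to_numpy() + 1j * df["pzmax_im"].to_numpy()).reshape(fx.size, nb)
        sigma = df["pvd_sigma"].to_numpy().reshape(fx.size, nb)
        return SfdTallyResult(
            fx=fx, grid=grid, pzmax=pzmax, pvd=pvd, sigma_re=sigma,
            sigma_im=np.zeros_like(sigma), N=meta["N"], seed=meta.get("seed"),
            n_detected=meta.get("n_detected", 0),
            detected_weight=float(pvd[0, 0].real * meta["N"]) if fx[0] == 0 else 0.0,
            counts=np.zeros(nb, dtype=np.int64),
            stack_description=meta.get("stack", {}),
        )
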