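"""High-level simulation drivers tying transport to the SFD tally.

``run_simulation`` is the workhorse: it launches N photon packets into a
layer stack and returns a finalized :class:`~sfdepth.sfd_tally.SfdTallyResult`
with per-frequency depth distributions.  Reproducibility contract:
identical (seed, N, stack, fx, grid, roulette, specular) give bit-identical
tallies.  Packets are simulated in fixed-size chunks of 2**16, each chunk
drawing from an independent substream spawned from the seed, so a run can
be partitioned at chunk granularity without changing its output.

``two_layer_stack`` and ``phantom_sweep`` build the two-layer
scattering-over-absorbing geometry used to validate the depth-restricted
reflectance: a perfectly absorbing base starting at depth d extinguishes
every packet that dives below d, so the two-layer total reflectance equals
the homogeneous medium's reflectance restricted to maximum depths <= d.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .depth_metrics import restricted_reflectance
from .optics import OpticalProperties
from .sfd_tally import DepthGrid, SfdAccumulator, SfdTallyResult
from .transport import SPECULAR_EXCLUDE, LayerStack, kernel, kernel_py

__all__ = [
    "run_simulation",
    "two_layer_stack",
    "phantom_sweep",
    "CHUNK_SIZE",
    "DEFAULT_FX",
]

#: Packets per random-substream chunk (fixed: part of the determinism contract).
CHUNK_SIZE = 1 << 16

#: Default spatial-frequency list (mm^-1): the experimental projection set,
#: extendable to 0.5.
DEFAULT_FX = (0.0, 0.0125, 0.025, 0.0375, 0.05, 0.0625, 0.075, 0.0875,
              0.1, 0.125, 0.15, 0.175, 0.2, 0.25, 0.3)


def run_simulation(stack: LayerStack, fx_list=DEFAULT_FX, n_packets: int = 1_000_000,
                   seed: int = 0, grid: DepthGrid = DepthGrid(),
                   roulette_threshold: float = 1e-4, roulette_survival: float = 0.1,
                   specular: str = SPECULAR_EXCLUDE, use_jit: bool = True) -> SfdTallyResult:
    """Monte Carlo SFD depth-distribution simulation.

    Parameters
    ----------
    stack : LayerStack
        Medium description (last layer semi-infinite).
    fx_list : sequence of float
        Spatial frequencies (mm^-1) tallied in a single pass.
    n_packets : int
        Packets launched (normalization denominator), >= 1.
    seed : int
        Root seed; every random draw derives from it.
    grid : DepthGrid
        Maximum-depth binning (default dz = 0.01 mm, z_cap = 40 mm).
    roulette_threshold, roulette_survival : float
        Russian-roulette parameters; threshold 0 disables roulette.
    specular : str
        ``"exclude"`` (launch W = 1 just inside the surface; default) or
        ``"include"`` (launch W reduced by the normal-incidence specular
        reflection).
    use_jit : bool
        Use the numba kernel (default) or the pure-Python reference path.
    """
    if n_packets < 1:
        raise ValueError(f"n_packets must be >= 1, got {n_packets}")
    if not ((0.0 < roulette_threshold < 1.0) or roulette_threshold == 0.0):
        raise ValueError("roulette_threshold must be 0 (off) or in (0, 1)")
    if not (0.0 < roulette_survival < 1.0):
        raise ValueError("roulette_survival must be in (0, 1)")
    acc = SfdAccumulator(fx_list, grid)
    arrays = stack.to_arrays()
    w0 = stack.launch_weight(specular)
    kern = kernel if use_jit else kernel_py
    n_chunks = (n_packets + CHUNK_SIZE - 1) // CHUNK_SIZE
    children = np.random.SeedSequence(seed).spawn(n_chunks)
    launched = 0
    for c in range(n_chunks):
        n_this = min(CHUNK_SIZE, n_packets - launched)
        rng = np.random.Generator(np.random.PCG64(children[c]))
        n_det, wsum = kern.run_chunk(
            rng, n_this, *arrays, stack.n_ambient, w0,
            roulette_threshold, roulette_survival,
            acc.fx, grid.dz, grid.n_bins,
            acc.sum_re, acc.sum_im, acc.m2_re, acc.m2_im, acc.counts)
        acc.n_detected += int(n_det)
        acc.detected_weight += float(wsum)
        launched += n_this
    acc.n_launched = launched
    return acc.finalize(seed=seed, stack_description=stack.describe())


#: Default "perfectly extinguishing" base layer for two-layer studies.
ABSORBING_BASE = OpticalProperties(mua=100.0, mus=0.0, g=0.0, n=1.4)


def two_layer_stack(top: OpticalProperties, top_thickness: float,
                    base: OpticalProperties = ABSORBING_BASE,
                    n_ambient: float = 1.0) -> LayerStack:
    """Scattering top layer of finite thickness over a semi-infinite base."""
    if not (top_thickness > 0.0):
        raise ValueError(f"top_thickness must be > 0, got {top_thickness}")
    return LayerStack([(top, top_thickness), (base, math.inf)], n_ambient=n_ambient)


def phantom_sweep(top: OpticalProperties, depths, fx_list=DEFAULT_FX,
                  n_packets: int = 100_000, seed: int = 0,
                  grid: DepthGrid = DepthGrid(), base: OpticalProperties = ABSORBING_BASE,
                  homogeneous_result: SfdTallyResult | None = None,
                  **sim_kwargs) -> pd.DataFrame:
    """Two-layer reflectance vs. homogeneous depth-restricted reflectance.

    For each top-layer thickness d, runs an explicit two-layer simulation
    (absorbing base at depth d) and compares its total reflectance Rd(fx)
    with Pzmax(z<=d) of a homogeneous simulation of the top medium.  A
    thickness of 0 is reported as Rd = 0 (bare absorber).

    Returns a long-format frame with columns
    (d, fx, rd_two_layer, restricted_homog, difference, sigma_two_layer).
    """
    depths = [float(d) for d in depths]
    if homogeneous_result is None:
        homogeneous_result = run_simulation(
            LayerStack.homogeneous(top), fx_list, n_packets, seed, grid, **sim_kwargs)
    rows = []
    for j, d in enumerate(depths):
        if d < 0.0:
            raise ValueError(f"top-layer thickness must be >= 0, got {d}")
        if d == 0.0:
            rd = {f: 0.0 for f in homogeneous_result.fx}
            sig = {f: 0.0 for f in homogeneous_result.fx}
        else:
            res = run_simulation(two_layer_stack(top, d, base), fx_list,
                                 n_packets, seed + 1 + j, grid, **sim_kwargs)
            rd = {f: res.rd(f) for f in res.fx}
            sig = {f: float(res.sigma_re[res.fx_index(f), 0]) for f in res.fx}
        for f in homogeneous_result.fx:
            restr = restricted_reflectance(homogeneous_result.pzmax_row(f), d, grid)
            rows.append({
                "d": d, "fx": float(f),
                "rd_two_layer": rd[f],
                "restricted_homog": restr,
                "difference": rd[f] - restr,
                "sigma_two_layer": sig[f],
            })
    return pd.DataFrame(rows)
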