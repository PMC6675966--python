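"""Photon-packet random walk in a laterally infinite layered slab.

The medium is a stack of horizontal layers (the last one semi-infinite)
bounded above by an ambient medium of refractive index ``n_ambient``.
Packets are launched as a pencil beam at the origin, normally incident,
and propagated with the conventional weighted Monte Carlo scheme:

* exponential free paths, s = -ln(u)/(mua+mus), in the current layer;
* discrete absorption weighting — at every collision the packet weight is
  multiplied by the single-scattering albedo mus/(mua+mus) instead of
  terminating packets probabilistically;
* Henyey-Greenstein scattering with uniform azimuth;
* stochastically sampled unpolarized Fresnel reflection/refraction at the
  top surface and at internal index mismatches (total internal reflection
  beyond the critical angle);
* Russian roulette once the weight drops below a threshold (survivors are
  reweighted so the tally stays unbiased).

Each packet tracks the maximum depth ``z_max`` it ever visits.  A packet
that refracts out through the top surface is *detected* and yields a
:class:`DetectionEvent` carrying its weight, lateral displacement
``dx = x_exit - x_entry`` and ``z_max``; these are the only quantities the
spatial-frequency-domain tally needs.

The propagation kernel is defined once, in :func:`_build_kernel`, and
instantiated twice: jitted with numba for production runs, and as plain
Python for tests that need bit-identical reference behaviour or full
trajectory recording.  Both variants consume the same ``numpy.random.
Generator`` draws in the same order, so their outputs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import OpticalProperties

__all__ = [
    "LayerStack",
    "DetectionEvent",
    "sample_step",
    "sample_hg",
    "fresnel_reflectance",
    "kernel",
    "kernel_py",
    "SPECULAR_EXCLUDE",
    "SPECULAR_INCLUDE",
]

_TWO_PI = 2.0 * math.pi

#: Specular handling modes for the launch weight.
SPECULAR_EXCLUDE = "exclude"  # start just inside the medium with W = 1
SPECULAR_INCLUDE = "include"  # W = 1 - ((n - n_amb)/(n + n_amb))^2

# Packet status codes returned by the kernel.
STATUS_DETECTED = 1
STATUS_TERMINATED = 0
STATUS_ERROR = -1

# Hard cap on interactions per packet; a healthy simulation never reaches
# it (roulette or detection terminates packets long before).
_MAX_STEPS = 100_000_000


@dataclass(frozen=True)
class LayerStack:
    """Ordered layers over depth; the last layer is semi-infinite.

    Parameters
    ----------
    layers : sequence of (OpticalProperties, thickness_mm)
        Thickness of the last layer may be ``math.inf``; all finite
        thicknesses must be > 0.
    n_ambient : float
        Refractive index of the medium above the top surface (default 1.0).
    """

    layers: tuple[tuple[OpticalProperties, float], ...]
    n_ambient: float = 1.0

    def __init__(self, layers: Sequence[tuple[OpticalProperties, float]], n_ambient: float = 1.0):
        if len(layers) == 0:
            raise ValueError("LayerStack needs at least one layer")
        for i, (props, th) in enumerate(layers):
            if not isinstance(props, OpticalProperties):
                raise TypeError(f"layer {i}: expected OpticalProperties, got {type(props)}")
            last = i == len(layers) - 1
            if not (th > 0.0):
                raise ValueError(f"layer {i}: thickness must be > 0, got {th}")
            if math.isinf(th) and not last:
                raise ValueError(f"layer {i}: only the last layer may be semi-infinite")
        if not (n_ambient >= 1.0):
            raise ValueError(f"n_ambient must be >= 1, got {n_ambient}")
        object.__setattr__(self, "layers", tuple((p, float(t)) for p, t in layers))
        object.__setattr__(self, "n_ambient", float(n_ambient))

    @classmethod
    def homogeneous(cls, props: OpticalProperties, n_ambient: float = 1.0) -> "LayerStack":
        """A single semi-infinite layer."""
        return cls([(props, math.inf)], n_ambient=n_ambient)

    def to_arrays(self):
        """Flatten into float64 arrays for the kernel.

        Returns (mua, mus, g, n, z_top, z_bot); ``z_bot`` of the last
        layer is +inf.
        """
        L = len(self.layers)
        mua = np.empty(L)
        mus = np.empty(L)
        g = np.empty(L)
        n = np.empty(L)
        z_top = np.empty(L)
        z_bot = np.empty(L)
        depth = 0.0
        for i, (p, th) in enumerate(self.layers):
            mua[i], mus[i], g[i], n[i] = p.mua, p.mus, p.g, p.n
            z_top[i] = depth
            depth = depth + th
            z_bot[i] = depth
        return mua, mus, g, n, z_top, z_bot

    def launch_weight(self, specular: str = SPECULAR_EXCLUDE) -> float:
        """Initial packet weight under the chosen specular convention."""
        if specular == SPECULAR_EXCLUDE:
            return 1.0
        if specular == SPECULAR_INCLUDE:
            n0 = self.layers[0][0].n
            r = (n0 - self.n_ambient) / (n0 + self.n_ambient)
            return 1.0 - r * r
        raise ValueError(f"unknown specular mode {specular!r}")

    def describe(self) -> dict:
        """JSON-serializable description (for output sidecars)."""
        return {
            "n_ambient": self.n_ambient,
            "layers": [
                {"mua": p.mua, "mus": p.mus, "g": p.g, "n": p.n,
                 "thickness_mm": (None if math.isinf(t) else t)}
                for p, t in self.layers
            ],
        }


@dataclass(frozen=True)
class DetectionEvent:
    """A packet that exited through the top surface.

    ``dx`` is the lateral x-displacement between entry and exit (mm);
    ``z_deepest`` the maximum depth visited (mm); ``exit_direction`` the
    refracted direction in the ambient medium (recorded, unused by the
    default tally).
    """

    W: float
    dx: float
    z_deepest: float
    exit_direction: tuple[float, float, float] = field(default=(0.0, 0.0, -1.0))

    def __post_init__(self):
        if not (self.W > 0.0):
            raise ValueError(f"detected weight must be > 0, got {self.W}")
        if not (self.z_deepest >= 0.0):
            raise ValueError(f"z_deepest must be >= 0, got {self.z_deepest}")


def _build_kernel(decorate):
    """Construct the propagation kernel under a decorator (njit or identity)."""

    @decorate
    def sample_step(u, mut):
        # u in (0, 1]; exponential free path with attenuation mua+mus
        return -math.log(u) / mut

    @decorate
    def sample_hg(u, g):
        # Henyey-Greenstein inverse CDF for cos(theta); isotropic at g = 0
        if g == 0.0:
            return 2.0 * u - 1.0
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        c = (1.0 + g * g - t * t) / (2.0 * g)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        return c

    @decorate
    def fresnel_reflectance(n1, n2, cos_i):
        # unpolarized average of s and p power reflectances; 1 beyond the
        # critical angle
        if n1 == n2:
            return 0.0
        s2 = 1.0 - cos_i * cos_i
        if s2 < 0.0:
            s2 = 0.0
        sin_t = n1 / n2 * math.sqrt(s2)
        if sin_t >= 1.0:
            return 1.0
        cos_t = math.sqrt(1.0 - sin_t * sin_t)
        rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
        rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
        return 0.5 * (rs * rs + rp * rp)

    @decorate
    def propagate_one(rng, mua, mus, g, n, z_top, z_bot, n_amb, w0,
                      rthresh, rsurv, traj):
        """Transport one packet; returns (status, W, x_exit, z_max,
        ux, uy, uz, n_vertices)."""
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        W = w0
        layer = 0
        zmax = 0.0
        cap = traj.shape[0]
        nv = 0
        if cap > 0:
            traj[0, 0] = x
            traj[0, 1] = y
            traj[0, 2] = z
            nv = 1
        for _ in range(_MAX_STEPS):
            mut = mua[layer] + mus[layer]
            u = 1.0 - rng.random()
            s = -math.log(u) / mut
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                db = (z_bot[layer] - z) / uz
            elif uz < 0.0:
                db = (z_top[layer] - z) / uz
            else:
                db = math.inf
            if db <= s:
                # ---- boundary hit first: move exactly onto the boundary
                x += ux * db
                y += uy * db
                going_down = uz > 0.0
                if going_down:
                    z = z_bot[layer]
                else:
                    z = z_top[layer]
                if z > zmax:
                    zmax = z
                if nv > 0 and nv < cap:
                    traj[nv, 0] = x
                    traj[nv, 1] = y
                    traj[nv, 2] = z
                    nv += 1
                n1 = n[layer]
                if going_down:
                    n2 = n[layer + 1]
                elif layer == 0:
                    n2 = n_amb
                else:
                    n2 = n[layer - 1]
                ci = -uz if uz < 0.0 else uz
                R = fresnel_reflectance(n1, n2, ci)
                if rng.random() < R:
                    uz = -uz  # specular reflection back into the layer
                else:
                    # refract (Snell); transverse components scale by n1/n2
                    s2 = 1.0 - ci * ci
                    if s2 < 0.0:
                        s2 = 0.0
                    scale = n1 / n2
                    st2 = scale * scale * s2
                    ct = math.sqrt(1.0 - st2) if st2 < 1.0 else 0.0
                    ux *= scale
                    uy *= scale
                    uz = ct if going_down else -ct
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    if (not going_down) and layer == 0:
                        # escaped through the top surface: detected
                        return STATUS_DETECTED, W, x, zmax, ux, uy, uz, nv
                    layer = layer + 1 if going_down else layer - 1
            else:
                # ---- collision inside the layer
                x += ux * s
                y += uy * s
                z += uz * s
                if z > zmax:
                    zmax = z
                if nv > 0 and nv < cap:
                    traj[nv, 0] = x
                    traj[nv, 1] = y
                    traj[nv, 2] = z
                    nv += 1
                if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
                    return STATUS_ERROR, W, x, zmax, ux, uy, uz, nv
                W *= mus[layer] / mut  # discrete absorption weighting
                if W <= 0.0:
                    return STATUS_TERMINATED, W, x, zmax, ux, uy, uz, nv
                if W < rthresh:
                    if rng.random() < rsurv:
                        W /= rsurv  # unbiased reweighting
                    else:
                        return STATUS_TERMINATED, W, x, zmax, ux, uy, uz, nv
                cost = sample_hg(rng.random(), g[layer])
                phi = _TWO_PI * rng.random()
                sint = math.sqrt(1.0 - cost * cost)
                cosp = math.cos(phi)
                sinp = math.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz > 0.0 else -cost
                else:
                    tmp = math.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
                    nuz = -sint * cosp * tmp + uz * cost
                    ux, uy, uz = nux, nuy, nuz
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
        return STATUS_ERROR, W, x, zmax, ux, uy, uz, nv

    @decorate
    def run_chunk(rng, n_packets, mua, mus, g, n, z_top, z_bot, n_amb, w0,
                  rthresh, rsurv, fx, dz, n_bins,
                  sum_re, sum_im, m2_re, m2_im, counts):
        """Propagate ``n_packets`` and tally detections into the
        spatial-frequency-domain accumulator arrays (shape
        ``[n_fx, n_bins + 1]``; last bin is depth overflow).

        Returns (n_detected, detected_weight_sum)."""
        traj = np.empty((0, 3))
        n_fx = fx.shape[0]
        n_det = 0
        wsum = 0.0
        for _ in range(n_packets):
            status, W, xf, zmax, ux, uy, uz, nv = propagate_one(
                rng, mua, mus, g, n, z_top, z_bot, n_amb, w0,
                rthresh, rsurv, traj)
            if status == STATUS_DETECTED:
                n_det += 1
                wsum += W
                b = int(zmax / dz)
                if b > n_bins:
                    b = n_bins
                for k in range(n_fx):
                    ph = -_TWO_PI * fx[k] * xf
                    re = W * math.cos(ph)
                    im = W * math.sin(ph)
                    sum_re[k, b] += re
                    sum_im[k, b] += im
                    m2_re[k, b] += re * re
                    m2_im[k, b] += im * im
                counts[b] += 1
        return n_det, wsum

    @decorate
    def collect_events(rng, n_packets, mua, mus, g, n, z_top, z_bot, n_amb,
                       w0, rthresh, rsurv, det, W_out, dx_out, zmax_out,
                       exit_dir):
        """Propagate packets and record raw detection events (test hook)."""
        traj = np.empty((0, 3))
        n_det = 0
        for i in range(n_packets):
            status, W, xf, zmax, ux, uy, uz, nv = propagate_one(
                rng, mua, mus, g, n, z_top, z_bot, n_amb, w0,
                rthresh, rsurv, traj)
            det[i] = status
            W_out[i] = W
            dx_out[i] = xf
            zmax_out[i] = zmax
            exit_dir[i, 0] = ux
            exit_dir[i, 1] = uy
            exit_dir[i, 2] = uz
            if status == STATUS_DETECTED:
                n_det += 1
        return n_det

    return {
        "sample_step": sample_step,
        "sample_hg": sample_hg,
        "fresnel_reflectance": fresnel_reflectance,
        "propagate_one": propagate_one,
        "run_chunk": run_chunk,
        "collect_events": collect_events,
    }


class _Kernel:
    """Namespace wrapper over the kernel functions."""

    def __init__(self, funcs):
        self.__dict__.update(funcs)


def _identity(f):
    return f


#: Pure-Python kernel (reference path; supports trajectory recording).
kernel_py = _Kernel(_build_kernel(_identity))

try:
    from numba import njit

    kernel = _Kernel(_build_kernel(njit(cache=False)))
except ImportError:  # pragma: no cover - numba is a hard dependency
    kernel = kernel_py


# --- thin validated wrappers over the kernel scalar functions -------------

def sample_step(u: float, mut: float) -> float:
    """Exponential free-path length s = -ln(u)/mut for u in (0, 1]."""
    if not (0.0 < u <= 1.0):
        raise ValueError(f"u must be in (0, 1], got {u}")
    if not (mut > 0.0):
        raise ValueError(f"mut must be > 0, got {mut}")
    return kernel_py.sample_step(u, mut)


def sample_hg(u: float, g: float) -> float:
    """Henyey-Greenstein cos(theta) sample from a uniform variate."""
    if not (-1.0 < g < 1.0):
        raise ValueError(f"g must be in (-1, 1), got {g}")
    return kernel_py.sample_hg(u, g)


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel power reflectance at an n1 -> n2 interface."""
    if not (n1 >= 1.0 and n2 >= 1.0):
        raise ValueError("refractive indices must be >= 1")
    if not (0.0 <= cos_incident <= 1.0):
        raise ValueError(f"cos_incident must be in [0, 1], got {cos_incident}")
    return kernel_py.fresnel_reflectance(n1, n2, cos_incident)


def propagate_packet(stack: LayerStack, rng: np.random.Generator,
                     roulette_threshold: float = 1e-4,
                     roulette_survival: float = 0.1,
                     specular: str = SPECULAR_EXCLUDE,
                     record_trajectory: bool = False,
                     trajectory_capacity: int = 200_000):
    """Propagate a single packet (pure-Python path).

    Returns ``(event_or_None, trajectory_or_None)`` where ``event`` is a
    :class:`DetectionEvent` if the packet escaped the top surface, and
    ``trajectory`` an ``(n_vertices, 3)`` array of positions when
    ``record_trajectory`` is set.  Intended for tests and oracles; use
    :func:`sfdepth.simulate.run_simulation` for production tallies.
    """
    if not (0.0 < roulette_threshold < 1.0) and roulette_threshold != 0.0:
        raise ValueError("roulette_threshold must be 0 (off) or in (0, 1)")
    if not (0.0 < roulette_survival < 1.0):
        raise ValueError("roulette_survival must be in (0, 1)")
    arrays = stack.to_arrays()
    w0 = stack.launch_weight(specular)
    traj = np.empty((trajectory_capacity if record_trajectory else 0, 3))
    status, W, xf, zmax, ux, uy, uz, nv = kernel_py.propagate_one(
        rng, *arrays, stack.n_ambient, w0,
        roulette_threshold, roulette_survival, traj)
    if status == STATUS_ERROR:
        raise RuntimeError("non-finite packet coordinates (kernel bug)")
    out_traj = traj[:nv].copy() if record_trajectory else None
    if status == STATUS_DETECTED:
        return DetectionEvent(W=W, dx=xf, z_deepest=zmax,
                              exit_direction=(ux, uy, uz)), out_traj
    return None, out_traj
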