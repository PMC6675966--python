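"""Run configuration: serializable description of a complete simulation.

A :class:`RunConfig` captures everything that determines a run's output —
medium, frequencies, depth grid, packet count, seed, roulette and specular
settings — so that a saved config plus the package version reproduces the
output bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import yaml

from .optics import OpticalProperties
from .sfd_tally import DepthGrid
from .simulate import DEFAULT_FX
from .transport import SPECULAR_EXCLUDE, LayerStack

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Fully serializable simulation specification.

    ``layers`` is a list of dicts with keys mua, mus, g, n, thickness
    (``None`` for the semi-infinite last layer).
    """

    layers: list = field(default_factory=list)
    n_ambient: float = 1.0
    fx: list = field(default_factory=lambda: list(DEFAULT_FX))
    dz: float = 0.01
    z_cap: float = 40.0
    n_packets: int = 1_000_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    specular: str = SPECULAR_EXCLUDE

    def stack(self) -> LayerStack:
        if not self.layers:
            raise ValueError("config has no layers")
        out = []
        for i, spec in enumerate(self.layers):
            try:
                props = OpticalProperties(
                    mua=float(spec["mua"]), mus=float(spec["mus"]),
                    g=float(spec.get("g", 0.8)), n=float(spec.get("n", 1.4)))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"layer {i}: {exc}") from exc
            th = spec.get("thickness")
            out.append((props, math.inf if th is None else float(th)))
        return LayerStack(out, n_ambient=self.n_ambient)

    def grid(self) -> DepthGrid:
        return DepthGrid(dz=self.dz, z_cap=self.z_cap)

    def sim_kwargs(self) -> dict:
        return dict(
            fx_list=list(self.fx), n_packets=self.n_packets, seed=self.seed,
            grid=self.grid(), roulette_threshold=self.roulette_threshold,
            roulette_survival=self.roulette_survival, specular=self.specular)

    # ---- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
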