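"""Plant parameters of the reduced activated-sludge model.

The reduced model lumps the aerated biological stage of an activated-sludge
line into a single continuously stirred tank with six states (COD, dissolved
oxygen, ammonium, nitrate, heterotrophic and autotrophic biomass).  The
parameter set follows the ASM1 / BSM1 benchmark conventions: rates in 1/day,
concentrations in g/m^3, volumes in m^3, time in days.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PlantParameters:
    """Stoichiometric, kinetic, geometric and recycle constants.

    Defaults are the standard BSM1/ASM1 values; every field can be
    overridden from a YAML/JSON config.

    Attributes
    ----------
    Yh, Ya : heterotroph / autotroph yield coefficients (gCOD biomass per
        gCOD substrate, resp. gCOD per gN), dimensionless.
    mu_h, mu_a : maximum specific growth rates, 1/day.
    K_COD, K_OH, K_NO, K_NHA, K_OA : Monod half-saturation constants, g/m^3.
    b_h, b_a : decay rates, 1/day.
    i_xb, i_xp : nitrogen content of biomass / of particulate products,
        gN/gCOD.
    f_p : fraction of biomass yielding inert products on decay.
    eta_NOg : anoxic growth correction factor.
    f_r, f_w : sludge recycle and wastage ratios (fractions of influent
        flow); the settler retains biomass so that only the fraction
        ``f_w*(1+f_r)/(f_r+f_w)`` of the hydraulic dilution acts on the
        particulate states.
    V_o : aerated reactor volume, m^3.  Default lumps the three aerated
        tanks of one treatment line (1929 + 1276 + 1409 m^3) into the
        single reactor of the reduced model.
    SO_sat : dissolved-oxygen saturation concentration, g/m^3.
    u_min, u_max : bounds on the oxygen transfer coefficient KLa, 1/day.
    """

    Yh: float = 0.67
    Ya: float = 0.24
    mu_h: float = 4.0
    mu_a: float = 0.5
    K_COD: float = 10.0
    K_OH: float = 0.2
    K_NO: float = 0.5
    K_NHA: float = 1.0
    K_OA: float = 0.4
    b_h: float = 0.3
    b_a: float = 0.05
    i_xb: float = 0.08
    i_xp: float = 0.06
    f_p: float = 0.08
    eta_NOg: float = 0.8
    f_r: float = 2.1
    f_w: float = 0.01
    V_o: float = 4614.0
    SO_sat: float = 8.0
    u_min: float = 0.0
    u_max: float = 240.0

    def __post_init__(self) -> None:
        pos = ("mu_h", "mu_a", "K_COD", "K_OH", "K_NO", "K_NHA", "K_OA",
               "b_h", "b_a", "V_o", "SO_sat", "f_r", "f_w")
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.Yh < 1:
            raise ValueError("Yh must lie in (0, 1)")
        if not 0 < self.Ya < 1:
            raise ValueError("Ya must lie in (0, 1)")
        if not 0 <= self.f_p < 1:
            raise ValueError("f_p must lie in [0, 1)")
        if not 0 < self.eta_NOg <= 1:
            raise ValueError("eta_NOg must lie in (0, 1]")
        if self.u_min < 0 or self.u_max <= self.u_min:
            raise ValueError("require 0 <= u_min < u_max")

    @property
    def washout_ratio(self) -> float:
        """Effective fraction of the dilution rate seen by biomass.

        The secondary settler returns most sludge to the reactor; only the
        wasted share leaves the system, so particulate washout is scaled by
        f_w*(1+f_r)/(f_r+f_w) < 1.
        """
        return self.f_w * (1.0 + self.f_r) / (self.f_r + self.f_w)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown plant parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
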