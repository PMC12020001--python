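"""Parameter sets for the 2D rose water model.

The model represents a water molecule as a Lennard-Jones disc carrying
three hydrogen-bonding "arms" 120 degrees apart.  A pair interaction is
the sum of a 12-6 LJ term and an orientation-dependent hydrogen-bond
term confined to a distance window around the HB length ``r_hb``.

Two parametrizations are shipped:

``mb``
    Tuned to reproduce the Mercedes-Benz water model: the LJ contact
    distance (sigma = 0.7) is distinct from the HB length (1.0).
``real``
    LJ minimum moved onto the HB length (sigma = 0.890899), stronger LJ
    well and a wider HB window, giving less exaggerated volumetric
    behaviour.

All quantities are in reduced units: energies in eps_hb, lengths in
r_hb (both equal to 1 in the shipped presets).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

__all__ = ["ModelParams", "preset", "PRESETS"]


def _rose_raw(theta, a1: float, a2: float):
    """Unnormalized 3-petal rose function.

    Petals are phased so the three global minima sit at theta = 0 and
    +-2*pi/3, i.e. along the molecule's HB arm directions in its body
    frame.  Period is 2*pi/3.
    """
    import numpy as np

    return a1 * np.cos(3.0 * theta - math.pi) + a2 * np.cos(6.0 * theta)


def _rose_amax(a1: float, a2: float) -> float:
    """Maximum magnitude of the unnormalized rose function.

    Found analytically on the critical points of
    f(c) = -a1*c + a2*(2*c**2 - 1), c = cos(3*theta) in [-1, 1].
    """
    candidates = [-1.0, 1.0]
    if a2 != 0.0:
        c = a1 / (4.0 * a2)
        if -1.0 < c < 1.0:
            candidates.append(c)
    vals = [abs(-a1 * c + a2 * (2.0 * c * c - 1.0)) for c in candidates]
    return max(vals)


@dataclass(frozen=True)
class ModelParams:
    """Full rose-potential parameter set, including derived constants.

    ``r_l``/``r_u`` are the lower/upper limits of the HB switching
    window and ``a_max`` the normalization making the orientational
    term's global minimum exactly -1; all three are derived and must not
    be supplied.
    """

    eps_lj: float
    sigma_lj: float
    eps_hb: float
    r_hb: float
    r_fwhm: float
    a1: float
    a2: float
    lj_cutoff: float = dataclasses.field(default=0.0)
    r_l: float = dataclasses.field(init=False)
    r_u: float = dataclasses.field(init=False)
    a_max: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if self.eps_lj < 0 or self.eps_hb < 0:
            raise ValueError("energies must be non-negative")
        if self.sigma_lj <= 0 or self.r_hb <= 0 or self.r_fwhm <= 0:
            raise ValueError("lengths must be positive")
        object.__setattr__(self, "r_l", self.r_hb - self.r_fwhm)
        object.__setattr__(self, "r_u", self.r_hb + self.r_fwhm)
        object.__setattr__(self, "a_max", _rose_amax(self.a1, self.a2))
        if self.lj_cutoff <= 0.0:
            object.__setattr__(self, "lj_cutoff", 4.0 * self.sigma_lj)

    @property
    def cutoff(self) -> float:
        """Largest interaction range (LJ cutoff vs upper HB limit)."""
        return max(self.lj_cutoff, self.r_u)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "eps_lj": self.eps_lj,
            "sigma_lj": self.sigma_lj,
            "eps_hb": self.eps_hb,
            "r_hb": self.r_hb,
            "r_fwhm": self.r_fwhm,
            "a1": self.a1,
            "a2": self.a2,
            "lj_cutoff": self.lj_cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_toml(self, path: str | Path) -> None:
        lines = [f"{k} = {v!r}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ModelParams":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


PRESETS: dict[str, dict] = {
    "mb": dict(eps_lj=0.1, sigma_lj=0.7, eps_hb=1.0, r_hb=1.0,
               r_fwhm=0.2, a1=0.6, a2=-0.4),
    "real": dict(eps_lj=0.2, sigma_lj=0.890899, eps_hb=1.0, r_hb=1.0,
                 r_fwhm=0.41666, a1=0.6, a2=-0.4),
}


def preset(name: str) -> ModelParams:
    """Return a shipped parametrization, ``"mb"`` or ``"real"``."""
    try:
        return ModelParams(**PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
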