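"""The rose pair potential.

A pair of molecules interacts through

    u(r, theta_i, theta_j) = u_LJ(r) + u_HB(r, theta_ij) + u_HB(r, theta_ji)

where ``theta_ij`` is the orientation angle of the center-connecting
vector in molecule i's body frame.  Each molecule contributes its own
HB half independently of the partner's orientation ("half" hydrogen
bonds are possible); the per-molecule contribution is scaled so that a
fully aligned bond at r = r_hb totals exactly -eps_hb and one favorably
oriented molecule alone contributes -eps_hb/2.

The orientational term is the a_max-normalized 3-petal rose function

    U(theta) = (a1*cos(3*theta - pi) + a2*cos(6*theta)) / a_max

with period 2*pi/3 and global minimum exactly -1 along the three arm
directions (0, +-120 degrees in the body frame).  The distance term is
a double-sided cubic switching function: two mirrored smoothstep cubics
meeting with value 1 and zero slope at r_hb, falling to 0 with zero
slope at r_l = r_hb - r_fwhm and r_u = r_hb + r_fwhm; it passes through
1/2 at r_hb +- r_fwhm/2, so r_fwhm is the full width at half maximum.

The LJ term is truncated with cut-and-shift at ``lj_cutoff`` so the
total potential is continuous (and once differentiable away from r=0),
which keeps NVE energy conservation clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "PairGeometry",
    "lj_energy",
    "lj_energy_d",
    "rose_orientational",
    "rose_orientational_d",
    "switching",
    "switching_d",
    "hb_half_energy",
    "hb_pair_energy",
    "pair_energy",
]


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of a pair as seen from one molecule's body frame.

    ``dx``/``dy`` are the components of the vector to the partner in
    the observer's body frame; ``r`` and ``theta`` are its polar form.
    """

    dx: float
    dy: float

    @property
    def r(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def theta(self) -> float:
        return math.atan2(self.dy, self.dx)

    @classmethod
    def from_global(cls, delta_x: float, delta_y: float,
                    orientation: float) -> "PairGeometry":
        """Rotate a lab-frame connecting vector into the body frame of a
        molecule with the given orientation angle."""
        c, s = math.cos(orientation), math.sin(orientation)
        return cls(c * delta_x + s * delta_y, -s * delta_x + c * delta_y)


# -- Lennard-Jones ----------------------------------------------------

def _lj_raw(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def lj_energy(r, params: ModelParams):
    """Cut-and-shifted 12-6 LJ energy. ``r`` may be an array."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ energy undefined for r <= 0")
    shift = _lj_raw(params.lj_cutoff, params.eps_lj, params.sigma_lj)
    u = np.where(r < params.lj_cutoff,
                 _lj_raw(np.minimum(r, params.lj_cutoff), params.eps_lj,
                         params.sigma_lj) - shift,
                 0.0)
    return u if u.ndim else float(u)


def lj_energy_d(r, params: ModelParams):
    """d(lj_energy)/dr."""
    r = np.asarray(r, dtype=float)
    sr6 = (params.sigma_lj / r) ** 6
    d = 4.0 * params.eps_lj * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    d = np.where(r < params.lj_cutoff, d, 0.0)
    return d if d.ndim else float(d)


# -- rose orientational term ------------------------------------------

def rose_orientational(theta, params: ModelParams):
    """Normalized 3-petal rose value; global minimum is exactly -1."""
    theta = np.asarray(theta, dtype=float)
    v = (params.a1 * np.cos(3.0 * theta - math.pi)
         + params.a2 * np.cos(6.0 * theta)) / params.a_max
    return v if v.ndim else float(v)


def rose_orientational_d(theta, params: ModelParams):
    """d(rose_orientational)/dtheta."""
    theta = np.asarray(theta, dtype=float)
    v = (-3.0 * params.a1 * np.sin(3.0 * theta - math.pi)
         - 6.0 * params.a2 * np.sin(6.0 * theta)) / params.a_max
    return v if v.ndim else float(v)


# -- switching function -----------------------------------------------

def switching(r, params: ModelParams):
    """Double-sided cubic switching window on [r_l, r_u], peak 1 at r_hb."""
    r = np.asarray(r, dtype=float)
    t = np.clip(1.0 - np.abs(r - params.r_hb) / params.r_fwhm, 0.0, 1.0)
    s = t * t * (3.0 - 2.0 * t)
    return s if s.ndim else float(s)


def switching_d(r, params: ModelParams):
    """d(switching)/dr (zero at and outside the window limits)."""
    r = np.asarray(r, dtype=float)
    x = (r - params.r_hb) / params.r_fwhm
    t = 1.0 - np.abs(x)
    inside = t > 0.0
    tt = np.where(inside, t, 0.0)
    ds = 6.0 * tt * (1.0 - tt) * (-np.sign(x)) / params.r_fwhm
    ds = np.where(inside, ds, 0.0)
    return ds if ds.ndim else float(ds)


# -- hydrogen bond ----------------------------------------------------

def hb_half_energy(r, theta, params: ModelParams):
    """One molecule's contribution to the HB pair energy.

    Equals (eps_hb/2) * U(theta) * s(r): at the optimum -eps_hb/2,
    independent of the partner's orientation.
    """
    return 0.5 * params.eps_hb * rose_orientational(theta, params) \
        * switching(r, params)


def hb_pair_energy(geom_ij: PairGeometry, geom_ji: PairGeometry,
                   params: ModelParams) -> float:
    """Total HB energy of a pair: sum of the two half contributions.

    The two geometries must describe the same physical pair (equal
    center-center distances).
    """
    r1, r2 = geom_ij.r, geom_ji.r
    if abs(r1 - r2) > 1e-9 * max(1.0, r1):
        raise ValueError("geometries describe different distances "
                         f"({r1} vs {r2})")
    return float(hb_half_energy(r1, geom_ij.theta, params)
                 + hb_half_energy(r2, geom_ji.theta, params))


def pair_energy(delta_x: float, delta_y: float, phi_i: float, phi_j: float,
                params: ModelParams, split: bool = False):
    """Full pair energy from a minimum-imaged lab-frame displacement.

    ``delta`` points from molecule i to molecule j; ``phi`` are the
    molecular orientation angles.  With ``split=True`` returns
    ``(lj, hb)`` so HB statistics can reuse the decomposition.
    """
    r = math.hypot(delta_x, delta_y)
    if r == 0.0:
        raise ValueError("overlapping centers")
    u_lj = lj_energy(r, params)
    if params.r_l < r < params.r_u:
        g_ij = PairGeometry.from_global(delta_x, delta_y, phi_i)
        g_ji = PairGeometry.from_global(-delta_x, -delta_y, phi_j)
        u_hb = hb_pair_energy(g_ij, g_ji, params)
    else:
        u_hb = 0.0
    if split:
        return float(u_lj), float(u_hb)
    return float(u_lj) + float(u_hb)
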