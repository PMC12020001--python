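"""Exact-geometry fixture configurations.

Ideal lattices and random gases used by tests and by the grid runner's
cold-start option:

* honeycomb hydrogen-bond network - every molecule has exactly three
  neighbors at the bond length and its three arms point at them.  The
  two sublattices are rotated 60 degrees against each other (the A
  sublattice has arms at 0/120/240 degrees, B at 60/180/300).
* triangular close packing (hexagonal dense packing, 6 neighbors).
* uniform random gas with a minimum-separation constraint.
"""

from __future__ import annotations

import math

import numpy as np

from .forces import minimum_image
from .md import Configuration, PackingError

__all__ = ["make_honeycomb", "make_triangular", "make_gas"]


def make_honeycomb(n_cells: int, bond_length: float = 1.0) -> Configuration:
    """Periodic honeycomb network of ``n_cells x n_cells`` rectangular
    cells (4 molecules each), arm-aligned orientations."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    a = bond_length
    cell = np.array([3.0 * a, math.sqrt(3.0) * a])
    # A-sublattice arms at 0 deg, B-sublattice arms at 60 deg
    basis = [
        ((0.0, 0.0), 0.0),
        ((a, 0.0), math.pi / 3.0),
        ((1.5 * a, 0.5 * math.sqrt(3.0) * a), 0.0),
        ((2.5 * a, 0.5 * math.sqrt(3.0) * a), math.pi / 3.0),
    ]
    pos, phi = [], []
    for ix in range(n_cells):
        for iy in range(n_cells):
            shift = np.array([ix, iy]) * cell
            for (bx, by), ang in basis:
                pos.append(shift + (bx, by))
                phi.append(ang)
    return Configuration(np.array(pos), np.array(phi), cell * n_cells)


def make_triangular(n_cells: int, spacing: float = 0.7) -> Configuration:
    """Periodic triangular close packing, ``n_cells x n_cells``
    rectangular cells of 2 molecules; density 2/(sqrt(3)*spacing^2)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    a = spacing
    cell = np.array([a, math.sqrt(3.0) * a])
    basis = [(0.0, 0.0), (0.5 * a, 0.5 * math.sqrt(3.0) * a)]
    pos = []
    for ix in range(n_cells):
        for iy in range(n_cells):
            shift = np.array([ix, iy]) * cell
            for b in basis:
                pos.append(shift + b)
    pos = np.array(pos)
    return Configuration(pos, np.zeros(len(pos)), cell * n_cells)


def make_gas(n: int, box, min_sep: float, seed: int,
             max_tries: int = 2000) -> Configuration:
    """Uniform random configuration with a hard minimum separation."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    pts = np.empty((n, 2))
    placed = 0
    for _ in range(max_tries * n):
        cand = rng.random(2) * box
        if placed:
            d = minimum_image(pts[:placed] - cand, box)
            if np.min(np.hypot(d[:, 0], d[:, 1])) < min_sep:
                continue
        pts[placed] = cand
        placed += 1
        if placed == n:
            break
    else:
        raise PackingError(f"placed {placed}/{n} at min_sep {min_sep}")
    return Configuration(pts, rng.random(n) * 2.0 * math.pi, box)
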