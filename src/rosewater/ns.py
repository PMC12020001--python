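"""Constant-pressure nested sampling and partition-function thermodynamics.

Nested sampling builds a decreasing sequence of configurational
enthalpy levels H_i (H = U + pV).  The configuration-space volume
enclosed by level i shrinks geometrically,

    chi_i = chi_0 * (K / (K + 1))**i,

where K is the live-set size.  One run yields the constant-pressure
partition function - and hence <H>(T), C_p(T), kappa_T(T), alpha_P(T)
- at every temperature, because the level sequence is temperature
independent.  The kinetic prefactor of the partition function (Planck
constant, mass) only adds a T-dependent constant to log Z that cancels
in all response functions and is therefore dropped.

Sampling measure: positions are stored as fractional coordinates of an
isotropically rescalable square cell; the cell area V carries the
Jacobian weight V^N, imposed through the volume-move acceptance
min(1, (V'/V)^(N+1)) in ln V.  New live points are generated by
cloning a random survivor and random-walking it (L*N single-particle
translation+rotation sub-steps and L volume attempts) under the hard
constraint H < H_lim.  Walk step sizes are auto-tuned toward ~50%
acceptance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .forces import evaluate, minimum_image
from .params import ModelParams

__all__ = ["NSConfig", "NSRun", "ThermoCurve", "ns_sample",
           "partition_thermo", "enthalpy_error_estimate", "find_extrema"]


@dataclass
class NSConfig:
    """Run parameters; defaults are the production values."""

    n_particles: int = 32
    K: int = 500
    L: int = 5000
    n_iter: int = 500_000
    pressure: float = 0.1
    V0: float = 0.0      # 0 -> 100 * N * r_hb^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("live-set size K must be >= 2")
        if self.L < 1 or self.n_iter < 1 or self.n_particles < 1:
            raise ValueError("counts must be positive")
        if self.V0 <= 0.0:
            self.V0 = 100.0 * self.n_particles

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_particles", "K", "L", "n_iter", "pressure", "V0", "seed")}


@dataclass
class NSRun:
    """Decreasing enthalpy levels with their log phase-space volumes."""

    enthalpy_levels: np.ndarray
    volumes: np.ndarray          # cell area at each removed level
    pressure: float
    meta: NSConfig
    stats: dict = field(default_factory=dict)

    @property
    def log_volumes(self) -> np.ndarray:
        i = np.arange(1, len(self.enthalpy_levels) + 1)
        return i * math.log(self.meta.K / (self.meta.K + 1))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "i": np.arange(1, len(self.enthalpy_levels) + 1),
            "H": self.enthalpy_levels,
            "V": self.volumes,
            "log_chi": self.log_volumes,
        }).to_csv(path, index=False)
        Path(str(path) + ".json").write_text(
            json.dumps(self.meta.to_dict(), indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "NSRun":
        import pandas as pd

        df = pd.read_csv(path)
        meta = NSConfig(**json.loads(Path(str(path) + ".json").read_text()))
        return cls(df["H"].to_numpy(), df["V"].to_numpy(),
                   meta.pressure, meta)


@dataclass
class ThermoCurve:
    temperatures: np.ndarray
    values: np.ndarray
    quantity: str
    truncated: np.ndarray = None   # bool mask: T below resolvable range

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.values):
            raise ValueError("grid length mismatch")
        if self.truncated is None:
            self.truncated = np.zeros(len(self.values), dtype=bool)


# -- sampling ---------------------------------------------------------

def _particle_energy(pos, phi, box, i, p: ModelParams):
    """Sum of full pair energies involving particle i (O(N))."""
    d = minimum_image(np.delete(pos, i, axis=0) - pos[i], box)
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r <= 1e-12):
        return np.inf
    # LJ, cut and shift
    shift = 4.0 * p.eps_lj * ((p.sigma_lj / p.lj_cutoff) ** 12
                              - (p.sigma_lj / p.lj_cutoff) ** 6)
    sr6 = np.where(r < p.lj_cutoff, (p.sigma_lj / r) ** 6, 0.0)
    u = np.where(r < p.lj_cutoff,
                 4.0 * p.eps_lj * (sr6 * sr6 - sr6) - shift, 0.0)
    # HB halves of both molecules of each pair
    win = (r > p.r_l) & (r < p.r_u)
    if np.any(win):
        others = np.delete(phi, i)
        alpha = np.arctan2(d[:, 1], d[:, 0])
        th_i = alpha - phi[i]
        th_j = alpha + math.pi - others
        t = 1.0 - np.abs(r - p.r_hb) / p.r_fwhm
        t = np.clip(t, 0.0, 1.0)
        s = t * t * (3.0 - 2.0 * t)

        def rose(th):
            return (p.a1 * np.cos(3.0 * th - math.pi)
                    + p.a2 * np.cos(6.0 * th)) / p.a_max

        u = u + np.where(win, 0.5 * p.eps_hb * s * (rose(th_i) + rose(th_j)),
                         0.0)
    return float(np.sum(u))


def _total_energy(frac, phi, V, params: ModelParams | None) -> float:
    if params is None:
        return 0.0
    L = math.sqrt(V)
    box = np.array([L, L])
    return evaluate(frac * L, phi, box, params)["energy"]


def ns_sample(cfg: NSConfig, params: ModelParams | None,
              progress: bool = False) -> NSRun:
    """Run constant-pressure nested sampling.

    ``params=None`` disables interactions (ideal gas), used by the
    closed-form oracle tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n, K, p = cfg.n_particles, cfg.K, cfg.pressure

    # initial live set: V ~ V^N dV on (0, V0], positions uniform
    vols = cfg.V0 * rng.random(K) ** (1.0 / (n + 1))
    fracs = rng.random((K, n, 2))
    phis = rng.random((K, n)) * 2.0 * math.pi
    pots = np.array([_total_energy(fracs[k], phis[k], vols[k], params)
                     for k in range(K)])
    enthalpies = pots + p * vols

    step_xy = 0.3     # fractional-coordinate displacement scale
    step_phi = 1.0
    step_lnv = 0.3
    acc_hist, att_hist = 0, 0

    levels = np.empty(cfg.n_iter)
    level_vols = np.empty(cfg.n_iter)
    stall = 0
    for it in range(cfg.n_iter):
        worst = int(np.argmax(enthalpies))
        h_lim = float(enthalpies[worst])
        levels[it] = h_lim
        level_vols[it] = vols[worst]

        # clone a random survivor
        choices = [k for k in (rng.integers(K), rng.integers(K))
                   if k != worst]
        src = choices[0] if choices else (worst + 1) % K
        frac = fracs[src].copy()
        phi = phis[src].copy()
        V = float(vols[src])
        U = float(pots[src])

        acc = att = 0
        for _ in range(cfg.L):
            # one volume attempt per walk step
            att += 1
            lnv_new = math.log(V) + step_lnv * (2.0 * rng.random() - 1.0)
            V_new = math.exp(lnv_new)
            if V_new <= cfg.V0 and \
                    rng.random() < min(1.0, (V_new / V) ** (n + 1)):
                U_new = _total_energy(frac, phi, V_new, params)
                if U_new + p * V_new < h_lim:
                    V, U = V_new, U_new
                    acc += 1
            # N single-particle translation+rotation sub-steps
            L_side = math.sqrt(V)
            box = np.array([L_side, L_side])
            pos = frac * L_side
            for _ in range(n):
                att += 1
                i = int(rng.integers(n))
                if params is not None:
                    u_old = _particle_energy(pos, phi, box, i, params)
                old_pos = pos[i].copy()
                old_phi = phi[i]
                pos[i] = np.mod(pos[i] + step_xy * L_side
                                * (2.0 * rng.random(2) - 1.0), box)
                phi[i] = old_phi + step_phi * (2.0 * rng.random() - 1.0)
                if params is None:
                    acc += 1
                    continue
                u_new = _particle_energy(pos, phi, box, i, params)
                if U + (u_new - u_old) + p * V < h_lim:
                    U += u_new - u_old
                    acc += 1
                else:
                    pos[i] = old_pos
                    phi[i] = old_phi
            frac = pos / L_side

        # auto-tune toward ~50% acceptance
        acc_hist += acc
        att_hist += att
        if att_hist >= 2000:
            ratio = acc_hist / att_hist
            f = 1.1 if ratio > 0.5 else 1.0 / 1.1
            step_xy = min(0.5, max(1e-5, step_xy * f))
            step_phi = min(math.pi, max(1e-5, step_phi * f))
            step_lnv = min(1.0, max(1e-6, step_lnv * f))
            acc_hist = att_hist = 0
        if acc == 0:
            stall += 1

        fracs[worst] = frac
        phis[worst] = phi
        vols[worst] = V
        pots[worst] = U
        enthalpies[worst] = U + p * V
        if progress and it % 1000 == 0:
            print(f"NS iter {it}: H_lim = {h_lim:.4f}")

    stats = {"stalled_iterations": int(stall),
             "final_steps": [step_xy, step_phi, step_lnv]}
    if stall:
        stats["warning"] = "some walks accepted no moves"
    return NSRun(levels, level_vols, p, cfg, stats)


# -- thermodynamics ---------------------------------------------------

def _log_weights(run: NSRun, T: float):
    """log[(chi_{i-1} - chi_{i+1})/2 * exp(-H_i/T)], trapezoid widths."""
    log_chi = run.log_volumes
    n = len(log_chi)
    lo = np.concatenate([[0.0], log_chi[:-1]])        # chi_{i-1}, chi_0 = 1
    hi = np.concatenate([log_chi[1:], [-np.inf]])     # chi_{i+1}
    # log((exp(lo) - exp(hi))/2), lo > hi always
    log_width = lo + np.log1p(-np.exp(np.minimum(hi - lo, -1e-12))) \
        - math.log(2.0)
    return log_width - run.enthalpy_levels / T, n


def partition_thermo(run: NSRun, T_grid) -> dict[str, ThermoCurve]:
    """Ensemble averages on a temperature grid from one NS run.

    Returns curves for <H>, C_p (configurational variance plus the
    dof/2 kinetic term, dof = 3N), kappa_T and alpha_P.  Temperatures
    where more than half the weight sits on the last recorded level are
    flagged as truncated (the run did not cool far enough).
    """
    T_grid = np.asarray(T_grid, float)
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    if len(run.enthalpy_levels) < 2:
        raise ValueError("empty or degenerate NS run")
    H = run.enthalpy_levels
    V = run.volumes
    n_mol = run.meta.n_particles
    dof = 3 * n_mol

    means = {k: np.empty(len(T_grid)) for k in
             ("H", "H2", "V", "V2", "VH")}
    truncated = np.zeros(len(T_grid), dtype=bool)
    for t_i, T in enumerate(T_grid):
        lw, _ = _log_weights(run, T)
        lz = logsumexp(lw)
        w = np.exp(lw - lz)
        truncated[t_i] = w[-1] > 0.5
        means["H"][t_i] = np.dot(w, H)
        means["H2"][t_i] = np.dot(w, H * H)
        means["V"][t_i] = np.dot(w, V)
        means["V2"][t_i] = np.dot(w, V * V)
        means["VH"][t_i] = np.dot(w, V * H)

    var_h = np.maximum(means["H2"] - means["H"] ** 2, 0.0)
    var_v = np.maximum(means["V2"] - means["V"] ** 2, 0.0)
    cov_vh = means["VH"] - means["V"] * means["H"]
    curves = {
        "enthalpy": ThermoCurve(T_grid, means["H"] + 0.5 * dof * T_grid,
                                "enthalpy", truncated),
        "heat_capacity": ThermoCurve(
            T_grid, var_h / T_grid ** 2 + 0.5 * dof, "heat_capacity",
            truncated),
        "kappa_T": ThermoCurve(T_grid, var_v / (T_grid * means["V"]),
                               "kappa_T", truncated),
        "alpha_P": ThermoCurve(T_grid, cov_vh / (T_grid ** 2 * means["V"]),
                               "alpha_P", truncated),
        "conf_enthalpy": ThermoCurve(T_grid, means["H"], "conf_enthalpy",
                                     truncated),
    }
    return curves


def enthalpy_error_estimate(run: NSRun, T_grid, n_resample: int = 30,
                            seed: int = 0) -> np.ndarray:
    """NS statistical error of <H>(T) (configurational part).

    Resamples the stochastic level compressions t_j ~ Beta(K, 1)
    (log t_j = log(u)/K) and reports the standard deviation of the
    reweighted <H> over the resamples.
    """
    rng = np.random.default_rng(seed)
    T_grid = np.asarray(T_grid, float)
    H = run.enthalpy_levels
    K = run.meta.K
    n = len(H)
    out = np.empty((n_resample, len(T_grid)))
    for m in range(n_resample):
        log_t = np.log(rng.random(n)) / K
        log_chi = np.cumsum(log_t)
        lo = np.concatenate([[0.0], log_chi[:-1]])
        hi = np.concatenate([log_chi[1:], [-np.inf]])
        log_width = lo + np.log1p(-np.exp(np.minimum(hi - lo, -1e-12))) \
            - math.log(2.0)
        for t_i, T in enumerate(T_grid):
            lw = log_width - H / T
            w = np.exp(lw - logsumexp(lw))
            out[m, t_i] = np.dot(w, H)
    return out.std(axis=0)


def find_extrema(curve: ThermoCurve, prominence_floor: float = 0.0):
    """Interior local maxima of a thermodynamic response curve.

    Returns a list of (T_at_maximum, prominence) sorted by T; these are
    the candidate phase-transition temperatures.
    """
    if len(curve.values) < 5:
        raise ValueError("need at least 5 grid points")
    peaks, props = find_peaks(curve.values, prominence=prominence_floor
                              if prominence_floor > 0 else None)
    proms = props.get("prominences")
    if proms is None:
        from scipy.signal import peak_prominences

        proms = peak_prominences(curve.values, peaks)[0]
    out = [(float(curve.temperatures[i]), float(pr))
           for i, pr in zip(peaks, proms)]
    out.sort(key=lambda x: x[0])
    return out
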