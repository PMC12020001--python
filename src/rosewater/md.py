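"""NPT molecular dynamics for 2D translating-rotating rose molecules.

Velocity Verlet for both translation and rotation, velocity-rescale /
stochastic-velocity-rescale (Bussi) thermostats, Berendsen /
stochastic-cell-rescale barostats, rectangular periodic box with the
minimum-image convention.

Defaults mirror the production protocol: time step 0.001, 100,000
equilibration steps, 20 sampling series of 100,000 steps, 200
molecules, thermostat coupling 0.01 and barostat coupling 0.1 (reduced
time units).  Mass is 1; the moment of inertia defaults to
m*r_hb^2/4 = 0.25 - it only sets the rotational timescale, not any
equilibrium average.

Temperature convention: rotational degrees of freedom are thermostated
together with translation, dof = 3N - 2 (center-of-mass momentum is
removed at initialization and conserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forces import evaluate, minimum_image
from .params import ModelParams

__all__ = [
    "Configuration", "MDState", "MDProtocol", "Trajectory", "PackingError",
    "make_initial_configuration", "initialize_velocities", "vv_step",
    "apply_thermostat",
    "apply_barostat", "virial_pressure", "run_npt",
]


class PackingError(RuntimeError):
    """Raised when random insertion cannot place all molecules."""


class IntegrationError(RuntimeError):
    """Raised on non-finite forces (overlap blow-up)."""


@dataclass
class Configuration:
    """2D positions, one orientation angle per molecule, periodic box."""

    positions: np.ndarray   # (N, 2)
    orientations: np.ndarray  # (N,)
    box: np.ndarray         # (2,)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.orientations = np.atleast_1d(np.asarray(self.orientations, float))
        self.box = np.asarray(self.box, float)
        if len(self.positions) < 1:
            raise ValueError("need at least one molecule")
        self.wrap()

    @property
    def n_molecules(self) -> int:
        return len(self.positions)

    @property
    def area(self) -> float:
        return float(self.box[0] * self.box[1])

    @property
    def density(self) -> float:
        return self.n_molecules / self.area

    def wrap(self) -> None:
        self.positions = np.mod(self.positions, self.box)

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.orientations.copy(),
                             self.box.copy())


@dataclass
class MDState:
    config: Configuration
    velocities: np.ndarray          # (N, 2)
    angular_velocities: np.ndarray  # (N,)
    mass: float = 1.0
    moment_of_inertia: float = 0.25
    time: float = 0.0
    unwrapped: np.ndarray = field(default=None)  # (N, 2), for MSD

    def __post_init__(self) -> None:
        if self.unwrapped is None:
            self.unwrapped = self.config.positions.copy()

    @property
    def kinetic_energy(self) -> float:
        ke_t = 0.5 * self.mass * float(np.sum(self.velocities ** 2))
        ke_r = 0.5 * self.moment_of_inertia * float(
            np.sum(self.angular_velocities ** 2))
        return ke_t + ke_r

    @property
    def translational_kinetic_energy(self) -> float:
        return 0.5 * self.mass * float(np.sum(self.velocities ** 2))

    @property
    def dof(self) -> int:
        n = self.config.n_molecules
        return max(3 * n - 2, 1)

    @property
    def kinetic_temperature(self) -> float:
        return 2.0 * self.kinetic_energy / self.dof

    def copy(self) -> "MDState":
        return MDState(self.config.copy(), self.velocities.copy(),
                       self.angular_velocities.copy(), self.mass,
                       self.moment_of_inertia, self.time,
                       self.unwrapped.copy())


@dataclass
class MDProtocol:
    """Run lengths, couplings and seeds for one NPT simulation."""

    dt: float = 0.001
    n_equil: int = 100_000
    n_series: int = 20
    series_len: int = 100_000
    thermostat: str = "stochastic_rescale"
    barostat: str = "stochastic_cell_rescale"
    tau_T: float = 0.01
    tau_P: float = 0.1
    seed: int = 0
    n_molecules: int = 200
    sample_every: int = 10
    frame_every: int = 200

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("n_equil", "n_series", "series_len", "n_molecules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Sampled output of one NPT run.

    ``frames`` hold wrapped configurations; ``unwrapped`` the
    continuous (periodic-image-free) positions for MSD; per-sample
    scalar series carry enthalpy, area, kinetic temperature and virial
    pressure, each tagged with its sampling block.
    """

    frames: list                    # list[Configuration]
    unwrapped: np.ndarray           # (F, N, 2)
    frame_times: np.ndarray
    samples: dict                   # name -> (S,) array
    sample_block: np.ndarray        # (S,) int block index
    n_series: int
    dt_sample: float
    final_state: MDState = None


# -- setup ------------------------------------------------------------

def make_initial_configuration(n: int, density_guess: float, seed: int,
                               min_sep: float = 0.595,
                               max_tries: int = 2000) -> Configuration:
    """Random non-overlapping configuration in a square box.

    ``min_sep`` defaults to 0.85*sigma_lj of the MB parametrization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    side = math.sqrt(n / density_guess)
    box = np.array([side, side])
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
        raise PackingError(
            f"could only place {placed}/{n} molecules at density "
            f"{density_guess} with min separation {min_sep}")
    phi = rng.random(n) * 2.0 * math.pi
    return Configuration(pts, phi, box)


def initialize_velocities(state: MDState, T: float, rng) -> None:
    """Maxwell-Boltzmann draw with the COM momentum removed."""
    n = state.config.n_molecules
    v = rng.normal(0.0, math.sqrt(T / state.mass), size=(n, 2))
    v -= v.mean(axis=0)
    w = rng.normal(0.0, math.sqrt(T / state.moment_of_inertia), size=n)
    state.velocities = v
    state.angular_velocities = w


# -- integration ------------------------------------------------------

def _forces(state: MDState, params: ModelParams | None):
    if params is None:
        n = state.config.n_molecules
        return {"energy": 0.0, "forces": np.zeros((n, 2)),
                "torques": np.zeros(n), "virial": 0.0}
    return evaluate(state.config.positions, state.config.orientations,
                    state.config.box, params)


def vv_step(state: MDState, params: ModelParams | None, dt: float,
            cache: dict | None = None) -> dict:
    """One velocity-Verlet step, in place; returns the new force table.

    ``cache`` is the force table of the current positions (recomputed
    when omitted), so consecutive steps cost one force evaluation.
    """
    ft = cache if cache is not None else _forces(state, params)
    if not np.all(np.isfinite(ft["forces"])):
        raise IntegrationError("non-finite forces (overlapping molecules?)")
    inv_m = 1.0 / state.mass
    inv_i = 1.0 / state.moment_of_inertia
    state.velocities += 0.5 * dt * ft["forces"] * inv_m
    state.angular_velocities += 0.5 * dt * ft["torques"] * inv_i
    disp = dt * state.velocities
    state.config.positions += disp
    state.unwrapped += disp
    state.config.wrap()
    state.config.orientations = np.mod(
        state.config.orientations + dt * state.angular_velocities,
        2.0 * math.pi)
    ft = _forces(state, params)
    state.velocities += 0.5 * dt * ft["forces"] * inv_m
    state.angular_velocities += 0.5 * dt * ft["torques"] * inv_i
    state.time += dt
    return ft


# -- thermostats ------------------------------------------------------

def apply_thermostat(state: MDState, target_T: float, mode: str,
                     tau: float, dt: float = 0.0, rng=None) -> None:
    """Rescale (exact) or Bussi stochastic-rescale thermostat, in place."""
    if target_T <= 0:
        raise ValueError("target temperature must be positive")
    kin = state.kinetic_energy
    if kin <= 0.0:
        return  # nothing to rescale
    dof = state.dof
    if mode == "rescale":
        lam = math.sqrt(target_T * dof / (2.0 * kin))
        state.velocities *= lam
        state.angular_velocities *= lam
    elif mode == "stochastic_rescale":
        if rng is None:
            raise ValueError("stochastic thermostat needs an rng")
        kbar = 0.5 * dof * target_T
        c = math.exp(-dt / tau) if math.isfinite(tau) else 1.0
        r1 = rng.normal()
        rest = rng.chisquare(dof - 1) if dof > 1 else 0.0
        alpha2 = (c + (1.0 - c) * kbar / (dof * kin) * (r1 * r1 + rest)
                  + 2.0 * r1 * math.sqrt(c * (1.0 - c) * kbar / (dof * kin)))
        lam = math.sqrt(max(alpha2, 0.0))
        state.velocities *= lam
        state.angular_velocities *= lam
    else:
        raise ValueError(f"unknown thermostat mode {mode!r}")


# -- barostats --------------------------------------------------------

def virial_pressure(state: MDState, params: ModelParams | None,
                    cache: dict | None = None) -> float:
    """Instantaneous 2D virial pressure p = (2*K_trans + W) / (2*A)."""
    ft = cache if cache is not None else _forces(state, params)
    return (2.0 * state.translational_kinetic_energy + ft["virial"]) \
        / (2.0 * state.config.area)


def _rescale_cell(state: MDState, lin: float) -> None:
    state.config.box *= lin
    state.config.positions *= lin
    state.unwrapped *= lin
    state.config.wrap()


def apply_barostat(state: MDState, target_p: float, mode: str, tau: float,
                   dt: float, params: ModelParams | None,
                   rng=None, cache: dict | None = None,
                   target_T: float | None = None) -> None:
    """Berendsen or stochastic-cell-rescale barostat, in place.

    Isotropic rescaling of box, positions and unwrapped positions.
    The compressibility parameter is fixed at 1 in reduced units.
    """
    if target_p <= 0:
        raise ValueError("target pressure must be positive")
    p_inst = virial_pressure(state, params, cache)
    if mode == "berendsen":
        scale_a = 1.0 + (dt / tau) * (p_inst - target_p)
    elif mode == "stochastic_cell_rescale":
        if rng is None:
            raise ValueError("stochastic barostat needs an rng")
        T = target_T if target_T is not None else state.kinetic_temperature
        area = state.config.area
        deps = (-(dt / tau) * (target_p - p_inst)
                + math.sqrt(2.0 * T * dt / (area * tau)) * rng.normal())
        scale_a = math.exp(deps)
    else:
        raise ValueError(f"unknown barostat mode {mode!r}")
    if scale_a <= 0.0:
        return  # reject unphysical proposal
    _rescale_cell(state, math.sqrt(scale_a))


# -- production loop --------------------------------------------------

def run_npt(protocol: MDProtocol, params: ModelParams | None, T: float,
            p: float, initial: Configuration | None = None,
            density_guess: float | None = None) -> Trajectory:
    """Equilibrate then sample one (T*, p*) phase point.

    Equilibration uses the exact velocity rescale + Berendsen barostat;
    sampling switches to the stochastic velocity rescale and the
    stochastic cell rescale so the run targets the true NPT ensemble.
    """
    rng = np.random.default_rng(protocol.seed)
    if initial is None:
        if density_guess is None:
            density_guess = suggest_density(T, p)
        initial = make_initial_configuration(
            protocol.n_molecules, density_guess,
            seed=int(rng.integers(2 ** 31)))
    state = MDState(initial.copy(), np.zeros((initial.n_molecules, 2)),
                    np.zeros(initial.n_molecules))
    initialize_velocities(state, T, rng)
    dt = protocol.dt

    cache = _forces(state, params)
    for _ in range(protocol.n_equil):
        cache = vv_step(state, params, dt, cache)
        apply_thermostat(state, T, "rescale", protocol.tau_T)
        apply_barostat(state, p, "berendsen", protocol.tau_P, dt, params,
                       cache=cache)
        cache = None  # box changed; force cache invalid

    frames, unwrapped, frame_times = [], [], []
    names = ("enthalpy", "area", "kinetic_T", "pressure", "potential")
    samples = {k: [] for k in names}
    block_idx = []
    state.unwrapped = state.config.positions.copy()
    cache = _forces(state, params)
    step_no = 0
    for block in range(protocol.n_series):
        for _ in range(protocol.series_len):
            cache = vv_step(state, params, dt, cache)
            apply_thermostat(state, T, "stochastic_rescale", protocol.tau_T,
                             dt, rng)
            apply_barostat(state, p, "stochastic_cell_rescale",
                           protocol.tau_P, dt, params, rng, cache=cache,
                           target_T=T)
            cache = _forces(state, params)
            step_no += 1
            if step_no % protocol.sample_every == 0:
                h = (cache["energy"] + state.kinetic_energy
                     + p * state.config.area)
                samples["enthalpy"].append(h)
                samples["area"].append(state.config.area)
                samples["kinetic_T"].append(state.kinetic_temperature)
                samples["pressure"].append(
                    virial_pressure(state, params, cache))
                samples["potential"].append(cache["energy"])
                block_idx.append(block)
            if step_no % protocol.frame_every == 0:
                frames.append(state.config.copy())
                unwrapped.append(state.unwrapped.copy())
                frame_times.append(state.time)

    return Trajectory(
        frames=frames,
        unwrapped=np.array(unwrapped) if unwrapped
        else np.empty((0, initial.n_molecules, 2)),
        frame_times=np.array(frame_times),
        samples={k: np.array(v) for k, v in samples.items()},
        sample_block=np.array(block_idx, dtype=int),
        n_series=protocol.n_series,
        dt_sample=dt * protocol.sample_every,
        final_state=state,
    )


def suggest_density(T: float, p: float) -> float:
    """Crude starting-density heuristic: ideal-gas at low p, capped by
    typical condensed-phase densities at high p."""
    rho_gas = min(p / T, 0.85)
    return float(max(0.05, rho_gas) if p / T < 0.5 else 0.7)
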