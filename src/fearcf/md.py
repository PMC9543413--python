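"""Self-contained molecular dynamics: a flexible three-site water dimer and
analytic test particles, with velocity-Verlet integration and thermostats.

Everything is batched: state arrays may carry leading replica dimensions,
``positions`` has shape ``(..., n_atoms, 3)``.  Internal units are AKMA-style
(Å, amu, kcal/mol, time unit ``AKMA_TIME_FS`` fs); the public API takes times
in fs and velocities in Å per internal time unit.

The biasing-force hook sits inside :func:`velocity_verlet_step`: an optional
``extra_force`` callable is evaluated together with the system force field at
every force evaluation, exactly where an adaptive-bias library call belongs
in an MD package's step update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AKMA_TIME_FS, COULOMB, KB, MASS_H, MASS_O, TIP3P

__all__ = [
    "MDState", "WaterForceField", "SimulationConditions",
    "water_dimer_init", "compute_forces", "velocity_verlet_step",
    "apply_thermostat", "make_thermostat", "simulate",
    "AnalyticSystem", "double_well_1d", "harmonic_nd", "CartesianRC",
    "kinetic_energy", "kinetic_temperature", "maxwell_boltzmann_velocities",
]


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class MDState:
    """Positions/velocities/forces (..., n, 3), masses (n,), time in fs.

    Exactly one of ``box_edge`` (cubic periodic box, Å) or ``cavity_radius``
    (soft spherical restraint about the origin, Å) may be set; both None
    means open boundaries.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    forces: np.ndarray | None = None
    time_fs: float = 0.0
    box_edge: float | None = None
    cavity_radius: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.masses = np.asarray(self.masses, float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if self.masses.shape != self.positions.shape[-2:-1]:
            raise ValueError("masses must have shape (n_atoms,)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box_edge is not None and self.cavity_radius is not None:
            raise ValueError("choose periodic box or cavity, not both")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[-2]

    @property
    def n_dof(self) -> int:
        return 3 * self.n_atoms

    def copy(self) -> "MDState":
        return replace(
            self, positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            forces=None if self.forces is None else self.forces.copy())


def kinetic_energy(state: MDState) -> np.ndarray:
    """½ Σ m v², kcal/mol, per batch element."""
    v2 = np.einsum("...ij,...ij->...i", state.velocities, state.velocities)
    return 0.5 * np.einsum("...i,i->...", v2, state.masses)


def kinetic_temperature(state: MDState) -> np.ndarray:
    """Instantaneous kinetic temperature 2·KE / (n_dof k_B), K."""
    return 2.0 * kinetic_energy(state) / (state.n_dof * KB)


def maxwell_boltzmann_velocities(masses, temperature, rng, batch_shape=()):
    """Velocities (batch + (n, 3)) with per-component variance k_B T / m."""
    m = np.asarray(masses, float)
    sigma = np.sqrt(KB * temperature / m)[:, None]
    return rng.normal(size=batch_shape + (m.size, 3)) * sigma


# ---------------------------------------------------------------------------
# water force field
# ---------------------------------------------------------------------------

@dataclass
class WaterForceField:
    """Flexible three-site water: harmonic bonds/angles, LJ + Coulomb between
    molecules.  CHARMM-style energy forms E_b = k_b (r − r0)² and
    E_θ = k_θ (θ − θ0)² (force constants contain the conventional ½).

    Atom order per molecule: O, H, H.  Defaults are the standard published
    TIP3P charges/LJ parameters with flexible-bond constants
    (:data:`fearcf.constants.TIP3P`).
    """

    q_O: float = TIP3P["q_O"]
    q_H: float = TIP3P["q_H"]
    eps_O: float = TIP3P["eps_O"]
    rmin_half_O: float = TIP3P["rmin_half_O"]
    eps_H: float = TIP3P["eps_H"]
    rmin_half_H: float = TIP3P["rmin_half_H"]
    k_bond: float = TIP3P["k_bond"]
    r0: float = TIP3P["r0"]
    k_angle: float = TIP3P["k_angle"]
    theta0_deg: float = TIP3P["theta0_deg"]
    coulomb_constant: float = COULOMB
    cutoff: float | None = None
    cavity_k: float = 5.0       # kcal/mol/Å² per atom beyond the cavity
    n_molecules: int = 2

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if abs(self.q_O + 2 * self.q_H) > 1e-12:
            raise ValueError("molecular charge must be zero")
        nm = self.n_molecules
        o = np.arange(nm) * 3
        self._bonds = np.concatenate([np.stack([o, o + 1], 1),
                                      np.stack([o, o + 2], 1)])
        self._angles = np.stack([o + 1, o, o + 2], 1)   # H-O-H
        # intermolecular pair list
        q = np.array([self.q_O, self.q_H, self.q_H] * nm)
        eps = np.array([self.eps_O, self.eps_H, self.eps_H] * nm)
        rmh = np.array([self.rmin_half_O, self.rmin_half_H, self.rmin_half_H] * nm)
        pairs = []
        for a in range(3 * nm):
            for b in range(a + 1, 3 * nm):
                if a // 3 != b // 3:
                    pairs.append((a, b))
        self._pairs = np.array(pairs)
        ia, ib = self._pairs.T
        self._qq = self.coulomb_constant * q[ia] * q[ib]
        self._eps_ij = np.sqrt(eps[ia] * eps[ib])
        self._rmin_ij = rmh[ia] + rmh[ib]

    @property
    def masses(self) -> np.ndarray:
        return np.array([MASS_O, MASS_H, MASS_H] * self.n_molecules)

    def __call__(self, positions, box_edge=None, cavity_radius=None):
        """(forces, potential energy) at ``positions`` (..., 3·n_mol, 3)."""
        x = np.asarray(positions, float)
        if not np.all(np.isfinite(x)):
            raise ValueError("coordinate overflow")
        F = np.zeros_like(x)
        E = np.zeros(x.shape[:-2])

        # bonds
        d = x[..., self._bonds[:, 1], :] - x[..., self._bonds[:, 0], :]
        r = np.sqrt(np.einsum("...i,...i->...", d, d))
        dr = r - self.r0
        E += self.k_bond * np.sum(dr * dr, axis=-1)
        fb = (-2.0 * self.k_bond * dr / r)[..., None] * d    # on atom j
        np.add.at(F, (..., self._bonds[:, 1], slice(None)), fb)
        np.add.at(F, (..., self._bonds[:, 0], slice(None)), -fb)

        # angles (H-O-H)
        i, j, k = self._angles.T
        u = x[..., i, :] - x[..., j, :]
        w = x[..., k, :] - x[..., j, :]
        nu = np.sqrt(np.einsum("...i,...i->...", u, u))
        nw = np.sqrt(np.einsum("...i,...i->...", w, w))
        c = np.einsum("...i,...i->...", u, w) / (nu * nw)
        c = np.clip(c, -1.0, 1.0)
        theta = np.arccos(c)
        dth = theta - math.radians(self.theta0_deg)
        E += self.k_angle * np.sum(dth * dth, axis=-1)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
        coef = 2.0 * self.k_angle * dth / s
        uh = u / nu[..., None]
        wh = w / nw[..., None]
        dth_du = (uh * c[..., None] - wh) / nu[..., None]
        dth_dw = (wh * c[..., None] - uh) / nw[..., None]
        fi = -coef[..., None] * dth_du
        fk = -coef[..., None] * dth_dw
        np.add.at(F, (..., i, slice(None)), fi)
        np.add.at(F, (..., k, slice(None)), fk)
        np.add.at(F, (..., j, slice(None)), -(fi + fk))

        # intermolecular LJ + Coulomb (minimum image if periodic)
        ia, ib = self._pairs.T
        d = x[..., ib, :] - x[..., ia, :]
        if box_edge is not None:
            d -= box_edge * np.round(d / box_edge)
        r2 = np.einsum("...i,...i->...", d, d)
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        ecoul = self._qq * inv_r
        x6 = (self._rmin_ij * inv_r) ** 6
        elj = self._eps_ij * (x6 * x6 - 2.0 * x6)
        # dE/dr
        dEdr = -ecoul * inv_r + self._eps_ij * 12.0 * (-x6 * x6 + x6) * inv_r
        if self.cutoff is not None:
            live = r < self.cutoff
            ecoul = np.where(live, ecoul, 0.0)
            elj = np.where(live, elj, 0.0)
            dEdr = np.where(live, dEdr, 0.0)
        E += np.sum(ecoul + elj, axis=-1)
        fp = (-dEdr * inv_r)[..., None] * d                  # on atom b
        np.add.at(F, (..., ib, slice(None)), fp)
        np.add.at(F, (..., ia, slice(None)), -fp)

        if cavity_radius is not None:
            rr = np.sqrt(np.einsum("...ij,...ij->...i", x, x))
            out = np.maximum(rr - cavity_radius, 0.0)
            E += 0.5 * self.cavity_k * np.sum(out * out, axis=-1)
            F -= (self.cavity_k * out / np.maximum(rr, 1e-12))[..., None] * x
        return F, E


def compute_forces(state: MDState, ff: WaterForceField):
    """Forces and potential energy of ``state`` under ``ff``."""
    return ff(state.positions, box_edge=state.box_edge,
              cavity_radius=state.cavity_radius)


def water_dimer_init(separation: float, temperature: float = 300.0,
                     seed=0, orientation: str = "random",
                     ff: WaterForceField | None = None,
                     box_edge: float | None = None,
                     cavity_radius: float | None = 6.0,
                     batch_shape: tuple = ()) -> MDState:
    """Two waters at the given O–O separation (Å), internal geometry at the
    force-field equilibrium, Maxwell–Boltzmann velocities at ``temperature``.

    ``orientation='random'`` rotates each molecule independently (per seed);
    ``'linear'`` keeps both in the construction plane.  The dimer COM sits at
    the origin (the cavity center).
    """
    if separation <= 1.0:
        raise ValueError("separation must exceed 1 Å (overlapping atoms)")
    ff = ff or WaterForceField()
    rng = np.random.default_rng(seed)
    th = math.radians(ff.theta0_deg)
    mol = np.array([
        [0.0, 0.0, 0.0],
        [ff.r0, 0.0, 0.0],
        [ff.r0 * math.cos(th), ff.r0 * math.sin(th), 0.0],
    ])
    masses = ff.masses

    def place(offset):
        if orientation == "random":
            R = _random_rotation(rng)
            return mol @ R.T + offset
        return mol + offset

    n = int(np.prod(batch_shape, dtype=int)) if batch_shape else 1
    frames = []
    for _ in range(n):
        w1 = place(np.zeros(3))
        w2 = place(np.array([separation, 0.0, 0.0]))
        x = np.vstack([w1, w2])
        com = (masses[:, None] * x).sum(0) / masses.sum()
        frames.append(x - com)
    x = np.array(frames).reshape(batch_shape + (6, 3))
    v = maxwell_boltzmann_velocities(masses, temperature, rng, batch_shape)
    return MDState(positions=x, velocities=v, masses=masses,
                   box_edge=box_edge, cavity_radius=cavity_radius)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# integration and thermostats
# ---------------------------------------------------------------------------

@dataclass
class SimulationConditions:
    """Run conditions: temperature (K), timestep (fs), thermostat choice.

    ``thermostat`` is one of ``langevin`` (friction in fs⁻¹),
    ``velocity_scale`` (rescale every ``scale_interval`` steps),
    ``nose_hoover`` (single chain, ``tau_fs`` coupling time,
    ``nh_substeps`` sub-steps), or ``none`` (NVE).
    """

    temperature: float = 300.0
    timestep_fs: float = 1.0
    n_steps: int = 1000
    thermostat: str = "nose_hoover"
    friction_fs: float = 0.001
    tau_fs: float = 100.0
    nh_substeps: int = 10
    scale_interval: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.thermostat not in ("langevin", "velocity_scale",
                                   "nose_hoover", "none"):
            raise ValueError(f"invalid thermostat {self.thermostat!r}")


def velocity_verlet_step(state: MDState, force_provider, dt_fs: float,
                         extra_force=None) -> MDState:
    """One velocity-Verlet update (in place on the state arrays).

    ``force_provider(positions) -> (forces, energy)``; ``extra_force``
    (positions -> forces), when given, is added at every force evaluation —
    this is the biasing-force insertion point.
    """
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    dt = dt_fs / AKMA_TIME_FS
    inv_m = 1.0 / state.masses[:, None]

    def total_force(x):
        F, E = force_provider(x)
        if extra_force is not None:
            F = F + extra_force(x)
        return F, E

    if state.forces is None:
        state.forces, _ = total_force(state.positions)
    if not np.all(np.isfinite(state.forces)):
        raise ValueError("non-finite forces")
    v_half = state.velocities + 0.5 * dt * state.forces * inv_m
    state.positions = state.positions + dt * v_half
    state.forces, _ = total_force(state.positions)
    state.velocities = v_half + 0.5 * dt * state.forces * inv_m
    state.time_fs += dt_fs
    return state


def langevin_baoab_step(state: MDState, force_provider, dt_fs: float,
                        friction_fs: float, temperature: float, rng,
                        extra_force=None) -> MDState:
    """One BAOAB Langevin step (kick / drift / noise / drift / kick).

    The BAOAB splitting has very small configurational sampling error even
    for stiff modes (ω·dt approaching 1), which matters for a flexible
    water model integrated at 1 fs.  One force evaluation per step; the
    ``extra_force`` hook is the same biasing-force insertion point as in
    :func:`velocity_verlet_step`.
    """
    if dt_fs <= 0:
        raise ValueError("dt must be positive")
    dt = dt_fs / AKMA_TIME_FS
    gamma = friction_fs * AKMA_TIME_FS
    kT = KB * temperature
    inv_m = 1.0 / state.masses[:, None]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(kT / state.masses)[:, None]

    def total_force(x):
        F, E = force_provider(x)
        if extra_force is not None:
            F = F + extra_force(x)
        return F, E

    if state.forces is None:
        state.forces, _ = total_force(state.positions)
    if not np.all(np.isfinite(state.forces)):
        raise ValueError("non-finite forces")
    v = state.velocities + 0.5 * dt * state.forces * inv_m
    x = state.positions + 0.5 * dt * v
    v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
    state.positions = x + 0.5 * dt * v
    state.forces, _ = total_force(state.positions)
    state.velocities = v + 0.5 * dt * state.forces * inv_m
    state.time_fs += dt_fs
    return state


@dataclass
class _NoseHoover:
    zeta: np.ndarray        # per batch element


def make_thermostat(conditions: SimulationConditions, batch_shape=()):
    """Thermostat closure ``(state, rng) -> state`` applied once per step."""
    kT = KB * conditions.temperature
    dt = conditions.timestep_fs / AKMA_TIME_FS
    kind = conditions.thermostat

    if kind == "none":
        return lambda state, rng: state

    if kind == "langevin":
        gamma = conditions.friction_fs * AKMA_TIME_FS      # per time unit
        c1 = math.exp(-gamma * dt)
        c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))

        def langevin(state, rng):
            sigma = np.sqrt(kT / state.masses)[:, None]
            noise = rng.normal(size=state.velocities.shape)
            state.velocities = c1 * state.velocities + c2 * sigma * noise
            return state
        return langevin

    if kind == "velocity_scale":
        counter = {"n": 0}

        def rescale(state, rng):
            counter["n"] += 1
            if counter["n"] % conditions.scale_interval:
                return state
            ke = kinetic_energy(state)
            target = 0.5 * state.n_dof * kT
            lam = np.sqrt(target / np.maximum(ke, 1e-30))
            state.velocities = state.velocities * lam[..., None, None]
            return state
        return rescale

    # single-chain Nose-Hoover; Q = n_dof kT tau^2
    tau = conditions.tau_fs / AKMA_TIME_FS
    nh = _NoseHoover(zeta=np.zeros(batch_shape))

    def nose_hoover(state, rng):
        Q = state.n_dof * kT * tau * tau
        h = dt / conditions.nh_substeps
        for _ in range(conditions.nh_substeps):
            ke = kinetic_energy(state)
            nh.zeta = nh.zeta + 0.5 * h * (2.0 * ke - state.n_dof * kT) / Q
            state.velocities = state.velocities * np.exp(-h * nh.zeta)[..., None, None]
            ke = kinetic_energy(state)
            nh.zeta = nh.zeta + 0.5 * h * (2.0 * ke - state.n_dof * kT) / Q
        return state
    return nose_hoover


def apply_thermostat(state: MDState, conditions: SimulationConditions,
                     rng=None) -> MDState:
    """One-shot thermostat application (stateless convenience wrapper)."""
    rng = rng or np.random.default_rng(conditions.seed)
    return make_thermostat(conditions, state.positions.shape[:-2])(state, rng)


def simulate(state: MDState, force_provider, conditions: SimulationConditions,
             extra_force=None, callback=None, rng=None) -> MDState:
    """Run ``conditions.n_steps`` of thermostatted velocity-Verlet dynamics.

    ``callback(step, state)``, when given, runs after every step.
    """
    rng = rng or np.random.default_rng(conditions.seed)
    if conditions.thermostat == "langevin":
        for step in range(conditions.n_steps):
            langevin_baoab_step(state, force_provider, conditions.timestep_fs,
                                conditions.friction_fs, conditions.temperature,
                                rng, extra_force=extra_force)
            if callback is not None:
                callback(step, state)
        return state
    thermo = make_thermostat(conditions, state.positions.shape[:-2])
    for step in range(conditions.n_steps):
        velocity_verlet_step(state, force_provider, conditions.timestep_fs,
                             extra_force=extra_force)
        thermo(state, rng)
        if callback is not None:
            callback(step, state)
    return state


# ---------------------------------------------------------------------------
# analytic test systems
# ---------------------------------------------------------------------------

@dataclass
class AnalyticSystem:
    """A single particle whose coordinate(s) ARE the reaction coordinate(s).

    ``potential(xi) -> W`` and ``grad(xi) -> dW/dξ`` act on the selected
    coordinates (the first ``ndim`` Cartesian components of the particle).
    The exact W(ξ) is known in closed form, making adaptive-bias convergence
    testable against an analytic answer.
    """

    potential: object
    grad: object
    ndim: int = 1
    mass: float = 12.0

    def force_provider(self):
        d = self.ndim

        def provider(x):
            xi = x[..., 0, :d]
            F = np.zeros_like(x)
            F[..., 0, :d] = -self.grad(xi)
            return F, self.potential(xi)
        return provider

    def rc(self) -> "CartesianRC":
        return CartesianRC(self.ndim)

    def init_state(self, temperature, seed=0, batch_shape=(), x0=None) -> MDState:
        rng = np.random.default_rng(seed)
        masses = np.array([self.mass])
        x = np.zeros(batch_shape + (1, 3))
        if x0 is not None:
            x[..., 0, :self.ndim] = x0
        v = maxwell_boltzmann_velocities(masses, temperature, rng, batch_shape)
        v[..., self.ndim:] = 0.0      # unused components stay frozen
        return MDState(positions=x, velocities=v, masses=masses)


def double_well_1d(a: float = 2.0, x0: float = 1.0) -> AnalyticSystem:
    """W(x) = a ((x/x0)² − 1)²: two wells at ±x0 with barrier a (kcal/mol)."""

    def W(xi):
        s = (xi[..., 0] / x0) ** 2 - 1.0
        return a * s * s

    def dW(xi):
        x = xi[..., 0]
        g = 4.0 * a * x * ((x / x0) ** 2 - 1.0) / x0**2
        return g[..., None]

    return AnalyticSystem(potential=W, grad=dW, ndim=1)


def harmonic_nd(k=1.0, ndim: int = 1) -> AnalyticSystem:
    """W(ξ) = ½ Σ k_i ξ_i²."""
    k = np.broadcast_to(np.asarray(k, float), (ndim,))

    def W(xi):
        return 0.5 * np.einsum("...i,i->...", xi * xi, k)

    def dW(xi):
        return k * xi

    return AnalyticSystem(potential=W, grad=dW, ndim=ndim)


class CartesianRC:
    """RC adapter whose coordinates are the particle's own Cartesian axes.

    Presents the same evaluate/propagate surface as
    :class:`fearcf.rc_graph.RCGraph`, so drivers work with either.
    """

    def __init__(self, ndim: int = 1):
        self.ndim = ndim
        self.rc_names = [f"x{i}" for i in range(ndim)]
        self.rc_kinds = ["distance"] * ndim     # linear coordinates
        self.n_atoms = 1

    def evaluate(self, positions):
        return np.asarray(positions, float)[..., 0, :self.ndim]

    def forward_values(self, positions):
        return self.evaluate(positions), None

    def propagate_forces(self, positions, dW_dxi, vals=None):
        x = np.asarray(positions, float)
        F = np.zeros(x.shape[:-2] + (1, 3))
        F[..., 0, :self.ndim] = -np.asarray(dW_dxi, float)
        return F

    def jacobian(self, positions):
        x = np.asarray(positions, float)
        J = np.zeros(x.shape[:-2] + (self.ndim, 1, 3))
        for i in range(self.ndim):
            J[..., i, 0, i] = 1.0
        return J
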