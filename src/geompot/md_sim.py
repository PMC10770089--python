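"""Minimal molecular-dynamics driver (velocity Verlet, optional Berendsen
weak-coupling thermostat) and the interatomic distance distribution h(r).

Unit system: Angstrom, femtosecond, amu, kcal/mol.  The single conversion
constant is ``ACCEL_CONV``: a force of 1 kcal/mol/A on a 1 amu mass gives an
acceleration of 4.184e-4 A/fs^2 (thermochemical calorie).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .structures_io import AtomicConfiguration

__all__ = [
    "ACCEL_CONV",
    "KB",
    "MDState",
    "DistanceDistribution",
    "Trajectory",
    "kinetic_energy",
    "instantaneous_temperature",
    "maxwell_boltzmann_velocities",
    "velocity_verlet_step",
    "berendsen_rescale",
    "run_md",
    "distance_distribution",
]

# 1 (kcal/mol/A) / amu = 4184 J / (1 g * 1 A) = 4.184e-4 A/fs^2
ACCEL_CONV = 4.184e-4
# Boltzmann constant in kcal/mol/K
KB = 0.0019872041

EnergyForces = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class MDState:
    positions: np.ndarray  # (N, 3) Angstrom
    velocities: np.ndarray  # (N, 3) Angstrom/fs
    masses: np.ndarray  # (N,) amu
    time: float = 0.0  # fs
    timestep: float = 0.5  # fs
    thermostat: str = "none"  # "none" (NVE) or "berendsen"
    temperature_target: float | None = None  # K
    coupling_time: float = 100.0  # fs

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.thermostat not in ("none", "berendsen"):
            raise ValueError(f"unknown thermostat: {self.thermostat}")


@dataclass
class DistanceDistribution:
    r: np.ndarray  # bin centers, Angstrom
    h: np.ndarray  # ensemble-averaged density, >= 0
    ensemble_size: int


@dataclass
class Trajectory:
    frames: list[AtomicConfiguration]
    times: np.ndarray
    potential_energy: np.ndarray
    kinetic_energy: np.ndarray
    temperature: np.ndarray


def kinetic_energy(state: MDState) -> float:
    """Kinetic energy in kcal/mol."""
    v2 = np.sum(state.velocities**2, axis=1)
    return float(0.5 * np.sum(state.masses * v2) / ACCEL_CONV)


def _dof(n_atoms: int) -> int:
    # net momentum is removed at initialization and conserved thereafter
    return max(3 * n_atoms - 3, 1)


def instantaneous_temperature(state: MDState) -> float:
    """Temperature in K from equipartition over 3N - 3 degrees of freedom."""
    return 2.0 * kinetic_energy(state) / (_dof(len(state.masses)) * KB)


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, seed: int = 0
) -> np.ndarray:
    """Maxwell-Boltzmann draw at the target temperature with net momentum
    removed, then rescaled so the instantaneous temperature is exact."""
    rng = np.random.default_rng(seed)
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature * ACCEL_CONV / masses)
    v = rng.standard_normal((masses.size, 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    ke = 0.5 * np.sum(masses * np.sum(v**2, axis=1)) / ACCEL_CONV
    target_ke = 0.5 * _dof(masses.size) * KB * temperature
    if ke > 0:
        v *= np.sqrt(target_ke / ke)
    return v


def velocity_verlet_step(
    state: MDState,
    energy_forces: EnergyForces,
    forces: np.ndarray | None = None,
):
    """One velocity-Verlet update.  ``energy_forces`` maps positions to
    (potential energy, forces); passing the cached ``forces`` of the current
    positions avoids one evaluation.  Returns (new state, new forces,
    potential energy at the new positions)."""
    tau = state.timestep
    inv_m = 1.0 / state.masses[:, None]
    if forces is None:
        _, forces = energy_forces(state.positions)
    a0 = forces * ACCEL_CONV * inv_m
    new_pos = state.positions + state.velocities * tau + 0.5 * a0 * tau**2
    new_E, new_forces = energy_forces(new_pos)
    a1 = new_forces * ACCEL_CONV * inv_m
    new_vel = state.velocities + 0.5 * (a0 + a1) * tau
    new_state = replace(
        state, positions=new_pos, velocities=new_vel, time=state.time + tau
    )
    return new_state, new_forces, new_E


def berendsen_rescale(
    state: MDState, target_temperature: float, coupling_time: float
) -> MDState:
    """Weak-coupling velocity rescale:
    lambda = sqrt(1 + (tau/tau_c)(T_target/T_inst - 1))."""
    t_inst = instantaneous_temperature(state)
    if t_inst <= 0.0:
        warnings.warn("zero kinetic energy: skipping Berendsen rescale")
        return state
    lam = np.sqrt(
        1.0 + (state.timestep / coupling_time) * (target_temperature / t_inst - 1.0)
    )
    return replace(state, velocities=state.velocities * lam)


def run_md(
    initial: AtomicConfiguration,
    potential: Callable[[AtomicConfiguration], tuple[float, np.ndarray]],
    steps: int,
    timestep: float = 0.5,
    thermostat: str = "none",
    temperature: float | None = None,
    coupling_time: float = 100.0,
    seed: int = 0,
    stride: int = 1,
    initial_velocities: np.ndarray | None = None,
) -> Trajectory:
    """Integrate ``steps`` velocity-Verlet steps from ``initial``.

    Velocities start from a Maxwell-Boltzmann draw at ``temperature`` (zero
    if no temperature is given) unless supplied explicitly.  Frames are
    recorded every ``stride`` steps (the initial frame always included), each
    carrying its potential energy and forces.  Deterministic given ``seed``.
    """
    z = initial.atomic_numbers
    masses = initial.masses

    def ef_of_positions(R: np.ndarray):
        cfg = AtomicConfiguration(atomic_numbers=z, coordinates=R)
        return potential(cfg)

    if initial_velocities is not None:
        vel = np.asarray(initial_velocities, dtype=float)
    elif temperature is not None:
        vel = maxwell_boltzmann_velocities(masses, temperature, seed=seed)
    else:
        vel = np.zeros_like(initial.coordinates)

    state = MDState(
        positions=initial.coordinates.copy(),
        velocities=vel,
        masses=masses,
        timestep=timestep,
        thermostat=thermostat,
        temperature_target=temperature,
        coupling_time=coupling_time,
    )
    E0, forces = ef_of_positions(state.positions)

    frames = [initial.replace(energy=E0, forces=forces)]
    times = [0.0]
    pot = [E0]
    kin = [kinetic_energy(state)]
    temps = [instantaneous_temperature(state)]

    for step in range(1, steps + 1):
        state, forces, E = velocity_verlet_step(state, ef_of_positions, forces)
        if thermostat == "berendsen":
            if temperature is None:
                raise ValueError("berendsen thermostat requires a temperature")
            state = berendsen_rescale(state, temperature, coupling_time)
        if not np.all(np.isfinite(state.positions)):
            raise RuntimeError(f"NaN coordinates at step {step}")
        if step % stride == 0 or step == steps:
            frames.append(
                AtomicConfiguration(
                    atomic_numbers=z,
                    coordinates=state.positions.copy(),
                    energy=E,
                    forces=forces.copy(),
                )
            )
            times.append(state.time)
            pot.append(E)
            kin.append(kinetic_energy(state))
            temps.append(instantaneous_temperature(state))
    return Trajectory(
        frames=frames,
        times=np.array(times),
        potential_energy=np.array(pot),
        kinetic_energy=np.array(kin),
        temperature=np.array(temps),
    )


def distance_distribution(
    frames: Sequence[AtomicConfiguration],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> DistanceDistribution:
    """Histogram density of all interatomic pair distances, averaged over
    frames.  Invariant to rigid motions of the frames."""
    if not frames:
        raise ValueError("need at least one frame")
    all_d = [pdist(f.coordinates) for f in frames]
    if r_max is None:
        r_max = max(d.max() for d in all_d) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    acc = np.zeros(edges.size - 1)
    for d in all_d:
        counts, _ = np.histogram(d, bins=edges)
        acc += counts / (len(d) * bin_width)
    return DistanceDistribution(
        r=0.5 * (edges[:-1] + edges[1:]),
        h=acc / len(frames),
        ensemble_size=len(frames),
    )
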