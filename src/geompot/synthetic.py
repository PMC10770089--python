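"""Synthetic fixtures: random clusters, analytic bonded toy potentials with
exact energy/force labels, labeled datasets and random rigid transforms.

The toy potential mirrors the bonded terms of a classical force field
(harmonic bonds and angles, cosine dihedrals) so that every oracle used to
validate the learned model — rigid-motion invariance, force equivariance,
zero net force, finite-difference consistency — can first be exercised on a
ground-truth case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import grad
from scipy.spatial.transform import Rotation

from .structures_io import AtomicConfiguration

__all__ = [
    "ToyPotentialSpec",
    "TransformSpec",
    "random_cluster",
    "toy_energy_forces",
    "ToyPotential",
    "generate_dataset",
    "random_rigid_transform",
    "apply_transform",
    "chain_geometry",
    "reference_fixture",
]


@dataclass
class ToyPotentialSpec:
    """Bonded-term force field over a fixed reference topology.

    ``bonds``: (i, j, k, r0) with k in kcal/mol/A^2, r0 in Angstrom.
    ``angles``: (i, j, k, k_theta, theta0) — j is the apex; theta0 in radians.
    ``dihedrals``: (i, j, k, l, k_phi, n, phi0) — cosine torsion terms.
    ``atomic_numbers`` / ``equilibrium_coordinates`` define the reference
    molecule used by :func:`generate_dataset`.
    """

    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)
    dihedrals: list[tuple] = field(default_factory=list)
    atomic_numbers: np.ndarray | None = None
    equilibrium_coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        for i, j, k, r0 in self.bonds:
            if k < 0:
                raise ValueError("bond force constants must be >= 0")
        for *_, k_th, th0 in self.angles:
            if k_th < 0 or not 0.0 < th0 < math.pi:
                raise ValueError("angle terms need k >= 0 and 0 < theta0 < pi")

    def max_index(self) -> int:
        idx = [-1]
        idx += [max(b[0], b[1]) for b in self.bonds]
        idx += [max(a[0], a[1], a[2]) for a in self.angles]
        idx += [max(d[0], d[1], d[2], d[3]) for d in self.dihedrals]
        return max(idx)


@dataclass
class TransformSpec:
    """A rigid motion plus relabeling: proper rotation, translation and an
    atom-index permutation."""

    rotation: np.ndarray
    translation: np.ndarray
    permutation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-12:
            raise ValueError("rotation must be orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-12:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)
        self.permutation = np.asarray(self.permutation, dtype=int)

    def inverse(self) -> "TransformSpec":
        inv_perm = np.argsort(self.permutation)
        return TransformSpec(
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
            permutation=inv_perm,
        )


_LIGHT_ELEMENTS = np.array([1, 6, 7, 8])


def random_cluster(
    n_atoms: int,
    box_scale: float = 6.0,
    min_separation: float = 0.8,
    seed: int = 0,
    max_tries: int = 500,
) -> AtomicConfiguration:
    """Uniformly placed light-element atoms with all pairwise distances
    >= ``min_separation``; reproducible per seed."""
    rng = np.random.default_rng(seed)
    coords = np.empty((n_atoms, 3))
    placed = 0
    tries = 0
    while placed < n_atoms:
        candidate = rng.uniform(0.0, box_scale, size=3)
        if placed == 0 or np.all(
            np.linalg.norm(coords[:placed] - candidate, axis=1) >= min_separation
        ):
            coords[placed] = candidate
            placed += 1
        else:
            tries += 1
            if tries > max_tries * n_atoms:
                raise RuntimeError(
                    "packing failed: box too small for requested separation"
                )
    numbers = rng.choice(_LIGHT_ELEMENTS, size=n_atoms)
    return AtomicConfiguration(atomic_numbers=numbers, coordinates=coords)


def _value_of(x) -> float:
    # unwrap autograd boxes for validation-only checks
    while hasattr(x, "_value"):
        x = x._value
    return float(x)


def _toy_energy(R, spec: ToyPotentialSpec):
    total = 0.0
    for i, j, k, r0 in spec.bonds:
        d = R[j] - R[i]
        r = anp.sqrt(anp.sum(d * d))
        total = total + k * (r - r0) ** 2
    for i, j, k, k_th, th0 in spec.angles:
        a = R[i] - R[j]
        b = R[k] - R[j]
        na = anp.sqrt(anp.sum(a * a))
        nb = anp.sqrt(anp.sum(b * b))
        cosang = anp.sum(a * b) / (na * nb)
        if abs(_value_of(cosang)) >= 1.0 - 1e-10:
            raise ValueError("degenerate (collinear) angle term")
        total = total + k_th * (anp.arccos(cosang) - th0) ** 2
    for i, j, k, l, k_phi, n, phi0 in spec.dihedrals:
        b1 = R[j] - R[i]
        b2 = R[k] - R[j]
        b3 = R[l] - R[k]
        n1 = anp.cross(b1, b2)
        n2 = anp.cross(b2, b3)
        m1 = anp.cross(n1, b2 / anp.sqrt(anp.sum(b2 * b2)))
        x = anp.sum(n1 * n2)
        y = anp.sum(m1 * n2)
        phi = anp.arctan2(y, x)
        total = total + k_phi * (1.0 + anp.cos(n * phi - phi0))
    return total


def toy_energy_forces(config: AtomicConfiguration, spec: ToyPotentialSpec):
    """Exact energy (kcal/mol) and forces F = -dE/dR (kcal/mol/A)."""
    if spec.max_index() >= config.n_atoms:
        raise ValueError("potential term indexes an atom beyond N")
    R = config.coordinates
    energy = float(_toy_energy(R, spec))
    forces = -grad(lambda X: _toy_energy(X, spec))(R)
    return energy, np.asarray(forces)


class ToyPotential:
    """Callable adapter matching the MD driver's potential protocol."""

    def __init__(self, spec: ToyPotentialSpec):
        self.spec = spec

    def __call__(self, config: AtomicConfiguration):
        return toy_energy_forces(config, self.spec)


def generate_dataset(
    spec: ToyPotentialSpec,
    n_frames: int,
    displacement_scale: float,
    seed: int = 0,
) -> list[AtomicConfiguration]:
    """Gaussian displacements of the spec's equilibrium geometry, each frame
    labeled with the exact toy energy and forces."""
    if spec.equilibrium_coordinates is None or spec.atomic_numbers is None:
        raise ValueError("spec must carry a reference geometry and species")
    rng = np.random.default_rng(seed)
    base = np.asarray(spec.equilibrium_coordinates, dtype=float)
    out = []
    for k in range(n_frames):
        R = base + displacement_scale * rng.standard_normal(base.shape)
        cfg = AtomicConfiguration(
            atomic_numbers=spec.atomic_numbers, coordinates=R, identifier=f"frame{k}"
        )
        e, f = toy_energy_forces(cfg, spec)
        out.append(cfg.replace(energy=e, forces=f))
    return out


def random_rigid_transform(
    seed: int = 0, n_atoms: int | None = None, translation_scale: float = 5.0
) -> TransformSpec:
    """Uniform random rotation (quaternion method), bounded translation and —
    when ``n_atoms`` is given — a random permutation (identity otherwise)."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    perm = rng.permutation(n_atoms) if n_atoms else np.arange(0)
    return TransformSpec(rotation=R, translation=t, permutation=perm)


def apply_transform(
    config: AtomicConfiguration, t: TransformSpec
) -> AtomicConfiguration:
    """Rotate, translate, then permute atom labels.  Forces co-rotate and
    permute; the energy label is untouched."""
    R = config.coordinates @ t.rotation.T + t.translation
    F = None if config.forces is None else config.forces @ t.rotation.T
    z = config.atomic_numbers
    if t.permutation.size == config.n_atoms:
        R = R[t.permutation]
        z = z[t.permutation]
        if F is not None:
            F = F[t.permutation]
    return config.replace(atomic_numbers=z, coordinates=R, forces=F)


def chain_geometry(
    bond_lengths: list[float], angles: list[float], dihedrals: list[float]
) -> np.ndarray:
    """Cartesian coordinates of a chain from internal coordinates (standard
    sequential placement).  len(angles) = len(bonds) - 1, len(dihedrals) =
    len(bonds) - 2; angles/dihedrals in radians."""
    n = len(bond_lengths) + 1
    R = np.zeros((n, 3))
    if n > 1:
        R[1] = [bond_lengths[0], 0.0, 0.0]
    if n > 2:
        th = angles[0]
        R[2] = R[1] + bond_lengths[1] * np.array(
            [-math.cos(th), math.sin(th), 0.0]
        )
    for a in range(3, n):
        r = bond_lengths[a - 1]
        theta = angles[a - 2]
        phi = dihedrals[a - 3]
        b, c = R[a - 2], R[a - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - R[a - 3]
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        mvec = np.cross(nvec, bc)
        d2 = np.array(
            [
                -r * math.cos(theta),
                r * math.cos(phi) * math.sin(theta),
                r * math.sin(phi) * math.sin(theta),
            ]
        )
        R[a] = c + d2[0] * bc + d2[1] * mvec + d2[2] * nvec
    return R


def reference_fixture() -> dict:
    """The frozen parameter-recovery experiment: a 4-atom carbon chain with
    harmonic bonds/angles and one threefold cosine torsion, 50 training and
    10 validation frames at 0.05 A Gaussian displacement, seed 7.

    The chain is built at the exact minimum of every term (torsion at 60
    degrees where 1 + cos(3 phi) = 0), so the undisplaced energy is 0.
    """
    theta0 = math.radians(109.5)
    phi_min = math.pi / 3.0
    spec = ToyPotentialSpec(
        bonds=[(0, 1, 300.0, 1.5), (1, 2, 300.0, 1.5), (2, 3, 300.0, 1.5)],
        angles=[(0, 1, 2, 80.0, theta0), (1, 2, 3, 80.0, theta0)],
        dihedrals=[(0, 1, 2, 3, 5.0, 3, 0.0)],
        atomic_numbers=np.array([6, 6, 6, 6]),
        equilibrium_coordinates=chain_geometry(
            [1.5, 1.5, 1.5], [theta0, theta0], [phi_min]
        ),
    )
    train = generate_dataset(spec, 50, 0.05, seed=7)
    val = generate_dataset(spec, 10, 0.05, seed=8)
    # frozen model/optimizer settings for the recovery experiment (imported
    # lazily to keep this module independent of the network stack)
    from .network import ModelConfig
    from .training import TrainConfig

    model_config = ModelConfig(
        n_blocks=2, hidden_dim=64, n_heads=4, n_rbf=16, l_max=1, cutoff=5.0
    )
    train_config = TrainConfig(
        lr=2e-3,
        max_epochs=700,
        plateau_patience_epochs=40,
        early_stop_patience=200,
        grad_clip=50.0,
        seed=7,
    )
    return {
        "spec": spec,
        "train": train,
        "val": val,
        "seed": 7,
        "model_config": model_config,
        "train_config": train_config,
    }
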