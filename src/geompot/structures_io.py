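"""Molecular configuration data model, extended-XYZ / array-archive I/O and
cutoff neighbor lists.

Units are fixed throughout the package: coordinates in Angstrom, energies in
kcal/mol, forces in kcal/mol/Angstrom.  Callers converting from other unit
systems must do so before constructing :class:`AtomicConfiguration`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AtomicConfiguration",
    "NeighborList",
    "DatasetSplit",
    "read_xyz",
    "write_xyz",
    "read_array_archive",
    "write_array_archive",
    "build_neighbor_list",
    "symbol_to_z",
    "z_to_symbol",
    "ATOMIC_MASSES",
]

# fmt: off
_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe",
]

# Standard atomic weights (amu), index = atomic number.  Z = 0 is a sentinel.
ATOMIC_MASSES = np.array([
    0.0, 1.008, 4.0026, 6.94, 9.0122, 10.81, 12.011, 14.007, 15.999,
    18.998, 20.180, 22.990, 24.305, 26.982, 28.085, 30.974, 32.06,
    35.45, 39.948, 39.098, 40.078, 44.956, 47.867, 50.942, 51.996,
    54.938, 55.845, 58.933, 58.693, 63.546, 65.38, 69.723, 72.630,
    74.922, 78.971, 79.904, 83.798, 85.468, 87.62, 88.906, 91.224,
    92.906, 95.95, 97.0, 101.07, 102.91, 106.42, 107.87, 112.41,
    114.82, 118.71, 121.76, 127.60, 126.90, 131.29,
])
# fmt: on

_SYMBOL_TO_Z = {s: z for z, s in enumerate(_SYMBOLS) if z > 0}


def symbol_to_z(symbol: str) -> int:
    """Map an element symbol (case-sensitive, e.g. ``"Cl"``) to its atomic number."""
    try:
        return _SYMBOL_TO_Z[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def z_to_symbol(z: int) -> str:
    if not 1 <= z < len(_SYMBOLS):
        raise ValueError(f"atomic number out of supported range: {z}")
    return _SYMBOLS[z]


@dataclass
class AtomicConfiguration:
    """A single molecular configuration with optional energy/force labels.

    Parameters
    ----------
    atomic_numbers : (N,) int array
        Atomic numbers, all >= 1.
    coordinates : (N, 3) float array
        Cartesian coordinates in Angstrom.
    energy : float, optional
        Potential energy label in kcal/mol.
    forces : (N, 3) float array, optional
        Force labels in kcal/mol/Angstrom.
    identifier : str, optional
        Free-form label carried through I/O.
    """

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    energy: float | None = None
    forces: np.ndarray | None = None
    identifier: str | None = None

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size < 1:
            raise ValueError("atomic_numbers must be a non-empty 1-D array")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be positive")
        n = self.atomic_numbers.size
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates must have shape ({n}, 3), got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coordinates.shape:
                raise ValueError("forces must match coordinates' shape")

    @property
    def n_atoms(self) -> int:
        return self.atomic_numbers.size

    @property
    def masses(self) -> np.ndarray:
        """Per-atom masses in amu from the standard atomic-weight table."""
        return ATOMIC_MASSES[self.atomic_numbers]

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.coordinates).sum(axis=0) / m.sum()

    def replace(self, **kwargs) -> "AtomicConfiguration":
        data = dict(
            atomic_numbers=self.atomic_numbers,
            coordinates=self.coordinates,
            energy=self.energy,
            forces=self.forces,
            identifier=self.identifier,
        )
        data.update(kwargs)
        return AtomicConfiguration(**data)


@dataclass
class NeighborList:
    """Directed within-cutoff pairs of a configuration.

    ``pairs[k] = (i, j)`` carries ``displacement[k] = R_j - R_i`` and its
    Euclidean norm.  Both directions of every pair are present.
    """

    pairs: np.ndarray  # (E, 2) int
    displacement: np.ndarray  # (E, 3) float, Angstrom
    distance: np.ndarray  # (E,) float, Angstrom
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def source(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def target(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index lists over a configuration list."""

    train: list[int]
    validation: list[int]
    test: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split index lists must be disjoint")

    @classmethod
    def random(
        cls, n_total: int, n_train: int, n_val: int, n_test: int = 0, seed: int = 0
    ) -> "DatasetSplit":
        if n_train + n_val + n_test > n_total:
            raise ValueError("split sizes exceed dataset size")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_total)
        return cls(
            train=[int(i) for i in perm[:n_train]],
            validation=[int(i) for i in perm[n_train : n_train + n_val]],
            test=[int(i) for i in perm[n_train + n_val : n_train + n_val + n_test]],
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "train": list(map(int, self.train)),
            "val": list(map(int, self.validation)),
            "test": list(map(int, self.test)),
            "seed": int(self.seed),
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetSplit":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            train=payload["train"],
            validation=payload["val"],
            test=payload.get("test", []),
            seed=payload.get("seed", 0),
        )


class XYZParseError(ValueError):
    pass


_ENERGY_RE = re.compile(r"(?:^|\s)(?:E|energy)\s*=\s*([-+0-9.eEdD]+)")


def read_xyz(path: str | Path) -> list[AtomicConfiguration]:
    """Read a (possibly multi-frame) extended-XYZ file.

    Each frame: an atom-count line, a comment line optionally carrying
    ``E=<energy>``, then one ``symbol x y z [fx fy fz]`` line per atom.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[AtomicConfiguration] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():  # tolerate trailing blank lines
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: line {ln + 1}: expected atom count, got {lines[ln]!r}"
            ) from None
        if n < 1 or ln + 1 + n > len(lines):
            raise XYZParseError(f"{path}: line {ln + 1}: bad atom count {n}")
        comment = lines[ln + 1]
        energy = None
        m = _ENERGY_RE.search(comment)
        if m:
            energy = float(m.group(1).replace("D", "E").replace("d", "e"))
        numbers = np.empty(n, dtype=int)
        coords = np.empty((n, 3))
        forces = np.empty((n, 3))
        have_forces = True
        for a in range(n):
            parts = lines[ln + 2 + a].split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"{path}: line {ln + 3 + a}: expected 4 or 7 columns, "
                    f"got {len(parts)}"
                )
            numbers[a] = symbol_to_z(parts[0])
            coords[a] = [float(x) for x in parts[1:4]]
            if len(parts) == 7:
                forces[a] = [float(x) for x in parts[4:7]]
            else:
                have_forces = False
        configs.append(
            AtomicConfiguration(
                atomic_numbers=numbers,
                coordinates=coords,
                energy=energy,
                forces=forces.copy() if have_forces else None,
            )
        )
        ln += 2 + n
    return configs


def write_xyz(configs: Iterable[AtomicConfiguration], path: str | Path) -> None:
    """Write configurations as a multi-frame extended-XYZ file (readable by
    :func:`read_xyz`); energies and forces are serialized when present."""
    out: list[str] = []
    for cfg in configs:
        out.append(str(cfg.n_atoms))
        comment = ""
        if cfg.energy is not None:
            comment = f"E={cfg.energy:.12g}"
        if cfg.identifier:
            comment = (comment + " " + cfg.identifier).strip()
        out.append(comment)
        for a in range(cfg.n_atoms):
            row = f"{z_to_symbol(int(cfg.atomic_numbers[a])):2s} " + " ".join(
                f"{x:.12f}" for x in cfg.coordinates[a]
            )
            if cfg.forces is not None:
                row += " " + " ".join(f"{x:.12f}" for x in cfg.forces[a])
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")


def read_array_archive(path: str | Path) -> list[AtomicConfiguration]:
    """Read an ``.npz`` trajectory archive with keys ``z`` (N,), ``R``
    (frames, N, 3) and optional ``E`` (frames,), ``F`` (frames, N, 3) —
    the layout used by common MD benchmark datasets."""
    with np.load(path) as data:
        z = np.asarray(data["z"], dtype=int).ravel()
        R = np.asarray(data["R"], dtype=float)
        E = np.asarray(data["E"], dtype=float).ravel() if "E" in data else None
        F = np.asarray(data["F"], dtype=float) if "F" in data else None
    if R.ndim == 2:
        R = R[None]
    n_frames = R.shape[0]
    if R.shape[1] != z.size or R.shape[2] != 3:
        raise ValueError(f"coordinate array shape {R.shape} inconsistent with z")
    if E is not None and E.size != n_frames:
        raise ValueError("energy array length does not match frame count")
    if F is not None and F.shape != R.shape:
        raise ValueError("force array shape does not match coordinates")
    return [
        AtomicConfiguration(
            atomic_numbers=z,
            coordinates=R[k],
            energy=None if E is None else float(E[k]),
            forces=None if F is None else F[k],
        )
        for k in range(n_frames)
    ]


def write_array_archive(
    configs: Sequence[AtomicConfiguration], path: str | Path
) -> None:
    """Write frames sharing one atomic-number vector to a ``.npz`` archive."""
    if not configs:
        raise ValueError("cannot write an empty archive")
    z = configs[0].atomic_numbers
    for c in configs:
        if not np.array_equal(c.atomic_numbers, z):
            raise ValueError("all frames must share the same atomic numbers")
    payload = {"z": z, "R": np.stack([c.coordinates for c in configs])}
    if all(c.energy is not None for c in configs):
        payload["E"] = np.array([c.energy for c in configs])
    if all(c.forces is not None for c in configs):
        payload["F"] = np.stack([c.forces for c in configs])
    np.savez(path, **payload)


def build_neighbor_list(config: AtomicConfiguration, cutoff: float) -> NeighborList:
    """All directed pairs with ``0 < |R_j - R_i| <= cutoff`` (no periodicity).

    Raises if two atoms coincide: downstream geometry divides by ``|r_ij|``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    R = config.coordinates
    n = config.n_atoms
    if n == 1:
        return NeighborList(
            pairs=np.empty((0, 2), dtype=int),
            displacement=np.empty((0, 3)),
            distance=np.empty(0),
            cutoff=float(cutoff),
        )
    dmat = squareform(pdist(R))
    off_diag = ~np.eye(n, dtype=bool)
    if np.any(dmat[off_diag] == 0.0):
        i, j = np.argwhere((dmat == 0.0) & off_diag)[0]
        raise ValueError(f"atoms {i} and {j} are at identical coordinates")
    ii, jj = np.nonzero((dmat <= cutoff) & off_diag)
    disp = R[jj] - R[ii]
    return NeighborList(
        pairs=np.column_stack([ii, jj]),
        displacement=disp,
        distance=dmat[ii, jj],
        cutoff=float(cutoff),
    )
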