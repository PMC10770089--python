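"""Runtime geometry extraction from cutoff graphs.

The core objects are per-node *direction units* (sums of unit vectors toward
neighbors) whose inner products — directly or after vector rejection off an
edge axis — yield sums of angle, dihedral-torsion and improper-angle cosines
in time linear in the edge count.  Explicit trigonometric enumeration oracles
(quadratic/cubic cost, small N only) are provided for cross-validation.

Everything here is plain float64 NumPy; the learnable network lifts the same
operations to multi-channel embeddings in :mod:`geompot.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

from .structures_io import AtomicConfiguration, NeighborList, build_neighbor_list

__all__ = [
    "DirectionUnitField",
    "RejectionPair",
    "GeometryScalars",
    "SphericalExpansion",
    "direction_units",
    "direction_units_expanded",
    "angle_scalar",
    "vector_rejection",
    "rejection_pairs",
    "dihedral_scalar",
    "improper_scalar",
    "geometry_scalars",
    "spherical_harmonics",
    "high_order_angle_scalar",
    "oracle_angle_sum",
    "oracle_dihedral_sum",
    "oracle_improper_sum",
]

_ORACLE_MAX_ATOMS = 50  # enumeration oracles are O(N^2)-O(N^3); keep them small


@dataclass
class DirectionUnitField:
    """Per-node direction units, geometric (N, 3) and/or expanded per order.

    ``expanded[l]`` holds the (N, 2l+1) sum of real order-``l`` spherical
    harmonics of the neighbor unit vectors; at ``l = 1`` it equals the
    geometric form times ``sqrt(3 / 4 pi)`` (up to component ordering).
    """

    geometric: np.ndarray | None = None
    expanded: dict[int, np.ndarray] | None = None
    order_max: int = 1
    channels: int = 1


@dataclass
class RejectionPair:
    """Per-directed-edge rejection vectors; ``w`` uses v_i and v_j (dihedral),
    ``t`` uses v_i on both slots (improper).  All orthogonal to the edge."""

    w_ij: np.ndarray
    w_ji: np.ndarray
    t_ij: np.ndarray
    t_ji: np.ndarray


@dataclass
class GeometryScalars:
    angle: np.ndarray  # (N,)   sum of cos(theta_jik) over ordered neighbor pairs
    dihedral: np.ndarray  # (E,)   per directed edge
    improper: np.ndarray  # (E,)


@dataclass
class SphericalExpansion:
    """Real spherical-harmonic values of one unit vector for l = 0..l_max."""

    values: dict[int, np.ndarray] = field(default_factory=dict)
    l_max: int = 0
    convention: str = "real-orthonormal"

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[l] for l in sorted(self.values)])


def direction_units(nlist: NeighborList, n_atoms: int) -> DirectionUnitField:
    """v_i = sum over j in N(i) of r_ij / |r_ij|; isolated nodes get zeros.

    One vectorized pass over the directed edge list (linear in edge count).
    """
    u = nlist.displacement / nlist.distance[:, None]
    v = np.zeros((n_atoms, 3))
    np.add.at(v, nlist.source, u)
    return DirectionUnitField(geometric=v, order_max=1)


def direction_units_expanded(
    nlist: NeighborList, n_atoms: int, l_max: int
) -> DirectionUnitField:
    """Per-order sums of real spherical harmonics of neighbor unit vectors."""
    if not 1 <= l_max <= 4:
        raise ValueError("l_max must be in 1..4")
    u = nlist.displacement / nlist.distance[:, None]
    expanded: dict[int, np.ndarray] = {}
    for l in range(1, l_max + 1):
        y = _real_sh_batch(u, l)  # (E, 2l+1)
        acc = np.zeros((n_atoms, 2 * l + 1))
        np.add.at(acc, nlist.source, y)
        expanded[l] = acc
    return DirectionUnitField(expanded=expanded, order_max=l_max)


def angle_scalar(v: DirectionUnitField) -> np.ndarray:
    """<v_i, v_i> = sum over ordered neighbor pairs (j, k) of cos(theta_jik),
    diagonal j = k terms included (each contributes 1)."""
    if v.geometric is None:
        raise ValueError("geometric form required; see high_order_angle_scalar")
    return np.einsum("nd,nd->n", v.geometric, v.geometric)


def vector_rejection(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Component of ``a`` orthogonal to ``b``: a - <a, b_hat> b_hat.

    Broadcasts over leading axes; the last axis is the spatial one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    if np.any(nb == 0.0):
        raise ValueError("cannot reject off a zero vector")
    bhat = b / nb
    return a - np.sum(a * bhat, axis=-1, keepdims=True) * bhat


def rejection_pairs(v: DirectionUnitField, nlist: NeighborList) -> RejectionPair:
    if v.geometric is None:
        raise ValueError("geometric direction units required")
    u = nlist.displacement / nlist.distance[:, None]
    vi = v.geometric[nlist.source]
    vj = v.geometric[nlist.target]
    # Rej off -u equals Rej off u, so u_ji rejections reuse the same axis.
    w_ij = vector_rejection(vi, u)
    w_ji = vector_rejection(vj, u)
    return RejectionPair(w_ij=w_ij, w_ji=w_ji, t_ij=w_ij, t_ji=w_ij.copy())


def dihedral_scalar(v: DirectionUnitField, nlist: NeighborList) -> np.ndarray:
    """Per directed edge (i, j):
    <Rej_{u_ij}(v_i), Rej_{u_ji}(v_j)> = sum over m in N(i), n in N(j) of
    cos(phi_mijn), with the degenerate m = j / n = i terms vanishing."""
    rej = rejection_pairs(v, nlist)
    return np.einsum("ed,ed->e", rej.w_ij, rej.w_ji)


def improper_scalar(v: DirectionUnitField, nlist: NeighborList) -> np.ndarray:
    """Per directed edge (i, j): both rejections taken of v_i (vertex-centred),
    which reduces to |Rej_{u_ij}(v_i)|^2 = sum over m, n in N(i) of
    cos(psi_mijn)."""
    rej = rejection_pairs(v, nlist)
    return np.einsum("ed,ed->e", rej.t_ij, rej.t_ji)


def geometry_scalars(config: AtomicConfiguration, cutoff: float) -> GeometryScalars:
    """Convenience: build the neighbor list and all three RGC scalars."""
    nlist = build_neighbor_list(config, cutoff)
    v = direction_units(nlist, config.n_atoms)
    return GeometryScalars(
        angle=angle_scalar(v),
        dihedral=dihedral_scalar(v, nlist),
        improper=improper_scalar(v, nlist),
    )


def _real_sh_batch(u: np.ndarray, l: int) -> np.ndarray:
    """Real orthonormal spherical harmonics of order l for unit rows of u.

    Built from SciPy's complex harmonics; the (-1)^m factor cancels the
    Condon-Shortley phase so all components are plain real combinations.
    """
    u = np.atleast_2d(u)
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    cols = []
    for m in range(-l, l + 1):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.column_stack(cols)


def spherical_harmonics(u: np.ndarray, l_max: int) -> SphericalExpansion:
    """Real orthonormal spherical harmonics Y_{l,m}(u) for l = 0..l_max.

    ``u`` must be a unit 3-vector (|u| = 1 within 1e-8); ``l_max`` in 1..4.
    Satisfies the addition theorem:
    sum_m Y_{l,m}(a) Y_{l,m}(b) = (2l+1)/(4 pi) * P_l(a . b).
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("u must be a single 3-vector")
    if abs(np.linalg.norm(u) - 1.0) > 1e-8:
        raise ValueError("u must be a unit vector")
    if not 1 <= l_max <= 4:
        raise ValueError("l_max must be in 1..4")
    values = {l: _real_sh_batch(u[None], l)[0] for l in range(l_max + 1)}
    return SphericalExpansion(values=values, l_max=l_max)


def high_order_angle_scalar(v_expanded: DirectionUnitField) -> np.ndarray:
    """Sum over orders l of <v_i^(l), v_i^(l)>; by the addition theorem this
    equals sum_l (2l+1)/(4 pi) * sum_{j,k} P_l(cos theta_jik)."""
    if v_expanded.expanded is None:
        raise ValueError("expanded direction units required")
    parts = [
        np.einsum("nm,nm->n", block, block)
        for block in v_expanded.expanded.values()
    ]
    return np.sum(parts, axis=0)


# ---------------------------------------------------------------------------
# Enumeration oracles: explicit trigonometry over angle/dihedral/improper
# tuples, never via direction units.  Quadratic-to-cubic cost, small N only.
# ---------------------------------------------------------------------------


def _check_oracle_size(n: int) -> None:
    if n > _ORACLE_MAX_ATOMS:
        raise ValueError(
            f"enumeration oracles are restricted to N <= {_ORACLE_MAX_ATOMS}"
        )


def _neighbor_sets(config: AtomicConfiguration, cutoff: float):
    nlist = build_neighbor_list(config, cutoff)
    nbrs: list[list[int]] = [[] for _ in range(config.n_atoms)]
    for i, j in nlist.pairs:
        nbrs[i].append(int(j))
    return nlist, nbrs


def _torsion_cos(a, b, c, d) -> float:
    """Cosine of the torsion angle of the chain a-b-c-d (trans -> -1)."""
    n1 = np.cross(b - a, c - b)
    n2 = np.cross(c - b, d - c)
    denom = np.linalg.norm(n1) * np.linalg.norm(n2)
    if denom == 0.0:
        raise ValueError("degenerate (collinear) torsion")
    return float(np.cos(np.arccos(np.clip(np.dot(n1, n2) / denom, -1.0, 1.0))))


def _bend_angle(center, p, q) -> float:
    """Angle p-center-q in radians."""
    a = p - center
    b = q - center
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def oracle_angle_sum(config: AtomicConfiguration, cutoff: float) -> np.ndarray:
    """Per node i: sum over ordered neighbor pairs (j, k) of cos(theta_jik)."""
    _check_oracle_size(config.n_atoms)
    R = config.coordinates
    _, nbrs = _neighbor_sets(config, cutoff)
    out = np.zeros(config.n_atoms)
    for i in range(config.n_atoms):
        total = 0.0
        for j in nbrs[i]:
            for k in nbrs[i]:
                theta = _bend_angle(R[i], R[j], R[k])
                total += np.cos(theta)
        out[i] = total
    return out


def oracle_dihedral_sum(config: AtomicConfiguration, cutoff: float) -> np.ndarray:
    """Per directed edge (i, j): sum over m in N(i), n in N(j) of
    sin(theta_mij) sin(theta_ijn) cos(phi_mijn) — the inner product of unit
    rejections written in explicit trigonometric form."""
    _check_oracle_size(config.n_atoms)
    R = config.coordinates
    nlist, nbrs = _neighbor_sets(config, cutoff)
    out = np.zeros(nlist.n_pairs)
    for e, (i, j) in enumerate(nlist.pairs):
        total = 0.0
        for m in nbrs[i]:
            if m == j:
                continue  # sin(theta) = 0 exactly
            for n in nbrs[j]:
                if n == i:
                    continue
                s1 = np.sin(_bend_angle(R[i], R[m], R[j]))
                s2 = np.sin(_bend_angle(R[j], R[i], R[n]))
                if s1 == 0.0 or s2 == 0.0:
                    continue
                total += s1 * s2 * _torsion_cos(R[m], R[i], R[j], R[n])
        out[e] = total
    return out


def oracle_improper_sum(config: AtomicConfiguration, cutoff: float) -> np.ndarray:
    """Per directed edge (i, j): sum over m, n in N(i) of
    sin(theta_mij) sin(theta_nij) cos(psi_mijn), psi being the angle between
    the planes (m, i, j) and (n, i, j) about the shared edge."""
    _check_oracle_size(config.n_atoms)
    R = config.coordinates
    nlist, nbrs = _neighbor_sets(config, cutoff)
    out = np.zeros(nlist.n_pairs)
    for e, (i, j) in enumerate(nlist.pairs):
        total = 0.0
        for m in nbrs[i]:
            if m == j:
                continue
            for n in nbrs[i]:
                if n == j:
                    continue
                t1 = _bend_angle(R[i], R[m], R[j])
                t2 = _bend_angle(R[i], R[n], R[j])
                s1, s2 = np.sin(t1), np.sin(t2)
                if s1 == 0.0 or s2 == 0.0:
                    continue
                n1 = np.cross(R[m] - R[i], R[j] - R[i])
                n2 = np.cross(R[n] - R[i], R[j] - R[i])
                denom = np.linalg.norm(n1) * np.linalg.norm(n2)
                if denom == 0.0:
                    continue
                psi = np.arccos(np.clip(np.dot(n1, n2) / denom, -1.0, 1.0))
                total += s1 * s2 * np.cos(psi)
        out[e] = total
    return out


def oracle_high_order_angle_sum(
    config: AtomicConfiguration, cutoff: float, l_max: int
) -> np.ndarray:
    """Per node: sum_l (2l+1)/(4 pi) sum_{j,k} P_l(cos theta_jik) by direct
    Legendre evaluation over neighbor pairs."""
    _check_oracle_size(config.n_atoms)
    R = config.coordinates
    _, nbrs = _neighbor_sets(config, cutoff)
    out = np.zeros(config.n_atoms)
    for i in range(config.n_atoms):
        total = 0.0
        for j in nbrs[i]:
            for k in nbrs[i]:
                c = np.cos(_bend_angle(R[i], R[j], R[k]))
                for l in range(1, l_max + 1):
                    total += (2 * l + 1) / (4 * np.pi) * eval_legendre(l, c)
        out[i] = total
    return out
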