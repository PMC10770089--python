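"""Equivariant vector-scalar message-passing network.

The model keeps three embeddings per configuration: an invariant per-node
scalar ``h`` (N, F), an invariant per-directed-edge scalar ``f`` (E, F) and an
equivariant per-node vector ``v`` (N, M, F), where M = sum_{l=1..l_max}(2l+1)
stacks the spherical-harmonic orders of the direction-unit channels (M = 3 in
the plain geometric case).  Scalars gate vectors (Scalar2Vec) and vector inner
products — channelwise angle and rejection-based dihedral/improper terms —
feed back into the scalars (Vec2Scalar).

The implementation runs on ``autograd.numpy`` so that forces are exact
negative energy gradients and force-loss training can differentiate through
the force computation.  All arithmetic is float64.

Vector channels never receive an additive bias; every update is built from
rotation-equivariant primitives, so scalar outputs are rotation/translation
invariant and forces equivariant by construction (and by test).
"""

from __future__ import annotations

import io
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import autograd.numpy as anp
import numpy as np
import yaml
from autograd import grad

from .structures_io import AtomicConfiguration, NeighborList, build_neighbor_list

__all__ = [
    "ModelConfig",
    "BlockState",
    "init_params",
    "total_energy",
    "predict_energy",
    "predict_forces",
    "predict_energy_forces",
    "predict_dipole",
    "predict_spatial_extent",
    "predict_scalar",
    "save_checkpoint",
    "load_checkpoint",
    "cosine_cutoff",
    "expnorm_rbf",
    "expand_directions",
    "Potential",
]

_SH_C1 = math.sqrt(3.0 / (4.0 * math.pi))


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference settings for molecular-dynamics datasets
    (9 blocks, 256-dim embeddings, 5 Angstrom cutoff); desk-scale tests use
    much smaller instances.
    """

    n_blocks: int = 9
    hidden_dim: int = 256
    l_max: int = 1
    cutoff: float = 5.0
    n_rbf: int = 32
    n_heads: int = 8
    activation: str = "silu"
    use_improper: bool = False
    head: str = "energy_forces"
    max_z: int = 55

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.l_max not in (1, 2):
            raise ValueError("l_max must be 1 or 2")
        if self.head not in ("energy_forces", "dipole", "spatial_extent", "scalar"):
            raise ValueError(f"unknown head: {self.head}")
        if self.activation != "silu":
            raise ValueError("only 'silu' activation is supported")

    @property
    def n_vector_components(self) -> int:
        return sum(2 * l + 1 for l in range(1, self.l_max + 1))


@dataclass
class BlockState:
    """Intermediate embeddings exposed for inspection and testing."""

    h: np.ndarray  # (N, F) invariant node scalars
    f: np.ndarray  # (E, F) invariant edge scalars
    v: np.ndarray  # (N, M, F) equivariant node vectors


# ---------------------------------------------------------------------------
# Differentiable primitives
# ---------------------------------------------------------------------------


def _silu(x):
    # x * sigmoid(x) written via tanh for numerical stability under autograd
    return x * 0.5 * (1.0 + anp.tanh(0.5 * x))


def cosine_cutoff(r, cutoff: float):
    """Smooth radial weight: 0.5 (cos(pi r / r_c) + 1), exactly 0 at r = r_c,
    1 at r = 0, monotone nonincreasing on [0, r_c]."""
    return 0.5 * (anp.cos(anp.pi * r / cutoff) + 1.0) * (r <= cutoff)


def expnorm_rbf(r, cutoff: float, n_rbf: int):
    """Exponential-normal radial basis on exp(-r) abscissae; values in [0, 1],
    smooth in r."""
    means = anp.linspace(math.exp(-cutoff), 1.0, n_rbf)
    beta = (2.0 / n_rbf * (1.0 - math.exp(-cutoff))) ** -2
    return anp.exp(-beta * (anp.exp(-r)[:, None] - means[None, :]) ** 2)


def expand_directions(u, l_max: int):
    """Real spherical-harmonic features of unit vectors u (E, 3) -> (E, M).

    Order l = 1 is sqrt(3/4pi) * (x, y, z) — Cartesian component order, a
    fixed orthogonal remix of the conventional m = -1..1 layout, so all inner
    products agree with the standard convention.  Order l = 2 uses the
    standard real harmonics.
    """
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    cols = [_SH_C1 * x, _SH_C1 * y, _SH_C1 * z]
    if l_max >= 2:
        c = 0.5 * math.sqrt(15.0 / math.pi)
        cols += [
            c * x * y,
            c * y * z,
            0.25 * math.sqrt(5.0 / math.pi) * (3.0 * z * z - 1.0),
            c * x * z,
            0.25 * math.sqrt(15.0 / math.pi) * (x * x - y * y),
        ]
    return anp.stack(cols, axis=1)


def _order_slices(l_max: int) -> list[slice]:
    out, start = [], 0
    for l in range(1, l_max + 1):
        out.append(slice(start, start + 2 * l + 1))
        start += 2 * l + 1
    return out


def _reject_expanded(a, U, slices):
    """Per-order vector rejection of channelled vectors a (E, M, F) off the
    direction features U (E, M).  Within each order block the rejection is
    a - <a, u> u / |u|^2; |Y_l(u)|^2 is a nonzero constant for unit u.
    Rejection is invariant to the sign of the axis, so the same U serves both
    edge directions (odd orders flip sign, even orders are already even).
    """
    parts = []
    for sl in slices:
        Ub = U[:, sl]
        n2 = anp.sum(Ub * Ub, axis=1)[:, None]
        coef = anp.sum(a[:, sl, :] * Ub[:, :, None], axis=1) / n2
        parts.append(a[:, sl, :] - coef[:, None, :] * Ub[:, :, None])
    return anp.concatenate(parts, axis=1)


def _layernorm(x, gain, bias, eps: float = 1e-6):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps) * gain + bias


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------


def _linear_init(rng, fan_in: int, fan_out: int, bias: bool = True):
    bound = 1.0 / math.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    if bias:
        return {"W": W, "b": np.zeros(fan_out)}
    return {"W": W}


def init_params(cfg: ModelConfig, seed: int = 0) -> dict:
    """Draw all learnable arrays; uniform fan-based weights, zero biases,
    no biases on any vector pathway.  Fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    F = cfg.hidden_dim
    K = cfg.n_rbf
    params: dict[str, Any] = {
        "atom_emb": rng.uniform(-1.0, 1.0, size=(cfg.max_z, F)) / math.sqrt(F),
        "embed": {
            "filter": _linear_init(rng, K, F),
            "fuse": _linear_init(rng, 2 * F, F),
            "ln_gain": np.ones(F),
            "ln_bias": np.zeros(F),
            "edge": _linear_init(rng, K, F),
        },
        "blocks": [],
        "output": [],
    }
    for _ in range(cfg.n_blocks):
        blk = {
            "Wq": _linear_init(rng, F, F),
            "Wk": _linear_init(rng, F, F),
            "Wval": _linear_init(rng, F, F),
            "dense_k": _linear_init(rng, F, F),
            "dense_v": _linear_init(rng, F, F),
            "dense_u": _linear_init(rng, F, F),
            "dense_w": _linear_init(rng, F, F),
            "Wvm": _linear_init(rng, F, F),
            "Wvch": _linear_init(rng, F, F, bias=False),
            "Wt": _linear_init(rng, F, F, bias=False),
            "Ws": _linear_init(rng, F, F, bias=False),
            "Wangle": _linear_init(rng, F, F),
            "Wres": _linear_init(rng, F, F),
            "WRt": _linear_init(rng, F, F, bias=False),
            "WRs": _linear_init(rng, F, F, bias=False),
            "dense_dihedral": _linear_init(rng, F, F),
            "ln_gain": np.ones(F),
            "ln_bias": np.zeros(F),
        }
        if cfg.use_improper:
            blk["WIt"] = _linear_init(rng, F, F, bias=False)
            blk["WIs"] = _linear_init(rng, F, F, bias=False)
            blk["dense_improper"] = _linear_init(rng, F, F)
        params["blocks"].append(blk)
    # two gated equivariant output blocks: F -> F // 2 -> 1
    dims = [F, max(F // 2, 1), 1]
    for fin, fout in zip(dims[:-1], dims[1:]):
        params["output"].append(
            {
                "Wo1": _linear_init(rng, fin, fout, bias=False),
                "dense_o2": _linear_init(rng, fin + fout, fout),
                "Wo3": _linear_init(rng, fout, fout),
                "Wo4": _linear_init(rng, fin, fout, bias=False),
                "Wo5": _linear_init(rng, fout, fout),
            }
        )
    return params


def _lin(x, p):
    y = x @ p["W"]
    if "b" in p:
        y = y + p["b"]
    return y


def _dense(x, p):
    return _silu(_lin(x, p))


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def _forward_atomwise(params, cfg: ModelConfig, z, R, ei, ej, scat):
    """Returns (h_out (N,), v_out (N, M, 1)) for one (possibly batched,
    block-diagonal) graph.  ``scat`` is the (N, E) 0/1 aggregation matrix;
    ``z``, ``ei``, ``ej`` are constants of the graph topology."""
    n_atoms = len(z)
    F = cfg.hidden_dim
    H = cfg.n_heads
    M = cfg.n_vector_components
    slices = _order_slices(cfg.l_max)
    n_edges = len(ei)

    x = params["atom_emb"][z]  # (N, F)
    if n_edges > 0:
        d = R[ej] - R[ei]
        r = anp.sqrt(anp.sum(d * d, axis=1))
        u = d / r[:, None]
        U = expand_directions(u, cfg.l_max)  # (E, M)
        cut = cosine_cutoff(r, cfg.cutoff)  # (E,)
        rbf = expnorm_rbf(r, cfg.cutoff, cfg.n_rbf)  # (E, K)
        emb = params["embed"]
        filt = _lin(rbf, emb["filter"]) * cut[:, None]
        nbr = scat @ (filt * x[ej])
        f = _lin(rbf, emb["edge"])
    else:
        emb = params["embed"]
        nbr = anp.zeros((n_atoms, F))
        f = anp.zeros((0, F))
    h = _layernorm(
        _lin(anp.concatenate([x, nbr], axis=1), emb["fuse"]),
        emb["ln_gain"],
        emb["ln_bias"],
    )
    v = anp.zeros((n_atoms, M, F))

    for blk in params["blocks"]:
        # invariant layer norm on node scalars keeps attention scores bounded
        h = _layernorm(h, blk["ln_gain"], blk["ln_bias"])
        if n_edges > 0:
            # edge-fusion attention: activation-scored per head, no softmax
            q = _lin(h, blk["Wq"])[ei].reshape(n_edges, H, F // H)
            k = (_lin(h, blk["Wk"])[ej] * _dense(f, blk["dense_k"])).reshape(
                n_edges, H, F // H
            )
            score = anp.sum(q * k, axis=2)  # (E, H)
            alpha = _silu(score)
            val = (_lin(h, blk["Wval"])[ej] * _dense(f, blk["dense_v"])).reshape(
                n_edges, H, F // H
            )
            m_edge = (alpha[:, :, None] * val).reshape(n_edges, F) * cut[:, None]
            # vector messages, cutoff-weighted so they vanish smoothly at r_c
            s_u = _dense(m_edge, blk["dense_u"])
            s_w = _dense(m_edge, blk["dense_w"])
            vm_edge = (
                s_u[:, None, :] * U[:, :, None] + s_w[:, None, :] * v[ej]
            ) * cut[:, None, None]
            m_i = scat @ m_edge  # (N, F)
            vec_m = (scat @ vm_edge.reshape(n_edges, M * F)).reshape(n_atoms, M, F)
        else:
            m_i = anp.zeros((n_atoms, F))
            vec_m = anp.zeros((n_atoms, M, F))

        # Scalar2Vec: gated residual on the vector channels
        dv = vec_m + _lin(m_i, blk["Wvm"])[:, None, :] * (v @ blk["Wvch"]["W"])
        v = v + dv

        # Vec2Scalar: channelwise runtime angle term on nodes
        inner = anp.sum((v @ blk["Wt"]["W"]) * (v @ blk["Ws"]["W"]), axis=1)
        dh = inner * _lin(m_i, blk["Wangle"]) + _lin(m_i, blk["Wres"])
        h = h + dh

        if n_edges > 0:
            # channelwise runtime dihedral term on edges
            rt = _reject_expanded((v @ blk["WRt"]["W"])[ei], U, slices)
            rs = _reject_expanded((v @ blk["WRs"]["W"])[ej], U, slices)
            df = anp.sum(rt * rs, axis=1) * _dense(f, blk["dense_dihedral"])
            if cfg.use_improper:
                it_ = _reject_expanded((v @ blk["WIt"]["W"])[ei], U, slices)
                is_ = _reject_expanded((v @ blk["WIs"]["W"])[ei], U, slices)
                df = df + anp.sum(it_ * is_, axis=1) * _dense(
                    f, blk["dense_improper"]
                )
            f = f + df

    for ob in params["output"]:
        vn = v @ ob["Wo1"]["W"]  # (N, M, Fout)
        norms = anp.sqrt(anp.sum(vn * vn, axis=1) + 1e-32)
        t = _dense(anp.concatenate([norms, h], axis=1), ob["dense_o2"])
        h = _lin(t, ob["Wo3"])
        v = (v @ ob["Wo4"]["W"]) * _lin(t, ob["Wo5"])[:, None, :]

    return h[:, 0], v


def embedding_state(
    params, cfg: ModelConfig, config: AtomicConfiguration
) -> BlockState:
    """The initial embeddings h0, f0, v0 = 0 (pre message passing)."""
    _validate_species(cfg, config)
    nlist = build_neighbor_list(config, cfg.cutoff)
    ei, ej = nlist.source, nlist.target
    scat = _scatter_matrix(config.n_atoms, ei)
    n_edges = nlist.n_pairs
    x = params["atom_emb"][config.atomic_numbers]
    emb = params["embed"]
    if n_edges > 0:
        r = nlist.distance
        cut = cosine_cutoff(r, cfg.cutoff)
        rbf = expnorm_rbf(r, cfg.cutoff, cfg.n_rbf)
        filt = _lin(rbf, emb["filter"]) * cut[:, None]
        nbr = scat @ (filt * x[ej])
        f = _lin(rbf, emb["edge"])
    else:
        nbr = np.zeros_like(x)
        f = np.zeros((0, cfg.hidden_dim))
    h = _layernorm(
        _lin(np.concatenate([x, nbr], axis=1), emb["fuse"]),
        emb["ln_gain"],
        emb["ln_bias"],
    )
    v = np.zeros((config.n_atoms, cfg.n_vector_components, cfg.hidden_dim))
    return BlockState(h=np.asarray(h), f=np.asarray(f), v=v)


def _scatter_matrix(n_atoms: int, ei) -> np.ndarray:
    scat = np.zeros((n_atoms, len(ei)))
    scat[ei, np.arange(len(ei))] = 1.0
    return scat


def _graph_constants(cfg: ModelConfig, config: AtomicConfiguration):
    nlist = build_neighbor_list(config, cfg.cutoff)
    ei = nlist.source
    ej = nlist.target
    return ei, ej, _scatter_matrix(config.n_atoms, ei)


def _validate_species(cfg: ModelConfig, config: AtomicConfiguration) -> None:
    if np.any(config.atomic_numbers >= cfg.max_z):
        raise ValueError("atomic number outside the embedding table")


# ---------------------------------------------------------------------------
# Property heads
# ---------------------------------------------------------------------------


def total_energy(
    params, cfg: ModelConfig, config: AtomicConfiguration, R=None
) -> float:
    """Sum of the final per-node scalars, in kcal/mol.  The neighbor list is
    built from the configuration's coordinates; passing ``R`` evaluates the
    same graph at displaced coordinates (used for differentiation)."""
    _validate_species(cfg, config)
    ei, ej, scat = _graph_constants(cfg, config)
    if R is None:
        R = config.coordinates
    h, _ = _forward_atomwise(params, cfg, config.atomic_numbers, R, ei, ej, scat)
    return anp.sum(h)


def predict_energy(params, cfg: ModelConfig, config: AtomicConfiguration) -> float:
    return float(total_energy(params, cfg, config))


def predict_energy_forces(params, cfg: ModelConfig, config: AtomicConfiguration):
    """Energy and exact forces F = -dE/dR from reverse-mode differentiation."""
    _validate_species(cfg, config)
    ei, ej, scat = _graph_constants(cfg, config)
    z = config.atomic_numbers

    def energy_of(R):
        h, _ = _forward_atomwise(params, cfg, z, R, ei, ej, scat)
        return anp.sum(h)

    R0 = config.coordinates
    return float(energy_of(R0)), -grad(energy_of)(R0)


def predict_forces(params, cfg: ModelConfig, config: AtomicConfiguration):
    return predict_energy_forces(params, cfg, config)[1]


def _final_state(params, cfg: ModelConfig, config: AtomicConfiguration):
    _validate_species(cfg, config)
    ei, ej, scat = _graph_constants(cfg, config)
    h, v = _forward_atomwise(
        params, cfg, config.atomic_numbers, config.coordinates, ei, ej, scat
    )
    return np.asarray(h), np.asarray(v)


def dipole_moment(h, v_cart, coordinates, masses) -> float:
    """|sum_i v_i + h_i (r_i - r_com)| from per-atom scalars ``h`` (N,) and
    Cartesian vector outputs ``v_cart`` (N, 3)."""
    h = np.asarray(h, dtype=float)
    com = (masses[:, None] * coordinates).sum(axis=0) / masses.sum()
    rel = coordinates - com
    return float(np.linalg.norm((v_cart + h[:, None] * rel).sum(axis=0)))


def spatial_extent(h, coordinates, masses) -> float:
    """sum_i h_i |r_i - r_com|^2."""
    h = np.asarray(h, dtype=float)
    com = (masses[:, None] * coordinates).sum(axis=0) / masses.sum()
    rel = coordinates - com
    return float(np.sum(h * np.sum(rel * rel, axis=1)))


def predict_dipole(params, cfg: ModelConfig, config: AtomicConfiguration) -> float:
    """Dipole magnitude from the final scalars and the Cartesian (l = 1) part
    of the final vector embedding; translation- and rotation-invariant."""
    h, v = _final_state(params, cfg, config)
    v_cart = v[:, :3, 0] / _SH_C1
    return dipole_moment(h, v_cart, config.coordinates, config.masses)


def predict_spatial_extent(
    params, cfg: ModelConfig, config: AtomicConfiguration
) -> float:
    h, _ = _final_state(params, cfg, config)
    return spatial_extent(h, config.coordinates, config.masses)


def predict_scalar(params, cfg: ModelConfig, config: AtomicConfiguration) -> float:
    """Plain sum of the final per-node scalars (shared with the energy head)."""
    h, _ = _final_state(params, cfg, config)
    return float(np.sum(h))


class Potential:
    """Callable adapter: configuration -> (energy, forces), for MD drivers."""

    def __init__(self, params, cfg: ModelConfig):
        self.params = params
        self.cfg = cfg

    def __call__(self, config: AtomicConfiguration):
        return predict_energy_forces(self.params, self.cfg, config)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive holding the YAML config + named arrays
# ---------------------------------------------------------------------------


def _flatten_params(params, prefix: str = "") -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    if isinstance(params, dict):
        for key, val in params.items():
            flat.update(_flatten_params(val, f"{prefix}{key}."))
    elif isinstance(params, list):
        for idx, val in enumerate(params):
            flat.update(_flatten_params(val, f"{prefix}{idx}."))
    else:
        flat[prefix[:-1]] = np.asarray(params)
    return flat


def _set_nested(container, keys: list[str], value) -> None:
    head = keys[0]
    if head.isdigit():
        head = int(head)
        while len(container) <= head:
            container.append(None)
    if len(keys) == 1:
        container[head] = value
        return
    nxt_is_idx = keys[1].isdigit()
    if isinstance(head, int):
        if container[head] is None:
            container[head] = [] if nxt_is_idx else {}
        _set_nested(container[head], keys[1:], value)
    else:
        if head not in container:
            container[head] = [] if nxt_is_idx else {}
        _set_nested(container[head], keys[1:], value)


def save_checkpoint(path, cfg: ModelConfig, params) -> None:
    payload = {f"param.{k}": v for k, v in _flatten_params(params).items()}
    payload["config_yaml"] = np.frombuffer(
        yaml.safe_dump(asdict(cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path):
    with np.load(path) as data:
        cfg = ModelConfig(
            **yaml.safe_load(io.BytesIO(data["config_yaml"].tobytes()))
        )
        params: dict = {}
        for key in data.files:
            if key.startswith("param."):
                arr = data[key]
                _set_nested(params, key[len("param.") :].split("."), arr)
    return cfg, params
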