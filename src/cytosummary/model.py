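"""Permutation-invariant Deep Sets aggregator f(X) = rho(sum_m phi(x_m)).

phi is a single fully connected layer (D -> N) with leaky-ReLU activation;
the cell dimension is collapsed by summation; rho is two fully connected
layers (N -> H -> L), each followed by a leaky ReLU. Implemented directly on
numpy arrays — the layers are small dense affine maps, and the training loop
(see :mod:`cytosummary.training`) backpropagates through this same code.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProfileTable, SampleSet, SingleCellTable

__all__ = [
    "ModelDims",
    "AggregatorModel",
    "ForwardState",
    "CheckpointError",
    "init_model",
    "forward",
    "aggregate_table",
    "save_model",
    "load_model",
]

_CHECKPOINT_VERSION = 1
_PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")


class CheckpointError(RuntimeError):
    """Checkpoint file unreadable or inconsistent with the requested model."""


@dataclass(frozen=True)
class ModelDims:
    """Layer widths: input D, phi width N, rho hidden H, output L."""

    D: int
    N: int = 2048
    H: int = 512
    L: int = 2048

    def __post_init__(self) -> None:
        for name in ("D", "N", "H", "L"):
            if getattr(self, name) < 1:
                raise ValueError(f"dimension {name} must be positive")


@dataclass
class AggregatorModel:
    """Weights of phi and rho plus architecture metadata; serializable."""

    dims: ModelDims
    slope: float  # leaky-ReLU negative slope
    seed: int
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "AggregatorModel":
        return AggregatorModel(
            dims=self.dims,
            slope=self.slope,
            seed=self.seed,
            params={k: v.copy() for k, v in self.params.items()},
        )

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.params.values())


@dataclass
class ForwardState:
    """Intermediates of one forward pass, retained for backprop and CPA."""

    X: np.ndarray    # M x D input
    A1: np.ndarray   # M x N pre-activation of the first layer
    H1: np.ndarray   # M x N post-activation (phi outputs)
    z: np.ndarray    # N pooled representation
    a2: np.ndarray
    h2: np.ndarray
    a3: np.ndarray
    v: np.ndarray    # L output profile


def _pool_rows(H: np.ndarray) -> np.ndarray:
    """Sum rows by balanced recursive halving.

    The midpoint split makes the pooled sum self-similar under set
    concatenation: pooling the stacked set [X; X] splits into two identical
    halves, so z(X ⊎ X) equals 2 * z(X) exactly in floating point.
    """
    n = H.shape[0]
    if n == 1:
        return H[0].copy()
    k = n // 2
    return _pool_rows(H[:k]) + _pool_rows(H[k:])


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def init_model(
    D: int, dims: ModelDims | None = None, slope: float = 0.01, seed: int = 0
) -> AggregatorModel:
    """Build a model with fan-in-scaled uniform (Kaiming-style) weights.

    Each weight matrix is drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)); biases
    start at zero. Reproducible given ``seed``.
    """
    dims = dims if dims is not None else ModelDims(D=D)
    if dims.D != D:
        raise ValueError(f"dims.D={dims.D} does not match feature count D={D}")
    rng = np.random.default_rng(seed)

    def uniform(fan_in: int, shape) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    params = {
        "W1": uniform(dims.D, (dims.D, dims.N)),
        "b1": np.zeros(dims.N),
        "W2": uniform(dims.N, (dims.N, dims.H)),
        "b2": np.zeros(dims.H),
        "W3": uniform(dims.H, (dims.H, dims.L)),
        "b3": np.zeros(dims.L),
    }
    return AggregatorModel(dims=dims, slope=slope, seed=seed, params=params)


def forward(
    model: AggregatorModel, X: SampleSet | np.ndarray, keep_state: bool = False
):
    """Aggregate one set: v = rho(sum_m phi(x_m)).

    Returns the length-L profile vector, or a :class:`ForwardState` when
    ``keep_state`` is set (needed for backprop, sensitivity analysis, and
    first-layer activations for critical-point analysis).
    """
    mat = X.X if isinstance(X, SampleSet) else np.asarray(X, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("input set must be M x D with M >= 1")
    d = model.dims
    if mat.shape[1] != d.D:
        raise ValueError(f"feature count {mat.shape[1]} != model D={d.D}")
    p, s = model.params, model.slope
    # einsum keeps each row's affine map bitwise independent of M (BLAS gemm
    # switches kernels with shape), preserving exact sum-pooling linearity
    A1 = np.einsum("md,dn->mn", mat, p["W1"]) + p["b1"]
    H1 = _leaky(A1, s)
    z = _pool_rows(H1)
    a2 = z @ p["W2"] + p["b2"]
    h2 = _leaky(a2, s)
    a3 = h2 @ p["W3"] + p["b3"]
    v = _leaky(a3, s)
    if keep_state:
        return ForwardState(X=mat, A1=A1, H1=H1, z=z, a2=a2, h2=h2, a3=a3, v=v)
    return v


def backward_view(
    model: AggregatorModel, state: ForwardState, dv: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backpropagate a gradient w.r.t. the output v of one view.

    Returns (parameter gradients, gradient w.r.t. the input matrix X).
    """
    p, s = model.params, model.slope
    da3 = dv * _leaky_grad(state.a3, s)
    gW3 = np.outer(state.h2, da3)
    gb3 = da3
    dh2 = p["W3"] @ da3
    da2 = dh2 * _leaky_grad(state.a2, s)
    gW2 = np.outer(state.z, da2)
    gb2 = da2
    dz = p["W2"] @ da2
    dH1 = np.broadcast_to(dz, state.H1.shape)
    dA1 = dH1 * _leaky_grad(state.A1, s)
    gW1 = state.X.T @ dA1
    gb1 = dA1.sum(axis=0)
    dX = dA1 @ p["W1"].T
    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
    return grads, dX


def aggregate_table(model: AggregatorModel, table: SingleCellTable) -> ProfileTable:
    """One learned profile per well; all cells are used (no subsampling)."""
    metas, rows = [], []
    for s in table.iter_wells():
        mask = (
            (table.meta["plate_id"] == s.well_key.plate_id)
            & (table.meta["well_id"] == s.well_key.well_id)
        ).to_numpy()
        first = int(np.flatnonzero(mask)[0])
        metas.append(
            {
                "plate_id": s.well_key.plate_id,
                "well_id": s.well_key.well_id,
                "compound_id": s.well_key.compound_id,
                "moa": table.meta["moa"].iloc[first],
                "dose": table.meta["dose"].iloc[first],
            }
        )
        rows.append(forward(model, s))
    return ProfileTable(meta=pd.DataFrame(metas), values=np.vstack(rows), method="model")


def save_model(model: AggregatorModel, path) -> str:
    """Write a self-describing .npz checkpoint with a versioned JSON header."""
    header = json.dumps(
        {
            "version": _CHECKPOINT_VERSION,
            "dims": {k: getattr(model.dims, k) for k in ("D", "N", "H", "L")},
            "slope": model.slope,
            "seed": model.seed,
        }
    )
    np.savez(
        path,
        __header__=np.array(header),
        **{k: model.params[k] for k in _PARAM_NAMES},
    )
    return str(path)


def load_model(path, expect_D: int | None = None) -> AggregatorModel:
    """Load a checkpoint; verifies header, shapes, and (optionally) D."""
    try:
        with np.load(path, allow_pickle=False) as blob:
            header = json.loads(str(blob["__header__"]))
            params = {k: blob[k].copy() for k in _PARAM_NAMES}
    except (OSError, KeyError, ValueError, zipfile.BadZipFile, json.JSONDecodeError) as exc:
        raise CheckpointError(f"unreadable checkpoint {path}: {exc}") from exc
    if header.get("version") != _CHECKPOINT_VERSION:
        raise CheckpointError(f"unsupported checkpoint version {header.get('version')}")
    dims = ModelDims(**header["dims"])
    if expect_D is not None and dims.D != expect_D:
        raise CheckpointError(f"checkpoint D={dims.D} does not match expected D={expect_D}")
    expected_shapes = {
        "W1": (dims.D, dims.N), "b1": (dims.N,),
        "W2": (dims.N, dims.H), "b2": (dims.H,),
        "W3": (dims.H, dims.L), "b3": (dims.L,),
    }
    for k, shape in expected_shapes.items():
        if params[k].shape != shape:
            raise CheckpointError(f"parameter {k} has shape {params[k].shape}, expected {shape}")
    return AggregatorModel(
        dims=dims, slope=float(header["slope"]), seed=int(header["seed"]), params=params
    )
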