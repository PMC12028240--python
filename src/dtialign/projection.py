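"""Projection heads: linear or n-layer MLP maps into the shared space.

``depth`` counts affine layers: depth 0 is a single affine (linear)
projection; depth n >= 1 chains n affine layers with the activation applied
after every layer except the last, so a "2-layer non-linear" head is two
affine maps with one activation between them.

Heads are plain numpy parameter stacks with hand-written forward/backward
passes; analytic gradients are validated against central finite differences
in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import erf

__all__ = [
    "ProjectionConfig",
    "ProjectionHead",
    "init_projection",
    "project",
    "save_checkpoint",
    "load_checkpoint",
]

_SQRT2 = float(np.sqrt(2.0))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(np.float64)


def _tanh_grad(x):
    return 1.0 - np.tanh(x) ** 2


def _gelu(x):
    # exact Gaussian-CDF form, x * Phi(x)
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    phi = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * phi


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "gelu": (_gelu, _gelu_grad),
}


@dataclass(frozen=True)
class ProjectionConfig:
    """Architecture and initialization seed of one projection head.

    hidden_dim defaults to output_dim when unset; activation is one of
    {'relu', 'tanh', 'gelu'}.
    """

    input_dim: int
    output_dim: int = 256
    depth: int = 0
    hidden_dim: int | None = None
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("input_dim and output_dim must be positive")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.hidden_dim is not None and self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; supported: {sorted(ACTIVATIONS)}"
            )

    @property
    def effective_hidden_dim(self) -> int:
        return self.output_dim if self.hidden_dim is None else self.hidden_dim

    def layer_shapes(self) -> list[tuple[int, int]]:
        """Fan-in/fan-out pairs for each affine layer."""
        if self.depth == 0:
            return [(self.input_dim, self.output_dim)]
        h = self.effective_hidden_dim
        dims = [self.input_dim] + [h] * (self.depth - 1) + [self.output_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class ProjectionHead:
    """Parameters of one head: an ordered list of (weight, bias) layers.

    Weights are stored (fan_in, fan_out); ``forward`` maps an
    (n, input_dim) matrix to (n, output_dim) row-wise.
    """

    config: ProjectionConfig
    layers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    # --- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Apply the head row-wise; pass ``cache=[]`` to record the
        intermediate values needed by :meth:`backward`."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has shape {X.shape}, expected (n, {self.config.input_dim})"
            )
        act, _ = ACTIVATIONS[self.config.activation]
        h = X
        last = len(self.layers) - 1
        for i, (W, b) in enumerate(self.layers):
            pre = h @ W + b
            if cache is not None:
                cache.append((h, pre))
            h = act(pre) if i < last else pre
        return h

    def backward(
        self, grad_out: np.ndarray, cache: list
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Backpropagate d(loss)/d(output); returns (d(loss)/d(input),
        per-layer (dW, db)) for the cache recorded by :meth:`forward`."""
        _, act_grad = ACTIVATIONS[self.config.activation]
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)  # type: ignore[list-item]
        g = np.asarray(grad_out, dtype=np.float64)
        last = len(self.layers) - 1
        for i in range(last, -1, -1):
            inp, pre = cache[i]
            if i < last:
                g = g * act_grad(pre)
            grads[i] = (inp.T @ g, g.sum(axis=0))
            g = g @ self.layers[i][0].T
        return g, grads

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in self.layers])

    def set_flat_params(self, flat: np.ndarray) -> None:
        pos = 0
        new_layers = []
        for W, b in self.layers:
            w = flat[pos : pos + W.size].reshape(W.shape)
            pos += W.size
            bb = flat[pos : pos + b.size].copy()
            pos += b.size
            new_layers.append((w.copy(), bb))
        self.layers = new_layers


def init_projection(config: ProjectionConfig) -> ProjectionHead:
    """Initialize a head with fan-in-scaled uniform weights.

    Each layer's weights and biases are drawn from
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)) using ``numpy.random.default_rng``
    seeded with ``config.seed``, so the same config reproduces bit-identical
    parameters on any platform.
    """
    rng = np.random.default_rng(config.seed)
    layers = []
    for fan_in, fan_out in config.layer_shapes():
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        layers.append((W, b))
    return ProjectionHead(config=config, layers=layers)


def project(head: ProjectionHead, matrix: np.ndarray) -> np.ndarray:
    """Map rows of ``matrix`` into the shared space (functional wrapper)."""
    return head.forward(matrix)


# --- checkpointing ----------------------------------------------------------


class CheckpointError(ValueError):
    """A checkpoint file is missing fields or structurally corrupted."""


def _head_to_dict(head: ProjectionHead) -> dict:
    return {
        "config": asdict(head.config),
        "layers": [{"weight": W.tolist(), "bias": b.tolist()} for W, b in head.layers],
    }


def _head_from_dict(data: dict) -> ProjectionHead:
    try:
        config = ProjectionConfig(**data["config"])
        layers = [
            (
                np.array(layer["weight"], dtype=np.float64),
                np.array(layer["bias"], dtype=np.float64),
            )
            for layer in data["layers"]
        ]
    except (KeyError, TypeError) as exc:
        raise CheckpointError(f"malformed checkpoint head record: {exc}") from None
    head = ProjectionHead(config=config, layers=layers)
    for (W, b), (fi, fo) in zip(layers, config.layer_shapes(), strict=True):
        if W.shape != (fi, fo) or b.shape != (fo,):
            raise CheckpointError(
                f"layer shape {W.shape}/{b.shape} inconsistent with config ({fi}, {fo})"
            )
    return head


def save_checkpoint(path, **heads: ProjectionHead) -> None:
    """Write named heads to a JSON checkpoint.

    Floats serialize via ``repr`` and therefore round-trip bit-exactly.
    """
    payload = {name: _head_to_dict(head) for name, head in heads.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"format": "dtialign-checkpoint-v1", "heads": payload}, fh)


def load_checkpoint(path) -> dict[str, ProjectionHead]:
    """Inverse of :func:`save_checkpoint`."""
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CheckpointError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(data, dict) or data.get("format") != "dtialign-checkpoint-v1":
        raise CheckpointError(f"{path}: not a dtialign checkpoint")
    return {name: _head_from_dict(rec) for name, rec in data["heads"].items()}
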