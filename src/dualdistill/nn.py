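"""A compact CPU training engine for small convolutional classifiers.

Implements the handful of layers the harness needs — strided 3x3
convolutions (via im2col), leaky ReLU, global average pooling, and a linear
head — with explicit forward/backward passes and momentum SGD. Weights are
He-initialised from a seeded generator, so runs are bit-reproducible on a
fixed machine.

The model registry maps architecture names to layer stacks:

* ``tiny-cnn-teacher`` — three strided conv blocks (8, 16, 32 channels),
  global average pool, linear head;
* ``tiny-cnn-student`` — two strided conv blocks (8, 16 channels), global
  average pool, linear head (roughly a quarter of the teacher's parameters).

These stand in for the large published backbones used as teachers and
students at full scale; any architecture can be slotted in by registering a
new builder.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

__all__ = [
    "ModelSpec",
    "Sequential",
    "build_model",
    "register_architecture",
    "ARCHITECTURES",
]


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class Conv2D(Layer):
    """3x3 (or kxk) convolution with stride, valid padding, via im2col."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, H, W, C) -> out: (B, Ho, Wo, out_ch)
        self.x_shape = x.shape
        k, s = self.kernel, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (B, Ho, Wo, C, k, k)
        b, ho, wo = win.shape[:3]
        self.cols = win.reshape(b, ho, wo, -1)  # C*k*k, C-major then k rows
        wmat = self.w.transpose(1, 2, 3, 0).reshape(-1, self.w.shape[0])
        self.wmat = wmat
        return self.cols @ wmat + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, ho, wo, oc = grad.shape
        k, s = self.kernel, self.stride
        gcols = grad @ self.wmat.T  # (B, Ho, Wo, C*k*k)
        cols_flat = self.cols.reshape(-1, self.cols.shape[-1])
        gw_mat = cols_flat.T @ grad.reshape(-1, oc)
        self.gw = gw_mat.reshape(
            self.w.shape[1], k, k, self.w.shape[0]
        ).transpose(3, 0, 1, 2)
        self.gb = grad.sum(axis=(0, 1, 2))

        gx = np.zeros(self.x_shape)
        gcols = gcols.reshape(b, ho, wo, self.x_shape[3], k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += gcols[
                    :, :, :, :, di, dj
                ]
        return gx

    def params_and_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class LeakyReLU(Layer):
    """Leaky rectifier; the small negative slope avoids dead units in
    narrow stacks, which otherwise stall small-model training for epochs."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self.mask, grad, self.slope * grad)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self.in_shape
        return np.broadcast_to(grad[:, None, None, :], self.in_shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw = self.x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params_and_grads(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Sequential:
    """A layer stack with logits output and momentum-SGD update."""

    def __init__(self, layers: list[Layer], name: str = "model"):
        self.layers = layers
        self.name = name
        self._velocity: list[np.ndarray] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params_and_grads())

    def sgd_step(self, lr: float, momentum: float = 0.9) -> None:
        pairs = [pg for layer in self.layers for pg in layer.params_and_grads()]
        if self._velocity is None:
            self._velocity = [np.zeros_like(p) for p, _ in pairs]
        for v, (p, g) in zip(self._velocity, pairs):
            v *= momentum
            v -= lr * g
            p += v

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, (p, _) in enumerate(layer.params_and_grads()):
                state[f"layer{i}.p{j}"] = p
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, (p, _) in enumerate(layer.params_and_grads()):
                key = f"layer{i}.p{j}"
                if state[key].shape != p.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p[...] = state[key]


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Architecture choice plus label-space size and init seed."""

    architecture: str = "tiny-cnn-student"
    n_classes: int = 10
    input_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"known: {sorted(ARCHITECTURES)}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _teacher(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    return Sequential(
        [
            Conv2D(3, 8, 3, 2, rng),
            LeakyReLU(),
            Conv2D(8, 16, 3, 2, rng),
            LeakyReLU(),
            Conv2D(16, 32, 3, 2, rng),
            LeakyReLU(),
            GlobalAvgPool(),
            Linear(32, spec.n_classes, rng),
        ],
        name=spec.architecture,
    )


def _student(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    return Sequential(
        [
            Conv2D(3, 8, 3, 2, rng),
            LeakyReLU(),
            Conv2D(8, 16, 3, 2, rng),
            LeakyReLU(),
            GlobalAvgPool(),
            Linear(16, spec.n_classes, rng),
        ],
        name=spec.architecture,
    )


ARCHITECTURES: dict[str, Callable[[ModelSpec, np.random.Generator], Sequential]] = {
    "tiny-cnn-teacher": _teacher,
    "tiny-cnn-student": _student,
}


def register_architecture(
    name: str, builder: Callable[[ModelSpec, np.random.Generator], Sequential]
) -> None:
    """Add a pluggable backbone to the registry."""
    ARCHITECTURES[name] = builder


def build_model(spec: ModelSpec) -> Sequential:
    rng = np.random.default_rng(spec.seed)
    return ARCHITECTURES[spec.architecture](spec, rng)
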