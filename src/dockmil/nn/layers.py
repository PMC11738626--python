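"""Parameterized building blocks: linear maps, MLPs and a GRU cell."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, sigmoid, tanh, relu, silu

_ACTIVATIONS = {"relu": relu, "silu": silu, "tanh": tanh, "sigmoid": sigmoid}


class Module:
    """Container tracking trainable Tensors (flat registry, no submodule magic)."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def register(self, name: str, value):
        if isinstance(value, Module):
            self._children[name] = value
        elif isinstance(value, Tensor):
            self._params[name] = value
        else:
            raise TypeError(f"cannot register {type(value)}")
        return value

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    # checkpoint (de)serialization ------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            if params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data = np.asarray(v, dtype=np.float64).copy()


class Linear(Module):
    """y = x W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = self.register("W", Tensor(rng.uniform(-bound, bound, (n_in, n_out)), True))
        self.b = self.register("b", Tensor(np.zeros(n_out), True)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class MLP(Module):
    """Stack of Linear layers with an activation between (not after) them."""

    def __init__(
        self,
        widths: list[int],
        rng: np.random.Generator,
        activation: str = "relu",
        final_activation: str | None = None,
    ):
        super().__init__()
        self.layers = [
            self.register(f"lin{i}", Linear(a, b, rng))
            for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]))
        ]
        self.act = _ACTIVATIONS[activation]
        self.final_act = _ACTIVATIONS[final_activation] if final_activation else None

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.act(x)
        if self.final_act is not None:
            x = self.final_act(x)
        return x


class GRUCell(Module):
    """Standard gated recurrent unit update h' = GRU(m, h)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.x2z = self.register("x2z", Linear(n_in, n_hidden, rng))
        self.h2z = self.register("h2z", Linear(n_hidden, n_hidden, rng, bias=False))
        self.x2r = self.register("x2r", Linear(n_in, n_hidden, rng))
        self.h2r = self.register("h2r", Linear(n_hidden, n_hidden, rng, bias=False))
        self.x2n = self.register("x2n", Linear(n_in, n_hidden, rng))
        self.h2n = self.register("h2n", Linear(n_hidden, n_hidden, rng, bias=False))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = sigmoid(self.x2z(x) + self.h2z(h))
        r = sigmoid(self.x2r(x) + self.h2r(h))
        n = tanh(self.x2n(x) + self.h2n(r * h))
        return (1.0 - z) * n + z * h


class GatedReadout(Module):
    """Gated attention-sum graph readout: r = sum_i sigmoid(f([h_i, x_i])) * tanh(g(h_i)).

    `x_i` are the input node features (skip connection), following the
    gated-graph-network readout family.
    """

    def __init__(self, n_hidden: int, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.gate = self.register("gate", Linear(n_hidden + n_in, n_out, rng))
        self.proj = self.register("proj", Linear(n_hidden, n_out, rng))

    def __call__(self, h: Tensor, x0: Tensor) -> Tensor:
        return sigmoid(self.gate(concatenate([h, x0], axis=1))) * tanh(self.proj(h))
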