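"""Model containers: a sequential stack and a parallel multi-branch merge."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


class Sequential:
    """A plain stack of layers applied in order."""

    def __init__(self, layers: list[Layer], name: str = "sequential"):
        self.layers = layers
        self.name = name

    def forward(self, x, training: bool = False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_arrays(self):
        out = []
        for layer in self.layers:
            out.extend(layer.param_arrays())
        return out

    def grads(self):
        g = {}
        for layer in self.layers:
            g.update(layer.grads())
        return g

    @property
    def n_parameters(self) -> int:
        return sum(a.size for _, a, _ in self.param_arrays())

    def per_layer_counts(self) -> list[tuple[str, int]]:
        return [(layer.name, layer.n_parameters) for layer in self.layers if layer.n_parameters]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: a.copy() for name, a, _ in self.param_arrays()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, a, _ in self.param_arrays():
            a[...] = state[name]


class MultiBranch:
    """Parallel branches whose flattened outputs are concatenated, then a head.

    ``forward`` takes a tuple of per-branch batches.  The concatenation is
    the merge step: branch b contributes columns
    ``[offset_b, offset_b + width_b)`` of the merged feature vector.
    """

    def __init__(self, branches: list[Sequential], head: Sequential, name: str = "multibranch"):
        self.branches = branches
        self.head = head
        self.name = name
        self._widths: list[int] | None = None

    def forward(self, inputs, training: bool = False):
        if len(inputs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} inputs, got {len(inputs)}")
        outs = [br.forward(x, training=training) for br, x in zip(self.branches, inputs)]
        for o in outs:
            if o.ndim != 2:
                raise ValueError("each branch must end flattened (2D batch output)")
        self._widths = [o.shape[1] for o in outs]
        merged = np.concatenate(outs, axis=1)
        return self.head.forward(merged, training=training)

    def backward(self, dout):
        dmerged = self.head.backward(dout)
        grads_in = []
        offset = 0
        for br, w in zip(self.branches, self._widths):
            grads_in.append(br.backward(dmerged[:, offset : offset + w]))
            offset += w
        return tuple(grads_in)

    def param_arrays(self):
        out = []
        for i, br in enumerate(self.branches):
            out.extend((f"branch{i}.{n}", a, t) for n, a, t in br.param_arrays())
        out.extend((f"head.{n}", a, t) for n, a, t in self.head.param_arrays())
        return out

    def grads(self):
        g = {}
        for i, br in enumerate(self.branches):
            g.update({f"branch{i}.{k}": v for k, v in br.grads().items()})
        g.update({f"head.{k}": v for k, v in self.head.grads().items()})
        return g

    @property
    def n_parameters(self) -> int:
        return sum(a.size for _, a, _ in self.param_arrays())

    def per_layer_counts(self) -> list[tuple[str, int]]:
        out = []
        for i, br in enumerate(self.branches):
            out.extend((f"branch{i}.{n}", c) for n, c in br.per_layer_counts())
        out.extend((f"head.{n}", c) for n, c in self.head.per_layer_counts())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: a.copy() for name, a, _ in self.param_arrays()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, a, _ in self.param_arrays():
            a[...] = state[name]


def clone_state(model) -> dict[str, np.ndarray]:
    return copy.deepcopy(model.state_dict())
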