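"""Multibranch classifier container: parallel branches, concatenation, softmax head."""

from __future__ import annotations

import copy

import numpy as np

from .core import Layer, Param, Sequential, softmax
from .fused import FusedEntry
from .layers import Dense


class MultibranchClassifier:
    """Parallel branches over the same epoched input, concatenated into a
    dense softmax head.

    ``forward`` returns logits; ``predict_proba`` applies the softmax.
    When every branch starts with a :class:`FusedEntry` sharing one FFT
    length, the input spectrum is computed once per batch and reused.
    """

    def __init__(self, branches: list[Sequential], head: Dense, n_classes: int,
                 input_shape: tuple[int, int] | None = None):
        self.branches = branches
        self.head = head
        self.n_classes = n_classes
        self.input_shape = input_shape  # (n_channels, n_samples) when built from a spec
        self._shared_L = None
        entries = [br.layers[0] for br in branches]
        if entries and all(isinstance(e, FusedEntry) for e in entries):
            lengths = {e.L for e in entries}
            if len(lengths) == 1:
                self._shared_L = lengths.pop()

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        out = [p for br in self.branches for p in br.params()]
        out.extend(self.head.params())
        return out

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        xf = None
        if self._shared_L is not None:
            xf = self.branches[0].layers[0].input_spectrum(x)
        outs = []
        for br in self.branches:
            kwargs = {"xf": xf} if xf is not None else {}
            outs.append(br.forward(x, training=training, rng=rng, **kwargs))
        self._split = np.cumsum([o.shape[1] for o in outs])[:-1]
        concat = np.concatenate(outs, axis=1)
        return self.head.forward(concat, training=training, rng=rng)

    def backward(self, dlogits: np.ndarray) -> None:
        dconcat = self.head.backward(dlogits)
        for br, piece in zip(self.branches, np.split(dconcat, self._split, axis=1)):
            br.backward(piece)

    def predict_proba(self, x: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        if batch_size is None or x.shape[0] <= batch_size:
            return softmax(self.forward(x, training=False))
        parts = [softmax(self.forward(x[i : i + batch_size], training=False))
                 for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(parts, axis=0)

    def predict(self, x: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        # argmax ties break toward the lowest class index
        return np.argmax(self.predict_proba(x, batch_size), axis=1)

    # -- state snapshots (for best-checkpoint restoration) -------------
    def get_state(self) -> dict:
        params = {p.name: p.value.copy() for p in self.params()}
        running = {}
        for i, br in enumerate(self.branches):
            for key, val in br.state().items():
                running[f"branch{i}/{key}"] = val.copy()
        return {"params": params, "running": running}

    def set_state(self, state: dict) -> None:
        by_name = {p.name: p for p in self.params()}
        for name, value in state["params"].items():
            by_name[name].value[...] = value
        for i, br in enumerate(self.branches):
            sub = {k.split("/", 1)[1]: v for k, v in state["running"].items()
                   if k.startswith(f"branch{i}/")}
            if sub:
                br.load_state(copy.deepcopy(sub))
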