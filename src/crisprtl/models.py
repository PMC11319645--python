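"""Model architectures, parameter-group tagging, and the ensemble wrapper.

Two families are defined as explicit computation graphs over the autodiff
engine in :mod:`crisprtl._autodiff`:

* ``rnn`` — token embedding of the start-symbol + 21-nt guide, a
  bidirectional gated recurrent (GRU) encoder, concatenation with the 11
  bio-features (and the 3-way enzyme indicator when multi-task), then a
  dense cascade ending in a scalar efficiency;
* ``cnn`` — the 30x4 one-hot context through three parallel 1-D
  convolution branches of distinct widths, global max pooling, a dense
  layer, concatenation with the scalar binding-energy feature, and a dense
  cascade ending in a scalar.

Every trainable parameter carries exactly one group tag so layer-freezing
schemes are definable as tag sets:

========================  =================================================
tag                       parameters
========================  =================================================
input_embedding_or_conv   token embedding matrix / convolution branches
sequence_encoder          recurrent gates (empty for the cnn)
dense_hidden              dense cascade except its final layer
last_hidden               final dense layer before the output unit
output                    output unit
========================  =================================================

Multi-task conditioning is a shared output head fed the enzyme indicator as
an input; there are no per-enzyme heads.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import EncodedBatch, DataError

__all__ = [
    "ModelSpec", "Model", "EnsembleModel", "build_model", "build_ensemble",
    "predict", "freeze_mask", "trainable_names", "ALL_GROUP_TAGS",
    "save_ensemble", "load_ensemble", "SCHEMES",
]

ALL_GROUP_TAGS = ("input_embedding_or_conv", "sequence_encoder",
                  "dense_hidden", "last_hidden", "output")
SCHEMES = ("full", "last_layer", "gradual_phase1", "gradual_phase2", "no_input_layer")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; defaults are config placeholders, not canon.

    The convolutional defaults follow the published CRISPRon shape (three
    branch widths 3/5/7 with 100 filters each, dense cascade 80 -> 60).
    """

    kind: str = "rnn"
    multi_task: bool = False
    # rnn hyperparameters
    embedding_dim: int = 44
    recurrent_units: int = 128
    dense_layers: tuple = (128, 64)
    #: emit the flattened per-position state sequence (False: final states only)
    return_sequences: bool = True
    # cnn hyperparameters
    conv_widths: tuple = (3, 5, 7)
    conv_filters: int = 100
    cnn_dense: tuple = (80, 60)
    pooling: str = "max"
    # shared
    n_biofeatures: int = 11
    n_enzymes: int = 3
    dropout_dense: float = 0.0
    last_activation: str = "sigmoid"
    init: str = "glorot_uniform"

    def __post_init__(self):
        if self.kind not in ("rnn", "cnn"):
            raise DataError(f"unknown model kind {self.kind!r}")
        if self.kind == "cnn" and self.multi_task:
            raise DataError("multi-task conditioning is defined for the rnn only")
        if self.pooling != "max":
            raise DataError("only max pooling is implemented")
        if self.kind == "cnn" and len(self.cnn_dense) < 2:
            raise DataError("cnn needs >= 2 dense layers (energy joins after the first)")

    @property
    def extra_dim(self) -> int:
        if self.kind == "cnn":
            return 1
        return self.n_biofeatures + (self.n_enzymes if self.multi_task else 0)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        for k in ("dense_layers", "conv_widths", "cnn_dense"):
            d[k] = tuple(d[k])
        return cls(**d)


def _init_matrix(rng: np.random.Generator, fan_in: int, fan_out: int,
                 scheme: str) -> np.ndarray:
    if scheme == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))
    if scheme == "glorot_normal":
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))
    if scheme == "he":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
    raise DataError(f"unknown init scheme {scheme!r}")


class Model:
    """One member network: a named parameter dict plus the forward graph."""

    def __init__(self, spec: ModelSpec, params: dict[str, Tensor], seed: int):
        self.spec = spec
        self.params = params
        self.seed = seed

    # ---- parameter groups ------------------------------------------------

    @property
    def param_groups(self) -> dict[str, set]:
        groups: dict[str, set] = {tag: set() for tag in ALL_GROUP_TAGS}
        n_dense = len(self.spec.dense_layers if self.spec.kind == "rnn"
                      else self.spec.cnn_dense)
        for name in self.params:
            if name.startswith(("embed.", "conv.")):
                groups["input_embedding_or_conv"].add(name)
            elif name.startswith("gru."):
                groups["sequence_encoder"].add(name)
            elif name.startswith("out."):
                groups["output"].add(name)
            elif name.startswith("dense."):
                layer = int(name.split(".")[1])
                tag = "last_hidden" if layer == n_dense - 1 else "dense_hidden"
                groups[tag].add(name)
            else:  # pragma: no cover
                raise AssertionError(f"untagged parameter {name}")
        return groups

    def copy(self) -> "Model":
        params = {k: Tensor(v.data.copy(), requires_grad=True)
                  for k, v in self.params.items()}
        return Model(self.spec, params, self.seed)

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # ---- forward ---------------------------------------------------------

    def _dense_cascade(self, h: Tensor, extra: Tensor | None,
                       energy_concat_after: int | None,
                       training: bool, rng) -> Tensor:
        spec = self.spec
        sizes = spec.dense_layers if spec.kind == "rnn" else spec.cnn_dense
        for i in range(len(sizes)):
            if energy_concat_after is not None and i == energy_concat_after:
                h = ad.concat([h, extra], axis=1)
            if training and spec.dropout_dense > 0.0:
                keep = (rng.random(h.shape) >= spec.dropout_dense) / (1 - spec.dropout_dense)
                h = h * Tensor(keep)
            h = ad.relu(h @ self.params[f"dense.{i}.W"] + self.params[f"dense.{i}.b"])
        out = h @ self.params["out.W"] + self.params["out.b"]
        if spec.last_activation == "sigmoid":
            out = ad.sigmoid(out)
        elif spec.last_activation != "linear":
            raise DataError(f"unknown last activation {spec.last_activation!r}")
        return out.reshape(out.shape[0])

    def _gru_direction(self, xe: Tensor, direction: str, n: int, steps: int) -> Tensor:
        """One GRU direction; returns the full state sequence flattened to
        (n, steps*H) so every position stays directly visible downstream."""
        H = self.spec.recurrent_units
        p = self.params
        h = Tensor(np.zeros((n, H)))
        order = range(steps) if direction == "fwd" else range(steps - 1, -1, -1)
        states: list[Tensor | None] = [None] * steps
        for t in order:
            x = xe[(slice(None), t, slice(None))]
            z = ad.sigmoid(x @ p[f"gru.{direction}.Wz"] + h @ p[f"gru.{direction}.Uz"]
                           + p[f"gru.{direction}.bz"])
            r = ad.sigmoid(x @ p[f"gru.{direction}.Wr"] + h @ p[f"gru.{direction}.Ur"]
                           + p[f"gru.{direction}.br"])
            c = ad.tanh(x @ p[f"gru.{direction}.Wh"] + (r * h) @ p[f"gru.{direction}.Uh"]
                        + p[f"gru.{direction}.bh"])
            h = h + z * (c - h)
            states[t] = h
        if not self.spec.return_sequences:
            return h
        return ad.stack(states, axis=1).reshape(n, steps * H)

    def forward(self, seq: Tensor | np.ndarray, extra: Tensor | np.ndarray,
                training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Scalar predictions for a batch; row-independent, so batch
        composition cannot change a sample's output."""
        seq_t = seq if isinstance(seq, Tensor) else Tensor(seq)
        extra_t = extra if isinstance(extra, Tensor) else Tensor(extra)
        n, steps, alpha = seq_t.shape
        spec = self.spec
        if training and spec.dropout_dense > 0.0 and rng is None:
            rng = np.random.default_rng(self.seed)
        if spec.kind == "rnn":
            if alpha != 5 or extra_t.shape[1] != spec.extra_dim:
                raise DataError(
                    f"rnn expects (n,22,5) sequences and {spec.extra_dim} side features; "
                    f"got {seq_t.shape} and {extra_t.shape} "
                    "(multi-task models need the enzyme indicator)")
            xe = (seq_t.reshape(n * steps, alpha) @ self.params["embed.E"]) \
                .reshape(n, steps, spec.embedding_dim)
            h_f = self._gru_direction(xe, "fwd", n, steps)
            h_b = self._gru_direction(xe, "bwd", n, steps)
            h = ad.concat([h_f, h_b, extra_t], axis=1)
            return self._dense_cascade(h, None, None, training, rng)
        # cnn
        if alpha != 4 or steps != 30 or extra_t.shape[1] != 1:
            raise DataError(f"cnn expects (n,30,4) sequences and a scalar energy; "
                            f"got {seq_t.shape} and {extra_t.shape}")
        branches = []
        for w in spec.conv_widths:
            W, b = self.params[f"conv.w{w}.W"], self.params[f"conv.w{w}.b"]
            windows = [seq_t[(slice(None), slice(i, i + w), slice(None))]
                       .reshape(n, w * alpha) for i in range(steps - w + 1)]
            acts = [ad.relu(win @ W + b) for win in windows]
            pooled = ad.stack(acts, axis=1).max(axis=1)  # global max pool
            branches.append(pooled)
        h = ad.concat(branches, axis=1)
        return self._dense_cascade(h, extra_t, 1, training, rng)


def build_model(spec: ModelSpec, seed: int) -> Model:
    """Instantiate a member with seeded random initial weights."""
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    if spec.kind == "rnn":
        p["embed.E"] = _init_matrix(rng, 5, spec.embedding_dim, spec.init)
        H, E = spec.recurrent_units, spec.embedding_dim
        for d in ("fwd", "bwd"):
            for gate in ("z", "r", "h"):
                p[f"gru.{d}.W{gate}"] = _init_matrix(rng, E, H, spec.init)
                p[f"gru.{d}.U{gate}"] = _init_matrix(rng, H, H, spec.init)
                p[f"gru.{d}.b{gate}"] = np.zeros(H)
        steps = 22  # start symbol + 21 nt
        width = 2 * H * (steps if spec.return_sequences else 1) + spec.extra_dim
        sizes = spec.dense_layers
    else:
        for w in spec.conv_widths:
            p[f"conv.w{w}.W"] = _init_matrix(rng, w * 4, spec.conv_filters, spec.init)
            p[f"conv.w{w}.b"] = np.zeros(spec.conv_filters)
        width = len(spec.conv_widths) * spec.conv_filters
        sizes = spec.cnn_dense
    for i, size in enumerate(sizes):
        if spec.kind == "cnn" and i == 1:
            width += 1  # energy score concatenated after the first dense layer
        p[f"dense.{i}.W"] = _init_matrix(rng, width, size, spec.init)
        p[f"dense.{i}.b"] = np.zeros(size)
        width = size
    p["out.W"] = _init_matrix(rng, width, 1, spec.init)
    p["out.b"] = np.zeros(1)
    params = {k: Tensor(v, requires_grad=True) for k, v in p.items()}
    return Model(spec, params, seed)


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    """N independently initialized members; prediction is the member mean."""

    members: list
    seeds: list = field(default_factory=list)

    def __post_init__(self):
        specs = {m.spec for m in self.members}
        if len(specs) > 1:
            raise DataError("all ensemble members must share one ModelSpec")

    @property
    def spec(self) -> ModelSpec:
        return self.members[0].spec

    @property
    def member_count(self) -> int:
        return len(self.members)

    def copy(self) -> "EnsembleModel":
        return EnsembleModel([m.copy() for m in self.members], list(self.seeds))


def build_ensemble(spec: ModelSpec, size: int, seed: int) -> EnsembleModel:
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(size)]
    return EnsembleModel([build_model(spec, s) for s in seeds], seeds)


def predict(model_or_ensemble, batch: EncodedBatch) -> np.ndarray:
    """Inference-mode predictions; ensembles average member outputs."""
    if isinstance(model_or_ensemble, EnsembleModel):
        preds = [predict(m, batch) for m in model_or_ensemble.members]
        return np.mean(preds, axis=0)
    model = model_or_ensemble
    if batch.kind != model.spec.kind:
        raise DataError(f"batch encoded for {batch.kind!r} but model is {model.spec.kind!r}")
    return model.forward(batch.seq, batch.extra, training=False).data


# ---------------------------------------------------------------------------
# freezing


def freeze_mask(spec: ModelSpec, scheme: str) -> set:
    """Group tags trainable under a fine-tuning scheme."""
    if scheme in ("full", "gradual_phase2"):
        return set(ALL_GROUP_TAGS)
    if scheme in ("last_layer", "gradual_phase1"):
        return {"last_hidden", "output"}
    if scheme == "no_input_layer":
        return set(ALL_GROUP_TAGS) - {"input_embedding_or_conv"}
    raise DataError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def trainable_names(model: Model, tags: set) -> set:
    groups = model.param_groups
    unknown = tags - set(ALL_GROUP_TAGS)
    if unknown:
        raise DataError(f"unknown parameter-group tags {unknown}")
    return set().union(*(groups[t] for t in tags)) if tags else set()


# ---------------------------------------------------------------------------
# checkpoints


def save_ensemble(ens: EnsembleModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "spec.json").write_text(ens.spec.to_json())
    (d / "seeds.json").write_text(json.dumps(ens.seeds))
    for i, m in enumerate(ens.members):
        np.savez(d / f"member_{i}.npz", **{k: v.data for k, v in m.params.items()})


def load_ensemble(directory) -> EnsembleModel:
    d = Path(directory)
    spec = ModelSpec.from_json((d / "spec.json").read_text())
    seeds = json.loads((d / "seeds.json").read_text())
    members = []
    for i, seed in enumerate(seeds):
        with np.load(d / f"member_{i}.npz") as npz:
            params = {k: Tensor(npz[k].copy(), requires_grad=True) for k in npz.files}
        members.append(Model(spec, params, seed))
    return EnsembleModel(members, seeds)
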