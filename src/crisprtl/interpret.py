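"""Gradient-saliency attribution over trained ensembles and logo export.

The attribution of nucleotide feature j is the average over samples of the
gradient of the model output with respect to that input feature:
I_j = (1/n) * sum_i dY_i/dX_{i,j}. For an ensemble, the per-member
attributions are averaged. The recurrent model's integer tokens do not
expose dY/dX directly, so its embedding lookup is computed as one-hot x
embedding-matrix and the gradient is taken at the one-hot layer. The two
fixed GG positions of the PAM carry no information and are dropped (the
recurrent input never contains them; the convolutional input drops columns
25-26 of the 30-mer).

Attributions are signed; the exported logo matrix is a plain TSV
(position x A/C/G/T) consumable by standard logo renderers, with an
optional matplotlib rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .core_data import ALPHABET, EncodedBatch, DataError, CONTEXT_PAM_GG
from .models import EnsembleModel, Model

__all__ = ["AttributionMatrix", "saliency", "export_logo", "read_logo", "render_logo"]


@dataclass
class AttributionMatrix:
    """Signed per-position, per-letter attribution scores.

    ``positions`` labels the rows (protospacer positions for the recurrent
    model; 30-mer offsets minus the PAM GG for the convolutional one).
    ``extra`` holds the scalar attributions of the non-sequence inputs
    (bio-features / energy), reported separately from the logo.
    """

    I: np.ndarray  # (positions, 4), letter order A,C,G,T
    positions: list
    n_samples: int
    extra: np.ndarray | None = None

    def top_positions(self, k: int = 3) -> list:
        """Positions of the k largest |I| entries (descending)."""
        flat = np.argsort(np.abs(self.I), axis=None)[::-1][:k]
        return [self.positions[i // self.I.shape[1]] for i in flat]


def _member_saliency(model: Model, batch: EncodedBatch) -> tuple[np.ndarray, np.ndarray]:
    seq = Tensor(batch.seq, requires_grad=True)
    extra = Tensor(batch.extra, requires_grad=True)
    out = model.forward(seq, extra, training=False)
    # each Y_i depends only on X_i, so seeding with ones yields all dY_i/dX_i
    out.backward(np.ones(batch.n))
    extra_grad = extra.grad if extra.grad is not None else np.zeros_like(extra.data)
    return seq.grad.mean(axis=0), extra_grad.mean(axis=0)


def saliency(model_or_ensemble, batch: EncodedBatch) -> AttributionMatrix:
    """Mean input gradient over the samples a model was trained on.

    Exact reverse-mode gradients (no finite differences); the ensemble
    attribution is the mean of member attributions, which by linearity of
    the gradient equals the attribution of the mean predictor.
    """
    if batch.n == 0:
        raise DataError("saliency needs at least one sample")
    if isinstance(model_or_ensemble, EnsembleModel):
        members = model_or_ensemble.members
    else:
        members = [model_or_ensemble]
    seq_grads, extra_grads = zip(*(_member_saliency(m, batch) for m in members))
    G = np.mean(seq_grads, axis=0)
    extra = np.mean(extra_grads, axis=0)
    if batch.kind == "rnn":
        # drop the start-symbol row and its alphabet column
        I = G[1:, 1:]
        positions = list(range(1, 22))  # 1-based protospacer + first PAM base
    else:
        lo, hi = CONTEXT_PAM_GG
        keep = [p for p in range(G.shape[0]) if p not in range(lo, hi)]
        I = G[keep]
        positions = keep
    assert I.shape[1] == len(ALPHABET)
    return AttributionMatrix(I=I, positions=positions, n_samples=batch.n, extra=extra)


def export_logo(attr: AttributionMatrix, path) -> None:
    """Write the position-weight-style matrix as TSV (one row per position,
    columns A/C/G/T), full float precision for exact round-trips."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(ALPHABET) + "\n")
        for pos, row in zip(attr.positions, attr.I):
            fh.write(str(pos) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_logo(path) -> AttributionMatrix:
    positions, rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[1:] != list(ALPHABET):
            raise DataError(f"unexpected logo columns {header[1:]}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            positions.append(int(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return AttributionMatrix(I=np.array(rows), positions=positions, n_samples=0)


def render_logo(attr: AttributionMatrix, path, signed: bool = True) -> None:
    """Optional sequence-logo rendering: letter height proportional to
    attribution, positives stacked up and negatives down."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2e7d32", "C": "#1565c0", "G": "#ef6c00", "T": "#c62828"}
    I = attr.I if signed else np.abs(attr.I)
    fig, ax = plt.subplots(figsize=(max(6, len(attr.positions) * 0.4), 3))
    for x, (pos, row) in enumerate(zip(attr.positions, I)):
        up = down = 0.0
        for letter, v in sorted(zip(ALPHABET, row), key=lambda t: abs(t[1])):
            if v == 0:
                continue
            base = up if v > 0 else down - abs(v)
            ax.text(x, base + abs(v) / 2, letter, ha="center", va="center",
                    fontsize=9 + 40 * abs(v) / (np.abs(I).max() + 1e-12),
                    color=colors[letter], fontweight="bold")
            if v > 0:
                up += v
            else:
                down -= abs(v)
    ax.set_xticks(range(len(attr.positions)))
    ax.set_xticklabels(attr.positions, fontsize=7)
    lim = np.abs(I).sum(axis=1).max() + 1e-12
    ax.set_ylim(-lim if signed else 0, lim)
    ax.set_xlim(-1, len(attr.positions))
    ax.set_ylabel("attribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
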