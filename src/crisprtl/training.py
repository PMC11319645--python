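"""Pre-training, hyper-parameter search, and the four fine-tuning schemes.

The transfer-learning recipe: an ensemble is pre-trained on a large
high-throughput source screen, then each member is fine-tuned independently
on a small cellular-context target set under one of four layer-freezing
schemes (``full``, ``last_layer``, ``gradual``, ``no_input_layer``), with
two baselines (``no_tl``: the pre-trained ensemble untouched;
``no_pretrain``: fresh ensembles trained on the target only).

Epoch budgets follow two protocols. The recurrent path determines a fixed
fine-tuning epoch count by cluster-aware k-fold cross-validation over the
target training set (rounded mean of the per-fold early-stopping optima),
then trains on all of it without further early stopping. The convolutional
path fine-tunes with early stopping directly (patience 100, max 5000 epochs
by default at full scale). Validation carve-outs are cluster-aware
throughout, mirroring the leakage control of the evaluation protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from ._autodiff import Adam
from .core_data import (Dataset, DataError, EncodedBatch, encode_rnn, encode_cnn,
                        ENZYMES)
from .leakage import cluster_guides, split_by_clusters
from .models import (ModelSpec, Model, EnsembleModel, build_model, build_ensemble,
                     freeze_mask, trainable_names, predict)

__all__ = [
    "TrainConfig", "HyperSearchSpace", "encode_for_spec", "pretrain",
    "fine_tune", "determine_epochs_cv", "baseline", "hyper_search",
    "predictor",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults echo the published convolutional
    protocol (Adam, learning rate 1e-4, batch 500, ensemble of 6)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 500
    max_epochs: int = 100
    patience: int = 10
    gradual_lr_factor: float = 0.1
    ensemble_size: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise DataError("learning_rate must be > 0")
        if self.patience > self.max_epochs:
            raise DataError("patience must be <= max_epochs")
        if self.ensemble_size < 1:
            raise DataError("ensemble_size must be >= 1")
        if self.optimizer != "adam":
            raise DataError("only the Adam optimizer is implemented")


# ---------------------------------------------------------------------------
# encoding helpers


def _concat_batches(batches: list[EncodedBatch]) -> EncodedBatch:
    return EncodedBatch(batches[0].kind,
                        np.concatenate([b.seq for b in batches]),
                        np.concatenate([b.extra for b in batches]),
                        np.concatenate([b.y for b in batches]),
                        [i for b in batches for i in b.ids])


def encode_for_spec(spec: ModelSpec, records, condition: str | None = None,
                    enzymes: tuple = ENZYMES, drop_unobserved: bool = True) -> EncodedBatch:
    """Encode records for a spec.

    Multi-task recurrent training flattens each guide into one sample per
    observed enzyme condition (a guide lacking a measurement under a
    condition simply contributes no sample there). ``condition`` fixes a
    single condition instead, e.g. when fine-tuning a multi-task model on a
    single-condition target set.
    """
    records = list(records)
    if spec.kind == "cnn":
        batch = encode_cnn(records)
    elif spec.multi_task:
        if condition is not None:
            batch = encode_rnn(records, condition, enzymes)
        else:
            per = [encode_rnn([r for r in records if c in r.efficiencies], c, enzymes)
                   for c in enzymes]
            per = [b for b in per if b.n]
            if not per:
                raise DataError("no observed efficiencies under any enzyme condition")
            batch = _concat_batches(per)
    else:
        batch = encode_rnn(records, None)
    if drop_unobserved:
        keep = np.isfinite(batch.y)
        if not keep.all():
            batch = batch.take(np.flatnonzero(keep))
    return batch


def predictor(ensemble: EnsembleModel, condition: str | None = None):
    """callable(Dataset | records) -> predictions, encoding per the spec."""

    def fn(data) -> np.ndarray:
        records = data.records if isinstance(data, Dataset) else list(data)
        cond = condition
        if ensemble.spec.multi_task and cond is None:
            cond = ENZYMES[0]
        batch = encode_for_spec(ensemble.spec, records, cond, drop_unobserved=False)
        return predict(ensemble, batch)

    return fn


# ---------------------------------------------------------------------------
# core member training loop


def _loss(model: Model, batch: EncodedBatch, idx, training: bool, rng):
    pred = model.forward(batch.seq[idx], batch.extra[idx], training=training, rng=rng)
    resid = pred - batch.y[idx]
    return (resid * resid).mean()


def _eval_loss(model: Model, batch: EncodedBatch) -> float:
    if batch.n == 0:
        return math.nan
    pred = model.forward(batch.seq, batch.extra, training=False)
    return float(np.mean((pred.data - batch.y) ** 2))


def train_member(model: Model, train: EncodedBatch, val: EncodedBatch | None,
                 config: TrainConfig, mask_names: set | None = None,
                 epochs: int | None = None, shuffle_seed: int = 0,
                 lr: float | None = None) -> list[dict]:
    """Train one member in place; returns the per-epoch log.

    With ``epochs`` given the member trains exactly that many epochs (zero
    leaves it untouched). Otherwise early stopping monitors the validation
    loss: training stops once ``config.patience`` epochs pass without
    improvement, and the best-epoch weights are restored. The log records
    train/validation loss per epoch and marks the best epoch.
    """
    if train.n == 0:
        raise DataError("empty training batch")
    mask = set(model.params) if mask_names is None else set(mask_names)
    opt = Adam(model.params, lr=lr if lr is not None else config.learning_rate,
               mask=mask)
    rng = np.random.default_rng([shuffle_seed, 2654435761])
    early_stop = epochs is None
    if early_stop and (val is None or val.n == 0):
        raise DataError("early stopping requires a non-empty validation batch")
    n_epochs = config.max_epochs if early_stop else epochs
    log: list[dict] = []
    best = (math.inf, 0, None)  # (val loss, epoch, weights)
    if val is not None and val.n:
        # epoch-0 entry: the un-trained starting point, also the early-stop
        # fallback when no epoch improves on it
        entry0 = {"epoch": 0, "val_loss": _eval_loss(model, val)}
        log.append(entry0)
        if early_stop:
            best = (entry0["val_loss"], 0,
                    {k: v.data.copy() for k, v in model.params.items()})
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(train.n)
        epoch_losses = []
        for start in range(0, train.n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = _loss(model, train, idx, training=True, rng=rng)
            if not np.isfinite(loss.data):
                raise DataError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val is not None and val.n:
            entry["val_loss"] = _eval_loss(model, val)
        log.append(entry)
        if early_stop:
            if entry["val_loss"] < best[0]:
                best = (entry["val_loss"], epoch,
                        {k: v.data.copy() for k, v in model.params.items()})
            if epoch - best[1] >= config.patience:
                break
    if early_stop and best[2] is not None:
        for k, v in model.params.items():
            v.data = best[2][k]
        for entry in log:
            entry["best"] = entry["epoch"] == best[1]
    return log


def write_log_tsv(logs: list[list[dict]], path) -> None:
    with open(path, "w") as fh:
        fh.write("member\tepoch\ttrain_loss\tval_loss\tbest\n")
        for m, log in enumerate(logs):
            for e in log:
                fh.write(f"{m}\t{e['epoch']}\t{e.get('train_loss', float('nan')):.6g}\t"
                         f"{e.get('val_loss', float('nan')):.6g}\t"
                         f"{int(e.get('best', False))}\n")


def _val_carveout(records: list, fraction: float, link_threshold: int,
                  seed: int) -> tuple[list, list]:
    """Cluster-aware train/validation carve-out over a record list."""
    ds = Dataset(records=list(records), name="carveout")
    clusters = cluster_guides(ds, link_threshold)
    plan = split_by_clusters(clusters, fraction, ordering="random", seed=seed,
                             link_threshold=link_threshold)
    by_id = ds.by_id()
    return ([by_id[i] for i in plan.train_ids], [by_id[i] for i in plan.test_ids])


# ---------------------------------------------------------------------------
# pre-training


def pretrain(spec: ModelSpec, dataset: Dataset, splitplan, config: TrainConfig,
             link_threshold: int = 5) -> EnsembleModel:
    """Train a fresh ensemble on the source training split.

    Each member starts from its own seed and early-stops on a cluster-aware
    10% validation carve-out of the training split. Per-epoch logs are kept
    on the returned ensemble (``.logs``).
    """
    by_id = dataset.by_id()
    train_records = [by_id[i] for i in splitplan.train_ids]
    tr, va = _val_carveout(train_records, 0.1, link_threshold, config.seed)
    train_b = encode_for_spec(spec, tr)
    val_b = encode_for_spec(spec, va)
    ens = build_ensemble(spec, config.ensemble_size, config.seed)
    logs, survivors, seeds = [], [], []
    for i, member in enumerate(ens.members):
        try:
            logs.append(train_member(member, train_b, val_b, config,
                                     shuffle_seed=ens.seeds[i]))
            survivors.append(member)
            seeds.append(ens.seeds[i])
        except DataError as exc:
            logs.append([{"epoch": 0, "error": str(exc)}])
    if not survivors:
        raise DataError("all ensemble members failed to train")
    out = EnsembleModel(survivors, seeds)
    out.logs = logs
    return out


# ---------------------------------------------------------------------------
# epoch determination and fine-tuning


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _cluster_folds(dataset: Dataset, k: int, link_threshold: int,
                   seed: int) -> list[list]:
    """k cluster-aware folds: whole clusters, balanced greedily by size."""
    clusters = cluster_guides(dataset, link_threshold)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    folds: list[list] = [[] for _ in range(k)]
    sizes = [0] * k
    for ci in order:
        j = int(np.argmin(sizes))
        folds[j].extend(sorted(clusters[ci].member_ids))
        sizes[j] += clusters[ci].size
    return folds


def determine_epochs_cv(pretrained: EnsembleModel, train_set: Dataset,
                        config: TrainConfig, scheme: str = "full",
                        k: int = 10, link_threshold: int = 5,
                        condition: str | None = None) -> int:
    """Fixed fine-tuning epoch budget by cluster-aware k-fold CV.

    Each fold fine-tunes a copy of the first ensemble member with early
    stopping (held-out fold as validation) and records the best epoch; the
    returned budget is the rounded (half away from zero) mean, at least 1.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    folds = _cluster_folds(train_set, k, link_threshold, config.seed)
    if any(not f for f in folds):
        raise DataError(f"fold too small to split: sizes {[len(f) for f in folds]}")
    by_id = train_set.by_id()
    mask_tags = freeze_mask(pretrained.spec,
                            "gradual_phase1" if scheme == "gradual" else scheme)
    best_epochs = []
    for i, fold in enumerate(folds):
        val_recs = [by_id[r] for r in fold]
        tr_recs = [by_id[r] for f in folds[:i] + folds[i + 1:] for r in f]
        member = pretrained.members[0].copy()
        names = trainable_names(member, mask_tags)
        log = train_member(member,
                           encode_for_spec(pretrained.spec, tr_recs, condition),
                           encode_for_spec(pretrained.spec, val_recs, condition),
                           config, mask_names=names, shuffle_seed=config.seed + i)
        best = next((e["epoch"] for e in log if e.get("best")), len(log))
        best_epochs.append(max(1, best))
    return max(1, _round_half_away(float(np.mean(best_epochs))))


def fine_tune(pretrained: EnsembleModel, train_set: Dataset, scheme: str,
              config: TrainConfig, epochs=None, link_threshold: int = 5,
              condition: str | None = None) -> EnsembleModel:
    """Fine-tune a copy of the pre-trained ensemble on a target training set.

    scheme: ``full`` | ``last_layer`` | ``gradual`` | ``no_input_layer``.
    ``gradual`` runs two phases: last-hidden + output at the configured
    learning rate, then all weights at learning_rate * gradual_lr_factor.

    ``epochs``: a fixed budget (int, or a (phase1, phase2) pair for
    gradual) trains without early stopping — the recurrent protocol, with
    the budget typically from :func:`determine_epochs_cv`. ``epochs=None``
    uses early stopping on a cluster-aware 10% carve-out — the
    convolutional protocol. Zero epochs leaves the copy identical to the
    pre-trained ensemble.
    """
    if scheme not in ("full", "last_layer", "gradual", "no_input_layer"):
        raise DataError(f"unknown fine-tuning scheme {scheme!r}")
    spec = pretrained.spec
    if condition is None and spec.multi_task:
        condition = ENZYMES[0]
    phases: list[tuple[str, float]]
    if scheme == "gradual":
        phases = [("gradual_phase1", config.learning_rate),
                  ("gradual_phase2", config.learning_rate * config.gradual_lr_factor)]
        if epochs is None:
            phase_epochs = [None, None]
        elif isinstance(epochs, (tuple, list)):
            phase_epochs = list(epochs)
        else:
            phase_epochs = [epochs, epochs]
    else:
        phases = [(scheme, config.learning_rate)]
        phase_epochs = [epochs]

    records = list(train_set.records)
    train_all = encode_for_spec(spec, records, condition)
    val_b = None
    if any(e is None for e in phase_epochs):
        tr, va = _val_carveout(records, 0.1, link_threshold, config.seed)
        train_es = encode_for_spec(spec, tr, condition)
        val_b = encode_for_spec(spec, va, condition)

    ens = pretrained.copy()
    logs = []
    for i, member in enumerate(ens.members):
        member_log = []
        for (phase, lr), n_ep in zip(phases, phase_epochs):
            names = trainable_names(member, freeze_mask(spec, phase))
            if not names:
                raise DataError(f"scheme {scheme!r} leaves no trainable parameters")
            batch = train_all if n_ep is not None else train_es
            member_log += train_member(member, batch, val_b, config,
                                       mask_names=names, epochs=n_ep,
                                       shuffle_seed=(config.seed * 1000 + i) % (2 ** 31),
                                       lr=lr)
        logs.append(member_log)
    ens.logs = logs
    return ens


def baseline(kind: str, pretrained: EnsembleModel | None = None,
             spec: ModelSpec | None = None, train_set: Dataset | None = None,
             config: TrainConfig | None = None, link_threshold: int = 5,
             condition: str | None = None) -> EnsembleModel:
    """The two non-TL reference protocols.

    ``no_tl`` returns the pre-trained ensemble untouched. ``no_pretrain``
    trains fresh randomly initialized ensembles on the target training set
    only, with early stopping on a cluster-aware carve-out.
    """
    if kind == "no_tl":
        if pretrained is None:
            raise DataError("no_tl baseline needs the pretrained ensemble")
        return pretrained
    if kind != "no_pretrain":
        raise DataError(f"unknown baseline {kind!r}")
    if spec is None or train_set is None or config is None:
        raise DataError("no_pretrain baseline needs spec, train_set, and config")
    if condition is None and spec.multi_task:
        condition = ENZYMES[0]
    tr, va = _val_carveout(list(train_set.records), 0.1, link_threshold, config.seed)
    train_b = encode_for_spec(spec, tr, condition)
    val_b = encode_for_spec(spec, va, condition)
    ens = build_ensemble(spec, config.ensemble_size, config.seed)
    logs = []
    for i, member in enumerate(ens.members):
        logs.append(train_member(member, train_b, val_b, config,
                                 shuffle_seed=ens.seeds[i]))
    ens.logs = logs
    return ens


# ---------------------------------------------------------------------------
# hyper-parameter search


@dataclass
class HyperSearchSpace:
    """Named choice lists over ModelSpec and TrainConfig fields.

    Each trial samples one value per key; keys must be valid field names of
    :class:`ModelSpec` (``spec_choices``) or :class:`TrainConfig`
    (``train_choices``). Every sampled point must construct valid objects.
    """

    spec_choices: dict = field(default_factory=dict)
    train_choices: dict = field(default_factory=dict)
    n_trials: int = 10
    seed: int = 0


def hyper_search(space: HyperSearchSpace, train_set: Dataset,
                 base_spec: ModelSpec = None, base_config: TrainConfig = None,
                 link_threshold: int = 5,
                 condition: str | None = None):
    """Random search; argmax of validation Spearman over sampled points.

    A random cluster-aware 10% of the training set serves as validation.
    Failed trials score -inf. Returns (best ModelSpec, best TrainConfig,
    trial table); reproducible under the space's seed.
    """
    from .evaluation import spearman

    base_spec = base_spec or ModelSpec()
    base_config = base_config or TrainConfig()
    rng = np.random.default_rng(space.seed)
    tr, va = _val_carveout(list(train_set.records), 0.1, link_threshold, space.seed)
    table = []
    best = (-math.inf, None, None)
    for trial in range(space.n_trials):
        spec_kw = {k: v[rng.integers(len(v))] for k, v in space.spec_choices.items()}
        train_kw = {k: v[rng.integers(len(v))] for k, v in space.train_choices.items()}
        row = {"trial": trial, **spec_kw, **train_kw}
        spec = replace(base_spec, **spec_kw)
        config = replace(base_config, **train_kw)
        try:
            model = build_model(spec, seed=int(rng.integers(2 ** 31)))
            train_b = encode_for_spec(spec, tr, condition)
            val_b = encode_for_spec(spec, va, condition)
            train_member(model, train_b, val_b, config, shuffle_seed=space.seed + trial)
            with np.errstate(all="ignore"):
                score = spearman(model.forward(val_b.seq, val_b.extra).data, val_b.y)
            row["score"] = float(score) if np.isfinite(score) else -math.inf
        except (DataError, FloatingPointError, OverflowError) as exc:
            row["score"] = -math.inf
            row["error"] = str(exc)
        table.append(row)
        if best[1] is None or row["score"] > best[0]:
            best = (row["score"], spec, config)
    return best[1], best[2], table
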