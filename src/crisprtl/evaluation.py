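"""Repeated cluster-aware evaluation, rank correlation, and significance.

Prediction performance is gauged by Spearman correlation of predicted and
measured efficiencies on held-out test sets. Because the cellular-context
datasets are small, a single split is noisy: the protocol repeats the
evaluation five times, each on an independent cluster-aware 80/20 split
(link threshold 5 over the 23-nt sequences), and reports the per-repeat
correlations and their mean. Method pairs are compared with the two-sided
Wilcoxon rank-sum test, exact for small samples.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import Dataset, DataError
from .leakage import cluster_guides, split_by_clusters

__all__ = [
    "spearman", "EvalResult", "evaluate_repeated", "compare_methods",
    "CrossPredictionMatrix", "cross_predict",
]


def spearman(pred, obs) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (with a warning) when either vector is constant, for which
    rank correlation is undefined.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 3:
        raise DataError("spearman needs two equal-length 1-D vectors of size >= 3")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("constant vector: Spearman correlation undefined, returning NaN")
        return math.nan
    rho, _ = stats.spearmanr(pred, obs)
    return float(rho)


@dataclass
class EvalResult:
    dataset: str
    method: str
    per_repeat: list
    repeat_seeds: list
    n_nan: int = 0

    @property
    def mean(self) -> float:
        vals = [v for v in self.per_repeat if np.isfinite(v)]
        return float(np.mean(vals)) if vals else math.nan

    def to_json(self) -> str:
        return json.dumps({"dataset": self.dataset, "method": self.method,
                           "per_repeat": self.per_repeat, "mean": self.mean,
                           "repeat_seeds": self.repeat_seeds, "n_nan": self.n_nan})


def evaluate_repeated(target: Dataset, method_factory, repeats: int = 5,
                      test_fraction: float = 0.2, link_threshold: int = 5,
                      seed: int = 0, min_test: int = 10) -> EvalResult:
    """Repeat train/test evaluation on independent cluster-aware splits.

    ``method_factory(train_dataset, seed) -> callable(test_dataset) ->
    predictions``. Each repeat draws its own random-ordered cluster split,
    trains via the factory, and scores Spearman on the held-out test set.
    NaN repeats (degenerate constant predictors) are excluded from the mean
    with a recorded count.
    """
    clusters = cluster_guides(target, link_threshold)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(repeats)]
    scores = []
    n_nan = 0
    for rseed in seeds:
        plan = split_by_clusters(clusters, test_fraction, ordering="random",
                                 seed=rseed, link_threshold=link_threshold)
        if len(plan.test_ids) < min_test:
            raise DataError(f"test set of {len(plan.test_ids)} records is below "
                            f"the minimum of {min_test}")
        train_ds = target.subset(plan.train_ids, name=target.name + ":train")
        test_ds = target.subset(plan.test_ids, name=target.name + ":test")
        predict_fn = method_factory(train_ds, rseed)
        obs = np.array([next(iter(r.efficiencies.values())) for r in test_ds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman(np.asarray(predict_fn(test_ds), dtype=float), obs)
        if not np.isfinite(rho):
            n_nan += 1
        scores.append(rho)
    return EvalResult(target.name, getattr(method_factory, "__name__", "method"),
                      scores, seeds, n_nan)


# ---------------------------------------------------------------------------
# significance


def _rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating rank assignments.

    All C(n1+n2, n1) assignments of the pooled (average) ranks to group a
    are enumerated; p is the probability of a rank sum at least as far from
    its null mean as the observed one. Ties are handled by permuting the
    tied average ranks like any others.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2.0
    d_obs = abs(w_obs - mean_w)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mean_w) >= d_obs - 1e-9:
            count += 1
    return count / total


def compare_methods(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two score collections.

    Exact by enumeration for groups of at most 10 scores each, otherwise
    the tie-corrected normal approximation. Symmetric in argument order.
    """
    a = np.asarray(getattr(a, "per_repeat", a), dtype=float)
    b = np.asarray(getattr(b, "per_repeat", b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("compare_methods needs non-empty score collections")
    if a.size <= 10 and b.size <= 10:
        return _rank_sum_exact_p(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# cross-context prediction matrix


@dataclass
class CrossPredictionMatrix:
    row_labels: list  # evaluation datasets
    col_labels: list  # models
    values: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("dataset\t" + "\t".join(self.col_labels) + "\n")
            for label, row in zip(self.row_labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    def report(self) -> str:
        """Plain-text table: rows = test datasets, columns = models."""
        width = max([len(s) for s in self.row_labels + self.col_labels] + [8]) + 2
        lines = ["".ljust(width) + "".join(c.ljust(width) for c in self.col_labels)]
        for label, row in zip(self.row_labels, self.values):
            lines.append(label.ljust(width) +
                         "".join(f"{v:.3f}".ljust(width) for v in row))
        return "\n".join(lines)


def cross_predict(models: dict, datasets: dict,
                  predictor_factory=None) -> CrossPredictionMatrix:
    """Score every model on every complete dataset.

    cell(d, m) = Spearman of model m's predictions against dataset d's
    observed efficiencies, on the full dataset (no splitting: the point is
    cross-context generalization, and each model saw only its own context).
    ``models`` maps name -> ensemble (or any callable(Dataset)->predictions
    when ``predictor_factory`` is None and the value is callable).
    """
    if predictor_factory is None:
        from .training import predictor as predictor_factory  # default wiring
    rows = list(datasets)
    cols = list(models)
    values = np.full((len(rows), len(cols)), np.nan)
    for i, dname in enumerate(rows):
        ds = datasets[dname]
        obs = np.array([next(iter(r.efficiencies.values())) for r in ds])
        for j, mname in enumerate(cols):
            model = models[mname]
            fn = model if callable(model) else predictor_factory(model)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values[i, j] = spearman(np.asarray(fn(ds), dtype=float), obs)
    return CrossPredictionMatrix(rows, cols, values)
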