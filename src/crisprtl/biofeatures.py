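"""Sequence-derived bio-features for the recurrent model and the pluggable
binding-energy feature for the convolutional model.

The recurrent architecture consumes 11 real-valued features per guide:

* 3 position-accessibility features — mean predicted unpaired probability of
  the guide secondary structure over protospacer windows 1-7, 8-14, 15-20
  (1-based);
* 1 stem-loop feature — the fraction of seed-region positions (16-20,
  PAM-proximal) predicted paired in a hairpin stem;
* 4 melting-temperature features — nearest-neighbor Tm of the full 20-mer
  and of sub-segments 1-5, 6-13, 14-20;
* 3 GC features — GC count and fraction of the 20-mer, and GC fraction of
  the seed region.

The exact feature formulas are a package default, not a published canon;
window boundaries are exposed via :class:`BioFeatureConfig`. Secondary
structure comes from a pluggable folding backend: the default is a
deterministic self-complementarity hairpin heuristic (no external tool);
an adapter for the ViennaRNA partition function is provided when its
python bindings are importable.

The convolutional model's energy feature approximates the Cas9–gRNA–DNA
binding free energy. That energy model is consumed, never re-implemented:
scores are attached from a precomputed column or any injected callable; a
simple GC-based proxy is provided for synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from Bio.SeqUtils import MeltingTemp

from .core_data import Dataset, DataError, GuideRecord

__all__ = [
    "BioFeatureConfig", "compute_biofeatures", "attach_biofeatures",
    "builtin_fold", "vienna_fold", "attach_energy_scores", "gc_proxy_energy",
    "N_BIOFEATURES",
]

N_BIOFEATURES = 11

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class BioFeatureConfig:
    """Window boundaries (1-based, inclusive, on the 20-nt protospacer)."""

    accessibility_windows: tuple = ((1, 7), (8, 14), (15, 20))
    tm_segments: tuple = ((1, 5), (6, 13), (14, 20))
    seed: tuple = (16, 20)


DEFAULT_CONFIG = BioFeatureConfig()


# ---------------------------------------------------------------------------
# folding backends
#
# Backend protocol: callable(seq: str) -> (pair_probs: np.ndarray, structure:
# str in dot-bracket). pair_probs[i] is the probability position i is paired.


def builtin_fold(seq: str) -> tuple[np.ndarray, str]:
    """Deterministic hairpin heuristic: the longest self-complementary stem
    with a loop of >= 3 nt is treated as paired with probability 1.

    This is a structural stand-in with the backend contract of a folding
    engine — deterministic and dependency-free, not thermodynamic.
    """
    n = len(seq)
    best = (0, 0, 0)  # (stem_len, i, j) pairing i..i+L-1 with j+L-1..j reversed
    for i in range(n):
        for j in range(i + 4, n):  # loop >= 3 between stem halves
            length = 0
            while (i + length < j - length - 3
                   and j - length < n
                   and COMPLEMENT[seq[i + length]] == seq[j - length]):
                length += 1
            if length > best[0]:
                best = (length, i, j)
    probs = np.zeros(n)
    structure = ["."] * n
    stem, i, j = best
    if stem >= 3:
        for k in range(stem):
            probs[i + k] = probs[j - k] = 1.0
            structure[i + k], structure[j - k] = "(", ")"
    return probs, "".join(structure)


def vienna_fold(seq: str) -> tuple[np.ndarray, str]:
    """Partition-function pairing probabilities from the ViennaRNA bindings."""
    import RNA  # optional dependency of the conda viennarna package

    rna = seq.replace("T", "U")
    fc = RNA.fold_compound(rna)
    structure, _ = fc.mfe()
    fc.pf()
    bpp = np.array(fc.bpp())[1:, 1:]  # 1-indexed upper-triangular
    pair_probs = bpp.sum(axis=0) + bpp.sum(axis=1)
    return np.clip(pair_probs, 0.0, 1.0), structure


_BACKENDS: dict[str, Callable] = {"builtin": builtin_fold, "vienna": vienna_fold}


# ---------------------------------------------------------------------------
# feature computation


def _gc_fraction(seq: str) -> float:
    return sum(c in "GC" for c in seq) / len(seq)


def compute_biofeatures(guide21: str, folding_backend="builtin",
                        config: BioFeatureConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The 11-vector of sequence bio-features for one guide.

    Pure: the same guide and backend always produce an identical vector.
    Feature order: accessibility x3, stem_loop, Tm full + x3 segments,
    GC count, GC fraction, seed GC fraction.
    """
    if len(guide21) != 21:
        raise DataError(f"expected a 21-nt guide, got {len(guide21)} nt")
    proto = guide21[:20]
    backend = _BACKENDS.get(folding_backend, folding_backend)
    if not callable(backend):
        raise DataError(f"unknown folding backend {folding_backend!r}")
    try:
        pair_probs, _structure = backend(proto)
    except Exception as exc:  # pragma: no cover - backend-specific
        raise DataError(f"folding backend {folding_backend!r} failed on {proto}: {exc}") from exc
    pair_probs = np.asarray(pair_probs, dtype=float)
    unpaired = 1.0 - pair_probs

    acc = [float(unpaired[lo - 1:hi].mean()) for lo, hi in config.accessibility_windows]
    s_lo, s_hi = config.seed
    stem_loop = float(pair_probs[s_lo - 1:s_hi].mean())
    tms = [float(MeltingTemp.Tm_NN(proto))]
    tms += [float(MeltingTemp.Tm_NN(proto[lo - 1:hi])) for lo, hi in config.tm_segments]
    gc_count = float(sum(c in "GC" for c in proto))
    gc_frac = _gc_fraction(proto)
    gc_seed = _gc_fraction(proto[s_lo - 1:s_hi])
    vec = np.array(acc + [stem_loop] + tms + [gc_count, gc_frac, gc_seed])
    assert vec.shape == (N_BIOFEATURES,) and np.isfinite(vec).all()
    return vec


def attach_biofeatures(dataset: Dataset, folding_backend="builtin",
                       config: BioFeatureConfig = DEFAULT_CONFIG) -> Dataset:
    """Populate ``biofeatures`` on every record, caching identical guides."""
    cache: dict[str, np.ndarray] = {}
    for rec in dataset:
        if rec.guide21 not in cache:
            cache[rec.guide21] = compute_biofeatures(rec.guide21, folding_backend, config)
        rec.biofeatures = cache[rec.guide21]
    return dataset


# ---------------------------------------------------------------------------
# binding-energy feature


def gc_proxy_energy(record: GuideRecord) -> float:
    """A documented GC-based stand-in for the binding free-energy score,
    for synthetic runs only: more GC -> more negative (stronger binding)."""
    seq = record.context30 if record.context30 is not None else record.guide21
    return -10.0 * _gc_fraction(seq) + 2.0


def attach_energy_scores(dataset: Dataset, source, allow_missing: bool = False) -> Dataset:
    """Populate ``energy_score`` from a callable(record)->float.

    Precomputed columns are ingested by ``read_dataset(schema={'energy':
    col})``; this attaches scores for records still lacking one. Records the
    source cannot resolve abort the run, or are dropped (with a count in the
    dataset provenance) when allow_missing is True.
    """
    if not callable(source):
        raise DataError("source must be a callable(record)->float "
                        "(column scores are ingested by read_dataset)")
    unresolved = []
    for rec in dataset:
        if rec.energy_score is not None:
            continue
        try:
            rec.energy_score = float(source(rec))
        except Exception:
            unresolved.append(rec.id)
    if unresolved:
        if not allow_missing:
            raise DataError(f"energy score unresolvable for {len(unresolved)} records: "
                            f"{unresolved[:10]}")
        keep = [r for r in dataset.records if r.id not in set(unresolved)]
        return Dataset(records=keep, name=dataset.name,
                       condition_labels=list(dataset.condition_labels),
                       provenance=dataset.provenance +
                       f" [dropped {len(unresolved)} records lacking energy scores]",
                       norm_params=dict(dataset.norm_params))
    return dataset
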