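"""Leakage control: Hamming similarity, clustering, and cluster-aware splits.

Near-duplicate guides shared between a training and an evaluation set (or
between a source and a target dataset) inflate measured performance. All
similarity here is Hamming distance over the 23-nt guide+PAM sequence; the
implicit GG is restored before comparison so thresholds match the published
convention. Edges and removals use the strict convention Hamming < T.

Candidate pairs are generated by pigeonhole segmentation: a 23-mer split
into max_dist+1 segments guarantees any pair within max_dist shares at
least one segment exactly, so only bucket collisions need exact
verification. This scales to the ~170k-guide source screens where the
naive quadratic scan does not.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import Dataset, DataError

__all__ = [
    "hamming", "find_similar_pairs", "cross_similar_pairs",
    "remove_source_leakage", "GuideCluster", "cluster_guides",
    "SplitPlan", "split_by_clusters", "constrain_test_complete",
]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _segments(length: int, n_parts: int) -> list[tuple[int, int]]:
    """Near-equal split of [0, length) into n_parts contiguous segments."""
    base, rem = divmod(length, n_parts)
    bounds, start = [], 0
    for i in range(n_parts):
        end = start + base + (1 if i < rem else 0)
        bounds.append((start, end))
        start = end
    return bounds


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def find_similar_pairs(seqs: list[str], max_dist: int) -> set[tuple[int, int]]:
    """All index pairs (i<j) with Hamming(seqs[i], seqs[j]) <= max_dist.

    Pigeonhole candidate generation (max_dist+1 segments; e.g. sizes
    5,5,5,4,4 for 23-mers at max_dist 4) followed by exact vectorized
    verification of bucket collisions.
    """
    if not seqs:
        return set()
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all sequences must have equal length")
    if max_dist >= length:
        return {(i, j) for i in range(len(seqs)) for j in range(i + 1, len(seqs))}
    enc = _encode(seqs)
    candidates: set[tuple[int, int]] = set()
    for lo, hi in _segments(length, max_dist + 1):
        buckets: dict[str, list[int]] = defaultdict(list)
        for idx, s in enumerate(seqs):
            buckets[s[lo:hi]].append(idx)
        for members in buckets.values():
            if len(members) > 1:
                for ai in range(len(members)):
                    for bi in range(ai + 1, len(members)):
                        candidates.add((members[ai], members[bi]))
    out = set()
    for i, j in candidates:
        if int((enc[i] != enc[j]).sum()) <= max_dist:
            out.add((i, j))
    return out


def cross_similar_pairs(queries: list[str], references: list[str],
                        max_dist: int) -> dict[int, tuple[int, int]]:
    """For each query index, the nearest reference within max_dist.

    Returns {query_index: (reference_index, distance)} for hits only; uses
    the same pigeonhole scheme over the pooled sequences.
    """
    if not queries or not references:
        return {}
    length = len(queries[0])
    if any(len(s) != length for s in queries + references):
        raise ValueError("all sequences must have equal length")
    q_enc, r_enc = _encode(queries), _encode(references)
    hits: dict[int, tuple[int, int]] = {}
    checked: set[tuple[int, int]] = set()
    for lo, hi in _segments(length, max_dist + 1):
        buckets: dict[str, list[int]] = defaultdict(list)
        for ridx, s in enumerate(references):
            buckets[s[lo:hi]].append(ridx)
        for qidx, s in enumerate(queries):
            for ridx in buckets.get(s[lo:hi], ()):
                if (qidx, ridx) in checked:
                    continue
                checked.add((qidx, ridx))
                d = int((q_enc[qidx] != r_enc[ridx]).sum())
                if d <= max_dist and (qidx not in hits or d < hits[qidx][1]):
                    hits[qidx] = (ridx, d)
    return hits


def remove_source_leakage(source: Dataset, targets: list[Dataset],
                          max_dist: int = 3, log_path=None) -> Dataset:
    """Drop source guides within Hamming <= max_dist of any target guide.

    The default max_dist=3 implements the strict "< 4 over the 23-nt
    sequence" removal between high-throughput source screens and the small
    target datasets. A TSV removal log (id, nearest target id, distance) is
    written when log_path is given.
    """
    if not targets:
        return source
    src_seqs = [r.guide23 for r in source]
    tgt_seqs, tgt_ids = [], []
    for ds in targets:
        for r in ds:
            tgt_seqs.append(r.guide23)
            tgt_ids.append(f"{ds.name}:{r.id}")
    hits = cross_similar_pairs(src_seqs, tgt_seqs, max_dist)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("id\tnearest_target_id\tdistance\n")
            for qidx in sorted(hits):
                ridx, d = hits[qidx]
                fh.write(f"{source.records[qidx].id}\t{tgt_ids[ridx]}\t{d}\n")
    survivors = [r for i, r in enumerate(source.records) if i not in hits]
    if not survivors:
        raise DataError(f"leakage removal against {len(targets)} targets left no records")
    return Dataset(records=survivors, name=source.name,
                   condition_labels=list(source.condition_labels),
                   provenance=source.provenance + " [leakage-filtered]",
                   norm_params=dict(source.norm_params))


# ---------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class GuideCluster:
    member_ids: frozenset
    @property
    def size(self) -> int:
        return len(self.member_ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_guides(dataset: Dataset, link_threshold: int) -> list[GuideCluster]:
    """Connected components of the graph with edges Hamming < link_threshold.

    Components are computed by union-find over the pigeonhole pair search at
    max_dist = link_threshold - 1. The result is order-invariant: clusters
    are returned sorted by (size desc, lexicographically smallest member id).
    """
    seqs = [r.guide23 for r in dataset]
    ids = [r.id for r in dataset]
    uf = _UnionFind(len(seqs))
    for i, j in find_similar_pairs(seqs, link_threshold - 1):
        uf.union(i, j)
    groups: dict[int, set] = defaultdict(set)
    for idx in range(len(seqs)):
        groups[uf.find(idx)].add(ids[idx])
    clusters = [GuideCluster(frozenset(m)) for m in groups.values()]
    clusters.sort(key=lambda c: (-c.size, min(c.member_ids)))
    return clusters


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    ratio: float
    link_threshold: int
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"train_ids": sorted(self.train_ids),
                       "test_ids": sorted(self.test_ids),
                       "ratio": self.ratio,
                       "link_threshold": self.link_threshold,
                       "seed": self.seed}, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["train_ids"], d["test_ids"], d["ratio"],
                   d["link_threshold"], d.get("seed"))


def split_by_clusters(clusters: list[GuideCluster], test_fraction: float,
                      ordering: str = "by_size_desc", seed: int | None = None,
                      link_threshold: int = 5) -> SplitPlan:
    """Assign whole clusters to train/test, preserving the requested ratio.

    Clusters are walked either by size (descending, ties broken by smallest
    member id) or in seeded random order, and each is assigned greedily to
    whichever set is currently furthest below its quota. The achieved test
    fraction is within max(cluster size)/N of the request. A cluster larger
    than both quotas goes to train with a warning.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0,1)")
    ordered = sorted(clusters, key=lambda c: (-c.size, min(c.member_ids)))
    if ordering == "random":
        rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(len(ordered))]
    elif ordering != "by_size_desc":
        raise ValueError(f"unknown ordering {ordering!r}")

    n_total = sum(c.size for c in ordered)
    test_quota = test_fraction * n_total
    train_quota = n_total - test_quota
    train_ids: list = []
    test_ids: list = []
    warns: list[str] = []
    n_train = n_test = 0
    for c in ordered:
        if c.size > max(train_quota, test_quota):
            msg = (f"cluster of size {c.size} exceeds both quotas "
                   f"(train {train_quota:.0f}, test {test_quota:.0f}); assigned to train")
            warnings.warn(msg)
            warns.append(msg)
            train_ids.extend(sorted(c.member_ids))
            n_train += c.size
            continue
        if (train_quota - n_train) >= (test_quota - n_test):
            train_ids.extend(sorted(c.member_ids))
            n_train += c.size
        else:
            test_ids.extend(sorted(c.member_ids))
            n_test += c.size
    return SplitPlan(train_ids, test_ids, ratio=1.0 - test_fraction,
                     link_threshold=link_threshold, seed=seed, warnings=warns)


def constrain_test_complete(plan: SplitPlan, dataset: Dataset,
                            conditions: list[str]) -> SplitPlan:
    """Move test guides lacking any listed condition (and their neighbors)
    into train.

    The whole connected component (within the plan's link threshold) of an
    incomplete test record moves, so the cross-set distance invariant is
    preserved; for singleton clusters this is exactly "move the record".
    """
    by_id = dataset.by_id()
    incomplete = {rid for rid in plan.test_ids
                  if any(c not in by_id[rid].efficiencies for c in conditions)}
    if not incomplete:
        return plan
    test_records = [by_id[rid] for rid in plan.test_ids]
    test_ds = Dataset(records=test_records, name=dataset.name + ":test",
                      condition_labels=list(dataset.condition_labels))
    moved = set(incomplete)
    for cluster in cluster_guides(test_ds, plan.link_threshold):
        if cluster.member_ids & incomplete:
            moved |= cluster.member_ids
    new_test = [rid for rid in plan.test_ids if rid not in moved]
    new_train = list(plan.train_ids) + sorted(moved)
    return SplitPlan(new_train, new_test, plan.ratio, plan.link_threshold,
                     plan.seed, list(plan.warnings))
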