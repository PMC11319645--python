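"""Hamming similarity search, clustering, and leakage-controlled splits."""

import numpy as np
import pytest

from crisprtl.core_data import ALPHABET, Dataset, GuideRecord
from crisprtl.leakage import (SplitPlan, cluster_guides, constrain_test_complete,
                              find_similar_pairs, hamming, remove_source_leakage,
                              split_by_clusters)

from conftest import make_dataset, random_context30


def rand_seqs(n, length, rng):
    return ["".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
            for _ in range(n)]


def brute_force_pairs(seqs, max_dist):
    enc = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    out = set()
    for i in range(len(seqs)):
        d = (enc[i] != enc[i + 1:]).sum(axis=1)
        for off in np.flatnonzero(d <= max_dist):
            out.add((i, i + 1 + int(off)))
    return out


def mutate(seq, k, rng):
    """Return a copy with exactly k positions changed."""
    pos = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = ALPHABET[(ALPHABET.index(out[p]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# hamming & pair search


def test_hamming_against_naive_loop_oracle():
    assert hamming("ACGT", "ACGT") == 0
    assert hamming("ACGT", "ACTT") == 1
    rng = np.random.default_rng(0)
    for _ in range(500):
        a, b = rand_seqs(2, 23, rng)
        assert hamming(a, b) == sum(x != y for x, y in zip(a, b))
    with pytest.raises(ValueError):
        hamming("ACG", "ACGT")


def test_similar_pairs_trivial_cases():
    assert find_similar_pairs(["ACGT" * 5 + "AAA"] * 5, 4) == {
        (i, j) for i in range(5) for j in range(i + 1, 5)}
    rng = np.random.default_rng(1)
    seqs = rand_seqs(30, 23, rng)
    distant = [s for s in seqs
               if all(hamming(s, t) > 4 for t in seqs if t != s)]
    assert find_similar_pairs(distant, 4) == set()


@pytest.mark.parametrize("seed", range(10))
def test_similar_pairs_equal_brute_force(seed):
    rng = np.random.default_rng(seed)
    seqs = rand_seqs(80, 23, rng)
    # plant some near-duplicates so the candidate path is exercised
    for k in range(1, 5):
        seqs.append(mutate(seqs[k], k, rng))
    for max_dist in (1, 3, 4):
        assert find_similar_pairs(seqs, max_dist) == brute_force_pairs(seqs, max_dist)


# ---------------------------------------------------------------------------
# clustering


def _partition(clusters):
    return {c.member_ids for c in clusters}


def test_distant_guides_are_singletons(small_pair):
    src, _, _, _ = small_pair
    sub = Dataset(records=src.records[:40], name="sub")
    seqs = [r.guide23 for r in sub]
    # random 23-mers are pairwise distant with overwhelming probability
    assert brute_force_pairs(seqs, 4) == set()
    clusters = cluster_guides(sub, 5)
    assert all(c.size == 1 for c in clusters) and len(clusters) == 40


def test_chained_similarity_is_transitive():
    rng = np.random.default_rng(5)
    a = rand_seqs(1, 23, rng)[0]
    b = mutate(a, 2, rng)
    c = mutate(b, 2, rng)
    assert hamming(a, c) <= 4
    ds = Dataset(records=[GuideRecord(id=x, guide21=s[:21], efficiencies={"c": .5})
                          for x, s in zip("abc", (a, b, c))], name="chain")
    clusters = cluster_guides(ds, 5)
    # comparisons run over guide21+"GG", so distances within the chain carry over
    assert len(clusters) == 1 and clusters[0].size == 3


def test_clustering_matches_transitive_closure_and_is_order_invariant():
    rng = np.random.default_rng(6)
    base = rand_seqs(60, 21, rng)
    seqs = base + [mutate(base[i], rng.integers(1, 5), rng) for i in range(20)]
    records = [GuideRecord(id=f"r{i}", guide21=s, efficiencies={"c": 0.5})
               for i, s in enumerate(seqs)]
    ds = Dataset(records=records, name="x")
    clusters = cluster_guides(ds, 5)

    # oracle: transitive closure over the brute-force adjacency matrix
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    g.add_edges_from(brute_force_pairs([s + "GG" for s in seqs], 4))
    expected = {frozenset(records[i].id for i in comp)
                for comp in nx.connected_components(g)}
    assert _partition(clusters) == expected

    shuffled = Dataset(records=[records[i] for i in rng.permutation(len(records))],
                       name="y")
    assert _partition(cluster_guides(shuffled, 5)) == expected


# ---------------------------------------------------------------------------
# splitting


def singleton_clusters(n):
    ds = make_dataset(n, seed=8, with_features=False)
    return cluster_guides(ds, 5), ds


def test_quota_split_of_singletons_is_exact():
    clusters, _ = singleton_clusters(100)
    assert all(c.size == 1 for c in clusters)
    plan = split_by_clusters(clusters, 0.15)
    assert len(plan.test_ids) == 15 and len(plan.train_ids) == 85


def test_giant_cluster_goes_to_train_with_warning():
    from crisprtl.leakage import GuideCluster
    giant = GuideCluster(frozenset(f"g{i}" for i in range(50)))
    with pytest.warns(UserWarning, match="exceeds both quotas"):
        plan = split_by_clusters([giant], 0.15)
    assert plan.test_ids == [] and len(plan.train_ids) == 50 and plan.warnings


def test_no_cross_set_pair_below_threshold():
    rng = np.random.default_rng(9)
    base = rand_seqs(120, 21, rng)
    seqs = base + [mutate(base[i % 40], rng.integers(1, 5), rng) for i in range(60)]
    records = [GuideRecord(id=f"r{i}", guide21=s, efficiencies={"c": 0.5})
               for i, s in enumerate(seqs)]
    ds = Dataset(records=records, name="x")
    by_id = ds.by_id()
    for ordering, seed in [("by_size_desc", None), ("random", 3)]:
        plan = split_by_clusters(cluster_guides(ds, 5), 0.2, ordering, seed)
        for tr in plan.train_ids:
            for te in plan.test_ids:
                assert hamming(by_id[tr].guide23, by_id[te].guide23) >= 5


def test_constrain_test_complete_moves_incomplete_records():
    ds = make_dataset(50, seed=10, conditions=("WT", "Esp", "HF"),
                      with_features=False)
    # make 20% of records incomplete
    rng = np.random.default_rng(0)
    incomplete = rng.choice(50, size=10, replace=False)
    for i in incomplete:
        del ds.records[i].efficiencies["HF"]
    clusters = cluster_guides(ds, 5)
    plan = split_by_clusters(clusters, 0.3, ordering="random", seed=1)
    fixed = constrain_test_complete(plan, ds, ["WT", "Esp", "HF"])
    by_id = ds.by_id()
    assert all(len(by_id[r].efficiencies) == 3 for r in fixed.test_ids)
    assert set(fixed.train_ids) | set(fixed.test_ids) == set(by_id)
    complete_plan = constrain_test_complete(fixed, ds, ["WT", "Esp", "HF"])
    assert complete_plan.test_ids == fixed.test_ids  # already complete: unchanged


# ---------------------------------------------------------------------------
# source-target leakage removal


def test_empty_target_list_is_identity(small_pair):
    src, _, _, _ = small_pair
    assert remove_source_leakage(src, []) is src


def test_exactly_the_planted_near_duplicates_are_removed(tmp_path):
    rng = np.random.default_rng(12)
    src = make_dataset(150, seed=13, with_features=False)
    tgt = make_dataset(40, seed=14, with_features=False)
    # plant k source records that are <4 mutations from target guides
    k = 7
    planted = []
    for j in range(k):
        g = mutate(tgt.records[j].guide21, rng.integers(0, 4), rng)
        rec = GuideRecord(id=f"planted{j}", guide21=g, efficiencies={"WT": 0.5})
        src.records.append(rec)
        planted.append(rec.id)
    filtered = remove_source_leakage(src, [tgt], max_dist=3,
                                     log_path=tmp_path / "removed.tsv")
    removed = {r.id for r in src} - {r.id for r in filtered}
    assert removed == set(planted)
    # survivors verified exhaustively
    for r in filtered:
        for t in tgt:
            assert hamming(r.guide23, t.guide23) >= 4
    log = (tmp_path / "removed.tsv").read_text().splitlines()
    assert len(log) == k + 1  # header + one line per removal
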