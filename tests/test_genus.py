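"""Sharing statistics and label-free architecture similarity."""

import itertools

import numpy as np
import pytest

import bgcline as bg


def test_genus_summary_on_fixture(inv):
    s = bg.genus_summary(inv)
    assert s.total_clusters == 56
    assert s.distinct_types == 40
    assert s.shared_groups == 9
    assert s.unshared_clusters == 31
    assert s.specific_per_strain == {
        "flavus": 5, "rumicis": 8, "houttuyneae": 10, "suffuscus": 8}


def test_per_strain_category_table(inv):
    s = bg.genus_summary(inv)
    expected = {
        "flavus": {"t1pks": 2, "t3pks": 1, "t1pks_t3pks": 1, "nrps": 3,
                   "pks_nrps": 3, "total": 10},
        "rumicis": {"t1pks": 3, "t3pks": 3, "t1pks_t3pks": 0, "nrps": 6,
                    "pks_nrps": 2, "total": 14},
        "houttuyneae": {"t1pks": 4, "t3pks": 3, "t1pks_t3pks": 0, "nrps": 7,
                        "pks_nrps": 4, "total": 18},
        "suffuscus": {"t1pks": 2, "t3pks": 2, "t1pks_t3pks": 0, "nrps": 5,
                      "pks_nrps": 5, "total": 14},
    }
    assert s.per_strain == expected


def test_sharing_matrix(inv):
    m = bg.sharing_matrix(inv)
    assert m.loc["houttuyneae", "suffuscus"] == 6
    assert m.loc["suffuscus", "houttuyneae"] == 6
    assert (m.values == m.values.T).all()
    for s in inv.strains:
        assert m.loc[s, s] == sum(1 for c in inv.clusters if c.strain == s)


def test_sharing_matrix_disjoint_strains():
    inv = bg.generate_inventory(2, 0, [2, 3], seed=1)
    m = bg.sharing_matrix(inv)
    assert m.iloc[0, 1] == 0 and m.iloc[1, 0] == 0


def test_summary_invariants_on_random_inventories():
    rng = np.random.default_rng(5)
    for _ in range(8):
        n_strains = int(rng.integers(2, 5))
        inv = bg.generate_inventory(
            n_strains, int(rng.integers(0, 6)),
            [int(k) for k in rng.integers(0, 5, size=n_strains)],
            seed=int(rng.integers(2 ** 31)))
        s = bg.genus_summary(inv)
        assert s.total_clusters == sum(v["total"] for v in s.per_strain.values())
        assert s.distinct_types == s.shared_groups + s.unshared_clusters
        assert s.unshared_clusters == sum(s.specific_per_strain.values())


def test_single_strain_inventory_all_specific():
    inv = bg.generate_inventory(1, 0, [4], seed=3)
    s = bg.genus_summary(inv)
    assert s.shared_groups == 0
    assert s.distinct_types == s.total_clusters == 4


def _lcs(a, b):
    # brute-force alignment oracle (match 1 / mismatch 0 / gap 0 == LCS)
    if not a or not b:
        return 0
    if a[-1] == b[-1]:
        return 1 + _lcs(a[:-1], b[:-1])
    return max(_lcs(a[:-1], b), _lcs(a, b[:-1]))


def test_similarity_examples(inv):
    a = inv.get("flavus", "t1pks-1")
    b = inv.get("suffuscus", "t1pks-1")
    assert bg.architecture_similarity(a, b) == 1.0
    assert bg.architecture_similarity(a, a) == 1.0
    f = inv.get("flavus", "nrps-3")
    r = inv.get("rumicis", "nrps-3")
    assert bg.architecture_similarity(f, r) < 1.0


def test_similarity_symmetric_and_matches_brute_force():
    rng = np.random.default_rng(9)
    clusters = [bg.generate_line(bg.random_chain(rng, max_len=4),
                                 seed=int(rng.integers(2 ** 31)),
                                 cluster_id=f"c{i}") for i in range(5)]
    from bgcline.genus import _module_signatures
    for a, b in itertools.combinations(clusters, 2):
        s_ab = bg.architecture_similarity(a, b)
        s_ba = bg.architecture_similarity(b, a)
        assert s_ab == pytest.approx(s_ba)
        sa, sb = _module_signatures(a), _module_signatures(b)
        assert s_ab == pytest.approx(_lcs(sa, sb) / max(len(sa), len(sb)))
        assert (s_ab == 1.0) == (sa == sb)
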