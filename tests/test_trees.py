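"""Distances, UPGMA, calibration, Newick round trips, Robinson–Foulds."""

import numpy as np
import pytest

import cpgphylo as cp
from cpgphylo.trees import Node, _bipartitions


def _msa(*rows, ids=None):
    ids = ids or [f"t{i}" for i in range(len(rows))]
    return cp.Msa(ids=list(ids), rows=list(rows))


# ---------------------------------------------------------------------------
# Percent identity and p-distance
# ---------------------------------------------------------------------------

def test_percent_identity_examples():
    assert cp.percent_identity(_msa("ACGT", "ACGT")).pid[0, 1] == 100.0
    assert cp.percent_identity(_msa("ACGT", "ACGA")).pid[0, 1] == 75.0
    # gap column excluded from numerator and denominator
    assert cp.percent_identity(_msa("AC-T", "ACGT")).pid[0, 1] == 100.0


def test_percent_identity_no_overlap_errors():
    with pytest.raises(ValueError, match="no co-ungapped"):
        cp.percent_identity(_msa("A--A", "-CC-"))


def test_p_distance_examples():
    assert np.all(cp.p_distance(_msa("ACGT", "ACGT")).d == 0)
    m = cp.RecodedMatrix(ids=["a", "b"], characters=["AAT", "ATT"],
                         position_index=[0, 1, 2])
    assert cp.p_distance(m).d[0, 1] == pytest.approx(1 / 3)


def test_p_distance_indel_scoring():
    # gap-vs-base counts once with count_indels; gap-vs-gap never counts
    msa = _msa("AC-TA-", "ACGTA-")
    assert cp.p_distance(msa).d[0, 1] == 0.0
    assert cp.p_distance(msa, count_indels=True).d[0, 1] == pytest.approx(1 / 5)


def test_p_distance_matches_brute_force():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n, L = int(rng.integers(2, 7)), int(rng.integers(4, 40))
        rows = ["".join(rng.choice(list("ACGT-N"), size=L,
                                   p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
                for _ in range(n)]
        rows = [r if set(r) != {"-"} else "A" + r[1:] for r in rows]
        msa = cp.Msa(ids=[f"s{i}" for i in range(n)], rows=rows)
        for count_indels in (False, True):
            try:
                dm = cp.p_distance(msa, count_indels=count_indels)
            except ValueError:
                continue  # a pair with no comparable positions
            for i in range(n):
                for j in range(i + 1, n):
                    comp = mism = 0
                    for x, y in zip(rows[i], rows[j]):
                        if x in "-N" and y in "-N":
                            continue
                        if x in "-N" or y in "-N":
                            if count_indels and "-" in (x, y):
                                comp += 1
                                mism += 1
                            continue
                        comp += 1
                        mism += x != y
                    assert dm.d[i, j] == pytest.approx(mism / comp)


def test_pid_and_p_distance_complementary_on_gap_free_alignment():
    rng = np.random.default_rng(21)
    rows = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(5)]
    msa = cp.Msa(ids=[f"s{i}" for i in range(5)], rows=rows)
    pid = cp.percent_identity(msa).pid
    d = cp.p_distance(msa).d
    assert np.allclose(pid / 100 + d, 1.0)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_two_taxa():
    dm = cp.DistanceMatrix(ids=["A", "B"], d=np.array([[0.0, 2.0], [2.0, 0.0]]))
    t = cp.upgma(dm)
    assert t.root.height == 1.0
    assert sorted(t.leaf_labels()) == ["A", "B"]


def test_upgma_three_taxa_heights():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    t = cp.upgma(cp.DistanceMatrix(ids=["A", "B", "C"], d=d))
    assert t.root.height == 2.0
    assert t.mrca("A", "B").height == 1.0


def test_upgma_rejects_nan_and_negative():
    bad = np.array([[0, np.nan], [np.nan, 0]])
    with pytest.raises(ValueError):
        cp.upgma(cp.DistanceMatrix(ids=["A", "B"], d=bad))
    with pytest.raises(ValueError):
        cp.upgma(cp.DistanceMatrix(ids=["A", "B"],
                                   d=np.array([[0.0, -1.0], [-1.0, 0.0]])))


def _random_ultrametric(rng, n):
    """Random clock tree with well-separated merge heights and its exact
    leaf-pair distance matrix (d = 2 × MRCA height)."""
    labels = [f"x{i:02d}" for i in range(n)]
    nodes = [Node(height=0.0, label=l) for l in labels]
    heights = np.cumsum(rng.uniform(0.5, 1.5, size=n - 1))
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(height=float(h), children=[a, b]))
    tree = cp.ClockTree(root=nodes[0])
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 2 * tree.mrca(a, labels[j]).height
    return tree, cp.DistanceMatrix(ids=labels, d=d)


def test_upgma_reconstructs_random_ultrametric_trees_exactly():
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(5, 16))
        truth, dm = _random_ultrametric(rng, n)
        rec = cp.upgma(dm)
        assert cp.rf_distance(rec, truth) == 0
        assert rec.max_height_spread() < 1e-9
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert rec.mrca(a, b).height == pytest.approx(
                    truth.mrca(a, b).height, abs=1e-9)


def test_upgma_heights_match_scipy_average_linkage():
    """Independent oracle: scipy's average-linkage cophenetic distances."""
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(31)
    for _ in range(10):
        n = int(rng.integers(4, 10))
        m = rng.uniform(0.1, 2.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = cp.DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d)
        tree = cp.upgma(dm)
        coph = squareform(cophenet(average(squareform(d))))
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, n):
                assert 2 * tree.mrca(a, dm.ids[j]).height == pytest.approx(
                    coph[i, j], rel=1e-9)


def test_upgma_always_ultrametric_on_random_input():
    rng = np.random.default_rng(37)
    for _ in range(20):
        n = int(rng.integers(3, 12))
        m = rng.uniform(0, 1, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        t = cp.upgma(cp.DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d))
        assert t.max_height_spread() < 1e-9


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _three_taxon_tree():
    d = np.array([[0, 0.001, 0.004], [0.001, 0, 0.004], [0.004, 0.004, 0]])
    return cp.upgma(cp.DistanceMatrix(ids=["A", "B", "C"], d=d))


def test_calibrate_scales_all_heights_linearly():
    t = _three_taxon_tree()  # MRCA(A,B) at 0.0005, root at 0.002
    cal = cp.calibrate(t, ("A", "B"), 1.7)
    assert cal.mrca("A", "B").height == pytest.approx(1.7)
    assert cal.root.height == pytest.approx(6.8)
    assert cal.time_scale == pytest.approx(3400)


def test_calibrate_on_root_sets_root_age():
    t = _three_taxon_tree()
    cal = cp.calibrate(t, ("A", "C"), 10.0)
    assert cal.root.height == pytest.approx(10.0)


def test_calibrate_idempotent_up_to_scale():
    t = _three_taxon_tree()
    once = cp.calibrate(t, ("A", "B"), 1.7)
    twice = cp.calibrate(once, ("A", "B"), 1.7)
    assert cp.to_newick(once) == cp.to_newick(twice)


def test_calibrate_zero_height_mrca_errors():
    d = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
    t = cp.upgma(cp.DistanceMatrix(ids=["A", "B", "C"], d=d))
    with pytest.raises(ValueError, match="cannot calibrate"):
        cp.calibrate(t, ("A", "B"), 1.7)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def test_two_leaf_newick():
    dm = cp.DistanceMatrix(ids=["A", "B"], d=np.array([[0.0, 2.0], [2.0, 0.0]]))
    assert cp.to_newick(cp.upgma(dm)) == "(A:1,B:1);"


def test_newick_round_trip_on_random_trees(tmp_path):
    rng = np.random.default_rng(19)
    for k in range(20):
        n = int(rng.integers(3, 12))
        truth, _ = _random_ultrametric(rng, n)
        p = tmp_path / f"t{k}.nwk"
        cp.write_newick(truth, p)
        back = cp.read_newick(p)
        assert cp.rf_distance(truth, back) == 0
        for i, a in enumerate(truth.leaf_labels()):
            for b in truth.leaf_labels()[i + 1:]:
                assert back.mrca(a, b).height == pytest.approx(
                    truth.mrca(a, b).height, abs=1e-9)


def test_newick_output_parses_with_dendropy():
    import dendropy

    truth, _ = _random_ultrametric(np.random.default_rng(20), 6)
    dt = dendropy.Tree.get(data=cp.to_newick(truth), schema="newick")
    assert {l.taxon.label for l in dt.leaf_node_iter()} == set(truth.leaf_labels())


def test_malformed_newick_errors():
    with pytest.raises(ValueError, match="malformed Newick"):
        cp.read_newick("((A:1,B:1;")


# ---------------------------------------------------------------------------
# Robinson–Foulds
# ---------------------------------------------------------------------------

def _tree_from_newick(s):
    return cp.read_newick(s)


def test_rf_identical_trees_zero():
    t, _ = _random_ultrametric(np.random.default_rng(23), 8)
    assert cp.rf_distance(t, t) == 0


def test_rf_four_taxon_alternative_topologies():
    t1 = _tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = _tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert cp.rf_distance(t1, t2) == 2


def test_rf_leaf_set_mismatch_errors():
    t1 = _tree_from_newick("(A:1,B:1);")
    t2 = _tree_from_newick("(A:1,C:1);")
    with pytest.raises(ValueError, match="leaf sets differ"):
        cp.rf_distance(t1, t2)


def test_rf_matches_dendropy_on_random_pairs():
    import dendropy

    rng = np.random.default_rng(23)
    for _ in range(25):
        n = int(rng.integers(4, 12))
        t1, _ = _random_ultrametric(rng, n)
        t2, _ = _random_ultrametric(rng, n)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=cp.to_newick(t1), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=cp.to_newick(t2), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert cp.rf_distance(t1, t2) == expected
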