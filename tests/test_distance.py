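"""Distance engine: site counting, K2P correction, similarity, NJ trees."""

from __future__ import annotations

import decimal
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeaudit.distance import (
    ComparisonError,
    DistanceMatrix,
    PairwiseComparison,
    SaturationError,
    compare_pair,
    distance_matrix,
    k2p_distance,
    nj_tree,
    p_distance,
    similarity_percent,
    similarity_matrix,
)
from barcodeaudit.tree import TreeNode

from conftest import make_record, mutate_at, random_seq


def k2p_decimal(p: float, q: float, prec: int = 50) -> float:
    """Independent high-precision evaluation of the K2P closed form."""
    with decimal.localcontext() as ctx:
        ctx.prec = prec
        P, Q = decimal.Decimal(repr(p)), decimal.Decimal(repr(q))
        one = decimal.Decimal(1)
        arg = (one - 2 * P - Q) * (one - 2 * Q).sqrt()
        return float(decimal.Decimal(-0.5) * arg.ln())


class TestComparePair:
    def test_identical(self):
        seq = "ACGT" * 25
        cmp = compare_pair(seq, seq)
        assert (cmp.sites_compared, cmp.transitions, cmp.transversions) == (100, 0, 0)
        assert cmp.P == 0 and cmp.Q == 0

    def test_transitions_and_transversions_counted(self):
        rng = np.random.default_rng(0)
        a = "A" * 100
        # 10 transitions A->G, 5 transversions A->T at fixed positions
        b = mutate_at(a, {i: "G" for i in range(10)} | {i: "T" for i in range(50, 55)})
        cmp = compare_pair(a, b)
        assert (cmp.sites_compared, cmp.transitions, cmp.transversions) == (100, 10, 5)
        assert cmp.P == pytest.approx(0.10)
        assert cmp.Q == pytest.approx(0.05)

    def test_ambiguity_and_gap_sites_excluded(self):
        a = "ACGT" * 25
        b = mutate_at(a, {0: "N", 10: "N", 20: "N"})
        assert compare_pair(a, b).sites_compared == 97
        c = mutate_at(a, {5: "-", 6: "R"})
        assert compare_pair(a, c).sites_compared == 98

    def test_errors(self):
        with pytest.raises(ComparisonError):
            compare_pair("ACGT", "ACGTA")
        with pytest.raises(ComparisonError):
            compare_pair("NNNN", "ACGT")


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(PairwiseComparison(100, 0, 0)) == 0.0

    def test_closed_form_example(self):
        # P=0.10, Q=0.05 evaluated independently at high precision
        cmp = PairwiseComparison(100, 10, 5)
        assert k2p_distance(cmp) == pytest.approx(0.17018, abs=1e-4)
        assert k2p_distance(cmp) == pytest.approx(k2p_decimal(0.10, 0.05), abs=1e-12)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            k2p_distance(PairwiseComparison(100, 50, 5))  # 1-2P-Q < 0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 600), st.integers(0, 600))
    def test_k2p_dominates_p_distance(self, ts, tv):
        # Jensen inequality: the correction never shrinks the raw distance
        cmp = PairwiseComparison(2000, ts, tv)
        if 1 - 2 * cmp.P - cmp.Q <= 0 or 1 - 2 * cmp.Q <= 0:
            return
        assert k2p_distance(cmp) >= p_distance(cmp) - 1e-12


class TestSimilarity:
    @pytest.mark.parametrize(
        "sites,mismatches,expected",
        [(650, 0, 100.00), (650, 2, 99.69), (640, 3, 99.53)],
    )
    def test_reported_values(self, sites, mismatches, expected):
        cmp = PairwiseComparison(sites, mismatches, 0)
        assert similarity_percent(cmp) == expected

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(1, 658), st.data())
    def test_similarity_complements_p_distance(self, sites, data):
        mism = data.draw(st.integers(0, sites))
        cmp = PairwiseComparison(sites, mism, 0)
        assert similarity_percent(cmp, rounded=False) == pytest.approx(
            100.0 * (1.0 - p_distance(cmp))
        )


class TestDistanceMatrix:
    def test_identical_records_zero(self):
        seq = random_seq(np.random.default_rng(1))
        recs = [make_record("a", seq), make_record("b", seq)]
        dm = distance_matrix(recs)
        assert np.allclose(dm.values, 0.0)

    def test_matches_pairwise_recomputation(self):
        rng = np.random.default_rng(2)
        recs = []
        base = random_seq(rng, 400)
        for i in range(10):
            muts = {int(p): "ACGT"[int(b)] for p, b in
                    zip(rng.integers(0, 400, size=rng.integers(0, 40)), rng.integers(0, 4, size=40))}
            recs.append(make_record(f"r{i}", mutate_at(base, muts)))
        dm = distance_matrix(recs, metric="k2p")
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                cmp = compare_pair(recs[i].sequence, recs[j].sequence)
                assert dm.values[i, j] == pytest.approx(k2p_distance(cmp), abs=1e-12)

    def test_permutation_relabels_consistently(self):
        rng = np.random.default_rng(3)
        recs = [make_record(f"r{i}", random_seq(rng, 300)) for i in range(6)]
        dm = distance_matrix(recs)
        perm = [3, 1, 5, 0, 2, 4]
        dm2 = distance_matrix([recs[i] for i in perm])
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert dm2.values[a, b] == pytest.approx(dm.values[i, j])

    def test_similarity_matrix_matches_compare_pair(self):
        rng = np.random.default_rng(4)
        refs = [make_record(f"r{i}", random_seq(rng, 250)) for i in range(5)]
        qs = [make_record(f"q{i}", random_seq(rng, 250), role="query",
                          morphology_label="X y") for i in range(3)]
        sims = similarity_matrix(qs, refs)
        for i, q in enumerate(qs):
            for j, r in enumerate(refs):
                cmp = compare_pair(q.sequence, r.sequence)
                assert sims[i, j] == pytest.approx(similarity_percent(cmp, rounded=False))


# ---------------------------------------------------------------------------
# neighbor joining


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths; returns the root.

    Built by sequential attachment, so every topology is reachable.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(label=l) for l in labels[:3]]
    root = TreeNode()
    for node in nodes:
        root.children.append((node, float(rng.uniform(0.05, 0.5))))
    edges = list(range(3))  # indices into a flat edge list we rebuild below

    def all_edges(node):
        out = []
        for k, (child, length) in enumerate(node.children):
            out.append((node, k))
            out.extend(all_edges(child))
        return out

    for label in labels[3:]:
        candidates = all_edges(root)
        parent, k = candidates[int(rng.integers(0, len(candidates)))]
        child, length = parent.children[k]
        split = float(rng.uniform(0.2, 0.8)) * length
        mid = TreeNode()
        mid.children.append((child, length - split))
        mid.children.append((TreeNode(label=label), float(rng.uniform(0.05, 0.5))))
        parent.children[k] = (mid, split)
    return root


def tree_distance_matrix(root: TreeNode) -> DistanceMatrix:
    paths = root.leaf_path_lengths()
    labels = sorted(l.label for l in root.leaves())
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = paths[frozenset((labels[i], labels[j]))]
    return DistanceMatrix(ids=tuple(labels), values=vals, metric="k2p")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        vals = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        dm = DistanceMatrix(ids=("a", "b", "c"), values=vals, metric="k2p")
        tree = nj_tree(dm)
        lengths = {child.label: l for child, l in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (8, 2)])
    def test_additive_matrix_recovery(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        true = random_additive_tree(rng, n_taxa)
        dm = tree_distance_matrix(true)
        recovered = nj_tree(dm)
        paths = recovered.leaf_path_lengths()
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert paths[frozenset((a, b))] == pytest.approx(
                    dm.get(a, b), abs=1e-9
                ), f"path {a}-{b}"

    def test_agrees_with_independent_nj_on_additive_input(self):
        # cross-check against scikit-bio's neighbor joining
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        true = random_additive_tree(rng, 7)
        dm = tree_distance_matrix(true)
        sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.ids))
        sk_tree = skbio.tree.nj(sk_dm)
        ours = nj_tree(dm).leaf_path_lengths()
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                assert ours[frozenset((a, b))] == pytest.approx(sk_d, abs=1e-6)

    def test_saturated_matrix_rejected(self):
        vals = np.array([[0.0, np.inf, 0.2], [np.inf, 0.0, 0.3], [0.2, 0.3, 0.0]])
        dm = DistanceMatrix(ids=("a", "b", "c"), values=vals, metric="k2p")
        with pytest.raises(SaturationError):
            nj_tree(dm)
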