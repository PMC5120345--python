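"""Tests for NJ construction, bootstrap supports, clusters, identity and gap."""
from __future__ import annotations

import numpy as np
import pytest

from rakerid.barcode_core import (
    DistanceMatrix,
    ReferencePanel,
    SequenceRecord,
    UNKNOWN,
    distance_matrix,
)
from rakerid.tree_cluster import (
    GapSummary,
    TreeError,
    UNASSIGNED,
    UNRESOLVED,
    assign_by_identity,
    barcoding_gap,
    bootstrap_support,
    extract_clusters,
    neighbor_joining,
)

from conftest import path_distance_matrix, random_additive_tree, tree_splits_oracle


def dmat(labels, d):
    d = np.asarray(d, dtype=float)
    n = len(labels)
    ones = np.ones((n, n))
    return DistanceMatrix(tuple(labels), d, ones, np.zeros((n, n)), np.zeros((n, n)))


def rec(id_, residues, species=UNKNOWN, marker="COI"):
    return SequenceRecord(id_, marker, species, residues)


# ------------------------------------------------------------ neighbor_joining


class TestNeighborJoining:
    def test_two_taxa_even_split(self):
        tree = neighbor_joining(dmat(["A", "B"], [[0, 0.2], [0.2, 0]]))
        (c1, l1), (c2, l2) = tree.root.children
        assert {c1.name, c2.name} == {"A", "B"}
        assert l1 == pytest.approx(0.1)
        assert l2 == pytest.approx(0.1)

    def test_four_taxon_additive_exact(self):
        # true tree ((A:0.1,B:0.2):0.05,(C:0.3,D:0.4)) -> path-sum distances
        labels = ["A", "B", "C", "D"]
        d = [
            [0.0, 0.3, 0.45, 0.55],
            [0.3, 0.0, 0.55, 0.65],
            [0.45, 0.55, 0.0, 0.7],
            [0.55, 0.65, 0.7, 0.0],
        ]
        tree = neighbor_joining(dmat(labels, d))
        assert set(tree.splits()) == {frozenset({"C", "D"})} or set(tree.splits()) == {
            frozenset({"A", "B"})
        }
        # recovered tree must reproduce the input distances exactly
        recovered = _tree_distances(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert recovered[(a, b)] == pytest.approx(d[i][j], abs=1e-12)

    def test_all_zero_matrix(self):
        tree = neighbor_joining(dmat(list("ABCD"), np.zeros((4, 4))))
        dists = _tree_distances(tree)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in dists.values())

    def test_nonfinite_error(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        # rejected either at matrix construction or inside NJ
        with pytest.raises(ValueError):
            neighbor_joining(dmat(list("ABC"), d))

    def test_recovers_50_random_additive_trees(self):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n_taxa = int(rng.integers(5, 11))
            adj, leaves = random_additive_tree(rng, n_taxa)
            dm = path_distance_matrix(adj, leaves)
            tree = neighbor_joining(dm)
            assert set(tree.splits()) == tree_splits_oracle(adj, leaves), f"trial {trial}"
            recovered = _tree_distances(tree)
            for i, a in enumerate(leaves):
                for j, b in enumerate(leaves):
                    if i < j:
                        assert recovered[(a, b)] == pytest.approx(
                            dm.d[i, j], abs=1e-9
                        ), f"trial {trial}: {a}-{b}"

    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        adj, leaves = random_additive_tree(rng, 8)
        dm = path_distance_matrix(adj, leaves)
        perm = rng.permutation(len(leaves))
        labels2 = [leaves[i] for i in perm]
        d2 = dm.d[np.ix_(perm, perm)]
        tree1 = neighbor_joining(dm)
        tree2 = neighbor_joining(dmat(labels2, d2))
        assert set(tree1.splits()) == set(tree2.splits())

    def test_negative_branch_clamped(self):
        # matrix engineered to produce a negative NJ branch length
        labels = list("ABCD")
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.45],
                [0.1, 0.0, 0.45, 0.4],
                [0.4, 0.45, 0.0, 0.05],
                [0.45, 0.4, 0.05, 0.0],
            ]
        )
        tree = neighbor_joining(dmat(labels, d))
        for node, _ in _iter_edges(tree):
            pass  # traversal itself asserts structure below
        assert all(ln >= 0 for _, ln in _all_branch_lengths(tree))


def _iter_edges(tree):
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child, length in node.children:
            yield child, length
            stack.append(child)


def _all_branch_lengths(tree):
    return list(_iter_edges(tree))


def _tree_distances(tree):
    """Leaf-to-leaf path sums of a PhyloTree (independent of NJ internals)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}

    def walk(node):
        nid = id(node)
        adj.setdefault(nid, [])
        if node.is_leaf:
            names[nid] = node.name
        for child, ln in node.children:
            cid = id(child)
            adj.setdefault(cid, []).append((nid, ln))
            adj[nid].append((cid, ln))
            walk(child)

    walk(tree.root)
    out: dict[tuple[str, str], float] = {}
    for src, sname in names.items():
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst, dname in names.items():
            out[(sname, dname)] = dist[dst]
    return out


# ----------------------------------------------------------- bootstrap_support


@pytest.fixture(scope="module")
def two_group_records():
    rng = np.random.default_rng(11)
    base = rng.integers(0, 4, size=200)
    other = base.copy()
    sites = rng.choice(200, size=20, replace=False)  # 10% divergence
    other[sites] = (other[sites] + 2) % 4
    letters = "AGCT"
    seq_a = "".join(letters[x] for x in base)
    seq_b = "".join(letters[x] for x in other)
    return [rec(f"a{i}", seq_a) for i in range(10)] + [
        rec(f"b{i}", seq_b) for i in range(10)
    ]


class TestBootstrap:
    def test_separating_edge_full_support(self, two_group_records):
        tree = bootstrap_support(two_group_records, replicates=20, seed=3)
        splits = tree.splits()
        group_a = frozenset(f"a{i}" for i in range(10))
        group_b = frozenset(f"b{i}" for i in range(10))
        hit = [s for s in splits if s in (group_a, group_b)]
        assert hit and splits[hit[0]] == pytest.approx(100.0)

    def test_single_replicate_quantized(self, two_group_records):
        tree = bootstrap_support(two_group_records[:6] + two_group_records[10:16], replicates=1, seed=9)
        sups = [s for s in tree.splits().values() if s is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_seed_determinism(self, two_group_records):
        t1 = bootstrap_support(two_group_records, replicates=15, seed=4)
        t2 = bootstrap_support(two_group_records, replicates=15, seed=4)
        assert t1.to_newick() == t2.to_newick()
        assert t1.splits() == t2.splits()

    def test_supports_in_range(self, two_group_records):
        tree = bootstrap_support(two_group_records, replicates=25, seed=5)
        for s in tree.splits().values():
            assert s is None or 0.0 <= s <= 100.0

    def test_replicates_must_be_positive(self, two_group_records):
        with pytest.raises(TreeError):
            bootstrap_support(two_group_records, replicates=0, seed=1)


# ------------------------------------------------------------ extract_clusters


class TestExtractClusters:
    def test_synthetic_default_five_clusters(self, panel, specimen_set):
        records = panel.records("COI") + specimen_set.sequences["COI"]
        tree = bootstrap_support(records, replicates=50, seed=1)
        clusters = extract_clusters(tree, panel, min_support=99.0)
        species_clusters = [c for c in clusters if c.species_call != UNRESOLVED]
        assert len(species_clusters) == 5
        truth = specimen_set.truth
        for c in species_clusters:
            for member in c.members:
                if member in truth:
                    assert truth[member] == c.species_call

    def test_unreachable_threshold_unresolved(self, panel, specimen_set):
        records = panel.records("COI") + specimen_set.sequences["COI"][:10]
        tree = bootstrap_support(records, replicates=10, seed=1)
        clusters = extract_clusters(tree, panel, min_support=101.0)
        query_ids = {r.id for r in specimen_set.sequences["COI"][:10]}
        for c in clusters:
            if query_ids & set(c.members):
                assert c.species_call == UNRESOLVED

    def test_single_species_tree(self):
        rng = np.random.default_rng(1)
        letters = "AGCT"
        seq = "".join(letters[x] for x in rng.integers(0, 4, size=100))
        records = [rec(f"r{i}", seq, species="Mobula_kuhlii") for i in range(3)]
        records += [rec("q1", seq), rec("q2", seq)]
        panel1 = ReferencePanel(records[:3])
        tree = neighbor_joining(distance_matrix(records))
        clusters = extract_clusters(tree, panel1, min_support=99.0)
        assert len(clusters) == 1
        assert set(clusters[0].members) == {r.id for r in records}
        assert clusters[0].species_call == "Mobula_kuhlii"

    def test_no_references_error(self, specimen_set, panel):
        queries = specimen_set.sequences["COI"][:4]
        tree = neighbor_joining(distance_matrix(queries))
        with pytest.raises(TreeError, match="no reference"):
            extract_clusters(tree, panel, 99.0)

    def test_manta_complex_caveat(self, panel, specimen_set):
        records = panel.records("COI") + specimen_set.sequences["COI"]
        tree = bootstrap_support(records, replicates=20, seed=1)
        clusters = extract_clusters(tree, panel, min_support=99.0)
        for c in clusters:
            if c.species_call == "Manta_birostris":
                assert c.complex_caveat
            elif c.species_call.startswith("Mobula"):
                assert not c.complex_caveat


# ---------------------------------------------------------- assign_by_identity


class TestAssignByIdentity:
    @pytest.fixture(scope="class")
    def small_panel(self):
        rng = np.random.default_rng(21)
        letters = "AGCT"
        a = "".join(letters[x] for x in rng.integers(0, 4, size=100))
        b_codes = rng.integers(0, 4, size=100)
        b = "".join(letters[x] for x in b_codes)
        return a, b, ReferencePanel(
            [
                rec("ref_jap", a, species="Mobula_japanica"),
                rec("ref_tar", b, species="Mobula_tarapacana"),
            ]
        )

    def test_exact_match(self, small_panel):
        a, _, panel = small_panel
        res = assign_by_identity(rec("q", a), panel)
        assert res.species == "Mobula_japanica"
        assert res.identity == 1.0

    def test_below_threshold_unassigned(self, small_panel):
        a, _, panel = small_panel
        # 2 mismatches in 100 sites -> identity 0.98 < 0.99
        mutated = ("T" if a[0] != "T" else "G") + ("T" if a[1] != "T" else "G") + a[2:]
        res = assign_by_identity(rec("q", mutated), panel, min_identity=0.99)
        assert res.species == UNASSIGNED
        assert res.identity == pytest.approx(0.98)

    def test_synthetic_queries_recover_truth(self, panel, specimen_set):
        for marker in ("COI", "NADH2"):
            for query in specimen_set.sequences[marker]:
                res = assign_by_identity(query, panel)
                assert res.species == specimen_set.truth[query.id]
                assert res.identity >= 0.98

    def test_tie_reported_first_wins(self):
        seq = "ACGT" * 25
        panel2 = ReferencePanel(
            [
                rec("r1", seq, species="Mobula_kuhlii"),
                rec("r2", seq, species="Mobula_thurstoni"),
            ]
        )
        res = assign_by_identity(rec("q", seq), panel2)
        assert res.species == "Mobula_kuhlii"
        assert res.best_ref == "r1"
        assert "r2" in res.tied_refs

    def test_manta_caveat_flag(self, panel, specimen_set):
        for query in specimen_set.sequences["COI"]:
            res = assign_by_identity(query, panel)
            assert res.complex_caveat == (res.species == "Manta_birostris")


# --------------------------------------------------------------- barcoding_gap


class TestBarcodingGap:
    def test_two_species_simple(self):
        d = np.array(
            [
                [0.0, 0.0, 0.08],
                [0.0, 0.0, 0.08],
                [0.08, 0.08, 0.0],
            ]
        )
        dm = dmat(["a1", "a2", "b1"], d)
        g = barcoding_gap(dm, {"a1": "A", "a2": "A", "b1": "B"})
        assert (g.intra_min, g.intra_max) == (0.0, 0.0)
        assert g.inter_min == pytest.approx(8.0)
        assert g.inter_max == pytest.approx(8.0)

    def test_unknown_excluded(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = 0.5  # saturated-looking pair involving UNKNOWN
        d[1, 2] = d[2, 1] = 0.5
        dm = dmat(["a1", "a2", "x"], d)
        with pytest.raises(TreeError):
            # only one species after exclusion -> no inter pair
            barcoding_gap(dm, {"a1": "A", "a2": "A", "x": UNKNOWN})

    def test_all_unknown_error(self):
        dm = dmat(["x", "y"], [[0, 0.1], [0.1, 0]])
        with pytest.raises(TreeError, match="UNKNOWN"):
            barcoding_gap(dm, {"x": UNKNOWN, "y": UNKNOWN})

    def test_synthetic_default_gap_exists(self, panel):
        for marker in ("COI", "NADH2"):
            dm = distance_matrix(panel.records(marker))
            g = barcoding_gap(dm, panel.species_map())
            assert g.gap_exists, marker
            assert g.intra_max <= 2.0  # intra stays around the ~1% scale
            assert g.inter_min >= 3.0

    def test_label_permutation_destroys_gap(self, panel):
        dm = distance_matrix(panel.records("COI"))
        labels = panel.species_map()
        ids = list(dm.labels)
        rng = np.random.default_rng(13)
        destroyed = 0
        for _ in range(20):
            perm = rng.permutation(len(ids))
            shuffled = {ids[i]: labels[ids[int(perm[i])]] for i in range(len(ids))}
            g = barcoding_gap(dm, shuffled)
            destroyed += not g.gap_exists
        assert destroyed >= 18  # with high probability the gap collapses

    def test_invariant_ranges(self):
        with pytest.raises(ValueError):
            GapSummary(intra_min=1.0, intra_max=0.5, inter_min=0, inter_max=0)
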