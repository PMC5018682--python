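"""Neighbor joining against additive-matrix oracles; clustering; bootstrap."""

import itertools

import numpy as np
import pytest

from opsin_charter import (Alignment, FormatError, PairMatrix, assign_cluster,
                           bootstrap_support, distance_from_identity, make_family,
                           make_opsin, neighbor_joining, triangle_violations,
                           write_newick)


def random_additive_matrix(rng, labels):
    """Distances from a random binary tree with positive branch lengths.

    Returns (matrix, bipartition set) — the generating topology is the
    oracle for what neighbor joining must recover.
    """
    # each working cluster tracks the distance from its leaves to its root
    work = [{l: 0.0} for l in labels]
    d: dict = {}
    splits = set()
    while len(work) > 1:
        i, j = sorted(rng.choice(len(work), size=2, replace=False))
        a, b = work[int(i)], work[int(j)]
        bl_a = float(rng.uniform(0.05, 1.0))
        bl_b = float(rng.uniform(0.05, 1.0))
        for x, dx in a.items():
            for y, dy in b.items():
                d[(x, y)] = d[(y, x)] = dx + bl_a + dy + bl_b
        new = {**{x: dx + bl_a for x, dx in a.items()},
               **{y: dy + bl_b for y, dy in b.items()}}
        work = [work[k] for k in range(len(work)) if k not in (int(i), int(j))]
        work.append(new)
        if 2 <= len(new) <= len(labels) - 2:
            splits.add(frozenset(new))
    n = len(labels)
    m = np.zeros((n, n))
    for ii, x in enumerate(labels):
        for jj, y in enumerate(labels):
            if ii != jj:
                m[ii, jj] = d[(x, y)]
    ref = min(labels)
    canon = {frozenset(set(labels) - s) if ref in s else s for s in splits}
    return PairMatrix(labels=tuple(labels), values=m, metric="distance"), canon


class TestDistanceFromIdentity:
    def test_full_identity_maps_to_zero(self):
        m = PairMatrix(labels=("a", "b"), values=np.full((2, 2), 100.0),
                       metric="identity")
        d = distance_from_identity(m)
        assert np.allclose(d.values, 0.0)

    def test_published_pair_value(self, reference_identity):
        d = distance_from_identity(reference_identity)
        assert d.get("Rh1", "Rh2") == pytest.approx(0.3084)

    def test_published_table_satisfies_triangle_inequality(self, reference_identity):
        d = distance_from_identity(reference_identity)
        assert triangle_violations(d) == []

    def test_non_identity_matrix_rejected(self):
        m = PairMatrix(labels=("a", "b"), values=np.zeros((2, 2)), metric="distance")
        with pytest.raises(FormatError):
            distance_from_identity(m)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = PairMatrix(labels=("a", "b", "c"),
                       values=np.array([[0.0, 0.3, 0.5],
                                        [0.3, 0.0, 0.6],
                                        [0.5, 0.6, 0.0]]),
                       metric="distance")
        t = neighbor_joining(m)
        assert t.path_length("a", "b") == pytest.approx(0.3)
        assert t.path_length("a", "c") == pytest.approx(0.5)
        assert t.path_length("b", "c") == pytest.approx(0.6)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_recovers_generating_topology_on_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        seen = set()
        for _ in range(40):
            m, true_splits = random_additive_matrix(rng, labels)
            t = neighbor_joining(m)
            assert t.bipartitions() == true_splits
            for a, b in itertools.combinations(labels, 2):
                assert t.path_length(a, b) == pytest.approx(m.get(a, b))
            seen.add(frozenset(true_splits))
        # the sampler visits several distinct topologies at each size
        assert len(seen) >= 3

    def test_taxon_order_permutation_invariance(self, reference_identity):
        d = distance_from_identity(reference_identity)
        t1 = neighbor_joining(d)
        perm = list(reversed(range(len(d.labels))))
        d2 = PairMatrix(labels=tuple(d.labels[i] for i in perm),
                        values=d.values[np.ix_(perm, perm)], metric="distance")
        t2 = neighbor_joining(d2)
        assert t1.bipartitions() == t2.bipartitions()

    def test_fewer_than_three_taxa_rejected(self):
        m = PairMatrix(labels=("a", "b"), values=np.array([[0.0, 1.0], [1.0, 0.0]]),
                       metric="distance")
        with pytest.raises(FormatError):
            neighbor_joining(m)

    def test_published_matrix_separates_the_two_published_groups(self, reference_identity):
        t = neighbor_joining(distance_from_identity(reference_identity))
        assert frozenset({"Rh3", "Rh4", "Rh5", "Rh7"}) in t.bipartitions()
        assert frozenset({"Rh3", "Rh4", "Rh5"}) in t.bipartitions()


class TestNewickRoundTrip:
    def test_topology_lengths_and_leaves_survive(self, tmp_path, reference_identity):
        dendropy = pytest.importorskip("dendropy")
        t = neighbor_joining(distance_from_identity(reference_identity))
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = dendropy.Tree.get(path=str(p), schema="newick")
        leaves = {l.taxon.label for l in back.leaf_node_iter()}
        assert leaves == set(t.leaves)
        pdm = back.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in back.taxon_namespace}
        for a, b in itertools.combinations(sorted(leaves), 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                t.path_length(a, b), abs=1e-4)


class TestBootstrap:
    def test_clean_family_supports_all_one(self):
        root, _ = make_opsin(2)
        leaves, _ = make_family(root, 5, 20, seed=4)
        aln = Alignment(ids=tuple(l.id for l in leaves),
                        rows=tuple(l.residues for l in leaves))
        t = bootstrap_support(aln, replicates=30, seed=9)
        for bp in t.bipartitions():
            assert t.support_of(bp) == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        root, _ = make_opsin(3)
        leaves, _ = make_family(root, 4, 30, seed=5)
        aln = Alignment(ids=tuple(l.id for l in leaves),
                        rows=tuple(l.residues for l in leaves))
        t1 = bootstrap_support(aln, replicates=25, seed=11)
        t2 = bootstrap_support(aln, replicates=25, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_single_replicate_supports_are_zero_or_one(self):
        root, _ = make_opsin(5)
        leaves, _ = make_family(root, 4, 15, seed=6)
        aln = Alignment(ids=tuple(l.id for l in leaves),
                        rows=tuple(l.residues for l in leaves))
        t = bootstrap_support(aln, replicates=1, seed=2)
        sups = {t.support_of(bp) for bp in t.bipartitions()}
        assert sups <= {0.0, 1.0}


class TestAssignCluster:
    def _matrix(self, labels, values):
        return PairMatrix(labels=labels, values=np.array(values), metric="distance")

    def test_query_identical_to_a_reference_joins_its_group(self):
        m = self._matrix(("q", "r1", "r2"),
                         [[0.0, 0.0, 0.8], [0.0, 0.0, 0.8], [0.8, 0.8, 0.0]])
        group, margin = assign_cluster("q", {"r1": "alpha", "r2": "beta"}, m)
        assert group == "alpha" and margin > 0

    def test_equidistant_query_is_unassigned(self):
        m = self._matrix(("q", "r1", "r2"),
                         [[0.0, 0.5, 0.5], [0.5, 0.0, 0.9], [0.5, 0.9, 0.0]])
        group, margin = assign_cluster("q", {"r1": "alpha", "r2": "beta"}, m)
        assert group == "unassigned" and margin == 0.0

    def test_query_among_references_rejected(self):
        m = self._matrix(("q", "r1", "r2"),
                         [[0.0, 0.5, 0.5], [0.5, 0.0, 0.9], [0.5, 0.9, 0.0]])
        with pytest.raises(FormatError):
            assign_cluster("q", {"q": "alpha", "r1": "alpha"}, m)

    def test_planted_subfamilies_recovered_for_held_out_leaves(self):
        """Leaves generated from three diverged subfamily roots are assigned
        to their planted subfamily >= 95% of the time over 50 seeds."""
        from opsin_charter import SeqRecord, build_matrix

        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        correct = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed + 1000)
            root = SeqRecord(id="root", kind="protein",
                             residues="".join(rng.choice(aas, size=100)))
            subroots, _ = make_family(root, 3, 25, seed=seed * 7 + 1,
                                      id_prefix="sub")
            leaves = []
            groups = {}
            for gi, sub in enumerate(subroots):
                fam, _ = make_family(sub, 3, 8, seed=seed * 11 + gi,
                                     id_prefix=f"g{gi}leaf")
                for leaf in fam:
                    leaves.append(leaf)
                    groups[leaf.id] = f"group{gi}"
            m = build_matrix(leaves, metric="identity")
            for held_out in (leaves[0].id, leaves[3].id, leaves[6].id):
                refs = {l.id: groups[l.id] for l in leaves if l.id != held_out}
                got, _ = assign_cluster(held_out, refs, m)
                correct += got == groups[held_out]
                total += 1
        assert correct / total >= 0.95
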