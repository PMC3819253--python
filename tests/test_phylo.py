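import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from kirfam.phylo import (
    SubstitutionModel,
    bootstrap_supports,
    complete_deletion,
    discrete_gamma_rates,
    distance_matrix,
    k2p_distance,
    log_likelihood,
    nj_tree,
    select_model,
    site_coverage_filter,
    tn93_distance,
)
from kirfam.records import Alignment, Transcript

from conftest import random_alignment


class TestK2P:
    def test_identical_sequences_distance_zero(self):
        r = k2p_distance("ACGT" * 30, "ACGT" * 30)
        assert r.d == 0.0 and r.P == 0.0 and r.Q == 0.0

    def test_formula_oracle(self):
        # P=0.1, Q=0.05 -> -1/2 ln(0.75) - 1/4 ln(0.90)
        a = "A" * 200
        b = "G" * 20 + "C" * 10 + "A" * 170
        r = k2p_distance(a, b)
        assert (r.P, r.Q) == (0.1, 0.05)
        assert r.d == pytest.approx(
            -0.5 * math.log(0.75) - 0.25 * math.log(0.90), abs=1e-12
        )

    def test_gamma_adjusted_formula(self):
        a = "A" * 200
        b = "G" * 20 + "C" * 10 + "A" * 170
        alpha = 0.7
        r = k2p_distance(a, b, gamma_alpha=alpha)
        w1, w2 = 0.75, 0.90
        expected = (alpha / 2) * (w1 ** (-1 / alpha) - 1) + (alpha / 4) * (
            w2 ** (-1 / alpha) - 1
        )
        assert r.d == pytest.approx(expected, abs=1e-12)

    def test_saturation_flagged(self):
        a = "A" * 100
        b = "G" * 60 + "C" * 40
        r = k2p_distance(a, b)
        assert r.saturated and math.isinf(r.d)

    def test_ambiguous_sites_excluded(self):
        r = k2p_distance("ACGTN-", "ACGTAA")
        assert r.n_sites == 4 and r.d == 0.0


class TestTN93:
    def test_identical_sequences(self):
        assert tn93_distance("ACGT" * 30, "ACGT" * 30).d == 0.0

    def test_equal_frequency_input_nests_to_k2p(self):
        # balanced mutations keep pooled base frequencies equal and
        # purine/pyrimidine transitions symmetric
        a = list("ACGT" * 30)
        b = a.copy()
        b[0], b[2] = "G", "A"      # A<->G swap
        b[5], b[7] = "T", "C"      # C<->T swap
        b[8], b[9] = "C", "A"      # A<->C swap
        a, b = "".join(a), "".join(b)
        assert tn93_distance(a, b).d == pytest.approx(
            k2p_distance(a, b).d, abs=1e-9
        )

    def test_fixed_pair_against_independent_oracle(self):
        # frozen value computed with ape::dist.dna(model="TN93") on the
        # same deterministic pair
        from kirfam.simulate import mutate_k2p

        rng = np.random.default_rng(42)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        b = mutate_k2p(anc, 0.12, kappa=6, seed=7)
        assert tn93_distance(anc, b).d == pytest.approx(0.09987829, abs=1e-7)


def _tree_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        key = tuple(sorted((t1.label, t2.label)))
        out[key] = pdm.distance(t1, t2)
    return out


def _random_additive_matrix(n: int, rng) -> pd.DataFrame:
    """Distances from a random binary tree with positive branch lengths."""
    labels = [f"T{i}" for i in range(n)]
    dmat = pd.DataFrame(0.0, index=labels, columns=labels)
    # each entry: (joined label, {leaf -> distance to current root})
    merged = [(lab, {lab: rng.uniform(0.05, 1.0)}) for lab in labels]
    while len(merged) > 1:
        i, j = sorted(rng.choice(len(merged), 2, replace=False))
        (na, da), (nb, db) = merged[i], merged[j]
        extra = rng.uniform(0.05, 1.0)
        for x in da:
            for y in db:
                dmat.loc[x, y] = dmat.loc[y, x] = da[x] + db[y]
        newd = {x: v + extra for x, v in {**da, **db}.items()}
        merged = [m for k, m in enumerate(merged) if k not in (i, j)]
        merged.append((na + nb, newd))
    return dmat


class TestNJ:
    def test_four_taxon_additive_exact(self):
        labels = list("ABCD")
        # tree ((A:1,B:2):1,(C:3,D:4)): internal edge 1
        mat = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = nj_tree(mat)
        recovered = _tree_distances(tree)
        for (x, y), d in recovered.items():
            assert d == pytest.approx(mat.loc[x, y], abs=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_additive_matrices_recovered(self, n):
        rng = np.random.default_rng(n)
        mat = _random_additive_matrix(n, rng)
        tree = nj_tree(mat)
        recovered = _tree_distances(tree)
        for (x, y), d in recovered.items():
            assert d == pytest.approx(mat.loc[x, y], abs=1e-8)

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        mat = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=labels, columns=labels,
        )
        tree = nj_tree(mat)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_star_matrix_internal_lengths_zero(self):
        labels = list("ABCDE")
        mat = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(mat.values, 0.0)
        tree = nj_tree(mat)
        for node in tree.preorder_internal_node_iter():
            for child in node.child_nodes():
                if not child.is_leaf():
                    assert child.edge.length == pytest.approx(0.0, abs=1e-12)

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        mat = _random_additive_matrix(7, rng)
        ours = nj_tree(mat)
        theirs = skbio_nj(DistanceMatrix(mat.to_numpy(), ids=list(mat.index)))
        ours_d = _tree_distances(ours)
        for (x, y), d in ours_d.items():
            assert d == pytest.approx(
                theirs.find(x).distance(theirs.find(y)), abs=1e-6
            )

    def test_fewer_than_three_taxa_rejected(self):
        mat = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"],
                           columns=["A", "B"], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(mat)

    def test_infinite_entries_rejected(self):
        labels = list("ABC")
        mat = pd.DataFrame(
            [[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]],
            index=labels, columns=labels,
        )
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(mat)


class TestSiteFilters:
    def test_gapless_alignment_unchanged(self):
        rng = np.random.default_rng(0)
        aln = random_alignment(rng, 5, 60)
        out, cols = site_coverage_filter(aln, 0.95)
        assert out.length == 60 and len(cols) == 60

    def test_boundary_inclusive(self):
        # 20 sequences, one gap in a column = coverage exactly 0.95: kept
        rows = ["A" * 10 for _ in range(20)]
        rows[0] = "-" + "A" * 9
        aln = Alignment([Transcript(id=f"s{i}", sequence=r)
                         for i, r in enumerate(rows)])
        out, cols = site_coverage_filter(aln, 0.95)
        assert out.length == 10

    def test_below_threshold_removed(self):
        rows = ["A" * 10 for _ in range(10)]
        rows[0] = "-" + "A" * 9   # coverage 0.9 in column 0
        aln = Alignment([Transcript(id=f"s{i}", sequence=r)
                         for i, r in enumerate(rows)])
        out, cols = site_coverage_filter(aln, 0.95)
        assert out.length == 9 and 0 not in cols

    def test_complete_deletion_drops_n_and_gap_columns(self):
        aln = Alignment([Transcript(id="a", sequence="ANGT"),
                         Transcript(id="b", sequence="A-GT")])
        out, cols = complete_deletion(aln)
        assert out.length == 3 and list(cols) == [0, 2, 3]


def _exhaustive_log_likelihood(aln, tree, model, scale=1.0):
    """Sum over all internal-node state assignments (oracle)."""
    from kirfam.phylo import _transition_matrices

    rates, probs = model.category_rates()
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
    seqs = {t.id: t.sequence for t in aln.members}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for site in range(aln.length):
        site_l = 0.0
        for c, rate in enumerate(rates):
            P = {
                id(n): _transition_matrices(
                    model, (n.edge.length or 0.0) * scale
                )[c]
                for n in nodes if n.parent_node is not None
            }
            acc = 0.0
            for states in itertools.product(range(4), repeat=len(internals)):
                st_of = {id(n): s for n, s in zip(internals, states)}
                for label, node in leaves.items():
                    st_of[id(node)] = code[seqs[label][site]]
                prob = model.freqs[st_of[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    prob *= P[id(n)][st_of[id(n.parent_node)], st_of[id(n)]]
                acc += prob
            site_l += probs[c] * acc
        total += math.log(site_l)
    return total


class TestLikelihood:
    def test_two_taxon_jc_closed_form(self):
        # one identical site: L = 1/4 (1/4 + 3/4 exp(-4t/3))
        aln = Alignment([Transcript(id="a", sequence="A"),
                         Transcript(id="b", sequence="A")])
        t = 0.3
        tree = dendropy.Tree.get(data=f"(a:{t/2},b:{t/2});", schema="newick")
        model = SubstitutionModel("JC69")
        ll = log_likelihood(aln, tree, model)
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_zero_branch_identical_sequences(self):
        aln = Alignment([Transcript(id="a", sequence="ACGTACGT"),
                         Transcript(id="b", sequence="ACGTACGT")])
        tree = dendropy.Tree.get(data="(a:0.0,b:0.0);", schema="newick")
        ll = log_likelihood(aln, tree, SubstitutionModel("JC69"))
        assert ll == pytest.approx(8 * math.log(0.25), abs=1e-10)

    @pytest.mark.parametrize("model_name,extra", [
        ("JC69", {}),
        ("K2P", {"rates": {"kappa": 4.0}}),
        ("TN93", {"rates": {"kappa1": 3.0, "kappa2": 6.0},
                  "freqs": np.array([0.3, 0.2, 0.3, 0.2])}),
    ])
    def test_pruning_matches_exhaustive_summation(self, model_name, extra):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 4, 8)
        tree = dendropy.Tree.get(
            data="((S0:0.1,S1:0.25):0.05,(S2:0.2,S3:0.15):0.1);",
            schema="newick",
        )
        model = SubstitutionModel(model_name, gamma_alpha=0.5, **extra)
        ours = log_likelihood(aln, tree, model)
        oracle = _exhaustive_log_likelihood(aln, tree, model)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_likelihood_invariant_under_rerooting(self):
        from kirfam.simulate import mutate_k2p

        rng = np.random.default_rng(4)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        aln = Alignment([
            Transcript(id=f"S{i}", sequence=mutate_k2p(anc, 0.1, seed=i))
            for i in range(5)
        ])
        dm = distance_matrix(aln)
        tree = nj_tree(dm)
        model = SubstitutionModel("K2P", rates={"kappa": 3.0})
        ll1 = log_likelihood(aln, tree, model)
        target = next(tree.preorder_internal_node_iter())
        for node in tree.preorder_internal_node_iter():
            if node is not tree.seed_node:
                target = node
                break
        tree.reroot_at_node(target)
        ll2 = log_likelihood(aln, tree, model)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_discrete_gamma_categories_have_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(rates) > 0).all()


class TestBootstrap:
    def _signal_alignment(self, seed=0, L=800):
        from kirfam.simulate import mutate_k2p

        rng = np.random.default_rng(seed)
        anc = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        cladeA = mutate_k2p(anc, 0.10, seed=1)
        cladeB = mutate_k2p(anc, 0.10, seed=2)
        members = []
        for i, base in enumerate([cladeA] * 3 + [cladeB] * 3):
            members.append(
                Transcript(id=f"x{i}",
                           sequence=mutate_k2p(base, 0.01, seed=10 + i))
            )
        return Alignment(members)

    def test_central_split_strongly_supported(self):
        aln = self._signal_alignment()
        tree = bootstrap_supports(aln, reps=100, seed=5)
        supports = {
            frozenset(lf.taxon.label for lf in n.leaf_iter()): n.support
            for n in tree.preorder_internal_node_iter()
            if hasattr(n, "support")
        }
        split = frozenset({"x0", "x1", "x2"})
        central = [
            s for side, s in supports.items()
            if side == split or side == frozenset({"x3", "x4", "x5"})
        ]
        assert central and max(central) >= 95

    def test_single_replicate_supports_are_binary(self):
        aln = self._signal_alignment(seed=2, L=300)
        tree = bootstrap_supports(aln, reps=1, seed=0)
        for n in tree.preorder_internal_node_iter():
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_supports_invariant_to_leaf_order(self):
        aln = self._signal_alignment(seed=3, L=400)
        shuffled = Alignment(list(reversed(aln.members)))
        t1 = bootstrap_supports(aln, reps=50, seed=9)
        t2 = bootstrap_supports(shuffled, reps=50, seed=9)

        def support_map(t):
            leaves = sorted(x.label for x in t.taxon_namespace)
            ref, full = leaves[0], frozenset(leaves)
            out = {}
            for n in t.preorder_internal_node_iter():
                if not hasattr(n, "support"):
                    continue
                side = frozenset(lf.taxon.label for lf in n.leaf_iter())
                if ref in side:
                    side = full - side
                out[side] = n.support
            return out

        assert support_map(t1) == support_map(t2)


class TestModelSelection:
    def test_zero_variation_selects_jc(self):
        aln = Alignment([Transcript(id=f"s{i}", sequence="ACGT" * 40)
                         for i in range(4)])
        tree = dendropy.Tree.get(
            data="((s0:0.01,s1:0.01):0.01,(s2:0.01,s3:0.01):0.01);",
            schema="newick",
        )
        best, table = select_model(aln, tree)
        assert best.label == "JC69"

    def test_candidate_grid_is_twenty(self):
        from kirfam.phylo import _candidate_models

        rng = np.random.default_rng(0)
        aln = random_alignment(rng, 3, 30)
        assert len(_candidate_models(aln)) == 20
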