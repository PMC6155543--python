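"""Tree-score statistics and likelihood-weighted consensus."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonearch import (
    CandidateTree,
    CandidateTreeSet,
    CloneNode,
    ClonalPhylogeny,
    PhylogenyError,
    clonal_subclonal_counts,
    consensus_summary,
    count_clones,
    leaf_depths,
    s50_weights,
    select_top_fraction,
    tree_score,
)
from clonearch.trees import chain_phylogeny, phylogeny_from_parents, star_phylogeny


# ---------------------------------------------------------------------------
# Independent brute-force oracle: explicit root-to-leaf path enumeration on a
# raw parent mapping, no shared code with the implementation.
# ---------------------------------------------------------------------------

def oracle_score(parents):
    """parents: list, parents[i] is the parent index of node i; parents[0] None."""
    n = len(parents)
    if n == 1:
        return 0.0
    children = set(p for p in parents if p is not None)
    leaves = [i for i in range(n) if i not in children]
    depths = []
    for leaf in leaves:
        d, u = 0, leaf
        while parents[u] is not None:
            u = parents[u]
            d += 1
        depths.append(d)
    return 1.0 - (sum(depths) / len(depths)) / (n - 1)


def all_parent_vectors(n):
    """Every rooted tree topology on n nodes, as increasing parent vectors."""
    if n == 1:
        yield [None]
        return
    for combo in itertools.product(*[range(i) for i in range(1, n)]):
        yield [None, *combo]


# ---------------------------------------------------------------------------
# leaf depths and tree score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "parents,expected",
    [
        ([None, 0, 1, 2], {(3, 3)}),  # chain r->a->b->c
        ([None, 0, 0, 0, 0], {(1, 1), (2, 1), (3, 1), (4, 1)}),  # star
        ([None, 0, 0, 2, 2], {(1, 1), (3, 2), (4, 2)}),  # r->a, r->b, b->c, b->d
    ],
)
def test_leaf_depths(parents, expected):
    tree = phylogeny_from_parents(parents)
    assert set(leaf_depths(tree)) == expected


def test_single_node_is_its_own_leaf():
    tree = phylogeny_from_parents([None])
    assert leaf_depths(tree) == [(0, 0)]
    assert tree_score(tree) == 0.0


@pytest.mark.parametrize("n", range(1, 51))
def test_linear_phylogenies_score_zero(n):
    assert tree_score(chain_phylogeny(n)) == 0.0


@pytest.mark.parametrize(
    "parents,expected",
    [
        ([None, 0, 0, 0, 0], 0.75),  # star N=5
        ([None, 0, 0, 2, 2], 7 / 12),  # leaves at depths 1, 2, 2
    ],
)
def test_tree_score_hand_values(parents, expected):
    assert tree_score(phylogeny_from_parents(parents)) == pytest.approx(expected)


def test_score_matches_oracle_exhaustively_and_is_bounded():
    """All rooted topologies with N <= 7: score == oracle, bounds, star max."""
    for n in range(1, 8):
        best = -1.0
        for parents in all_parent_vectors(n):
            score = tree_score(phylogeny_from_parents(parents))
            assert score == pytest.approx(oracle_score(parents), abs=1e-12)
            if n >= 2:
                assert 0.0 <= score <= 1.0 - 1.0 / (n - 1) + 1e-12
            best = max(best, score)
        if n >= 3:
            assert best == pytest.approx(1.0 - 1.0 / (n - 1))  # star attains max


def test_nonzero_score_first_attainable_at_three_clones():
    attainable = {
        n: any(
            tree_score(phylogeny_from_parents(p)) > 0 for p in all_parent_vectors(n)
        )
        for n in (1, 2, 3)
    }
    assert attainable == {1: False, 2: False, 3: True}


@settings(deadline=None, max_examples=200)
@given(st.data())
def test_random_trees_match_oracle(data):
    n = data.draw(st.integers(1, 40))
    parents = [None] + [data.draw(st.integers(0, i - 1)) for i in range(1, n)]
    tree = phylogeny_from_parents(parents)
    assert tree_score(tree) == pytest.approx(oracle_score(parents), abs=1e-12)
    clonal, subclonal = clonal_subclonal_counts(tree)
    assert clonal + subclonal == tree.total_mutations()


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_count_clones():
    assert count_clones(phylogeny_from_parents([None])) == 1
    assert count_clones(chain_phylogeny(4)) == 4
    assert count_clones(star_phylogeny(5)) == 5


@pytest.mark.parametrize(
    "builder,muts,expected",
    [
        (chain_phylogeny, [10, 5, 2], (10, 7)),
        (chain_phylogeny, [8], (8, 0)),
        (star_phylogeny, [3, 1, 1, 1], (3, 3)),
    ],
)
def test_clonal_subclonal_counts(builder, muts, expected):
    assert clonal_subclonal_counts(builder(len(muts), muts)) == expected


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def test_two_roots_rejected():
    with pytest.raises(PhylogenyError, match="one root"):
        ClonalPhylogeny([CloneNode(0, None, 1), CloneNode(1, None, 1)])


def test_cycle_rejected():
    with pytest.raises(PhylogenyError, match="not connected"):
        ClonalPhylogeny(
            [CloneNode(0, None, 1), CloneNode(1, 2, 1), CloneNode(2, 1, 1)]
        )


def test_missing_parent_rejected():
    with pytest.raises(PhylogenyError, match="missing parent"):
        ClonalPhylogeny([CloneNode(0, None, 1), CloneNode(1, 99, 1)])


def test_negative_mutations_rejected():
    with pytest.raises(PhylogenyError, match="n_mutations"):
        CloneNode(0, None, -1)


# ---------------------------------------------------------------------------
# candidate selection, weights and consensus
# ---------------------------------------------------------------------------

def _candidate_set(cdlls, sizes=None):
    sizes = sizes or [3] * len(cdlls)
    return CandidateTreeSet(
        "s1", [CandidateTree(chain_phylogeny(n), c) for c, n in zip(cdlls, sizes)]
    )


@pytest.mark.parametrize(
    "n_cands,fraction,expected",
    [(500, 0.1, 50), (3, 0.1, 1), (1, 1.0, 1)],
)
def test_select_top_fraction_count(n_cands, fraction, expected):
    cs = _candidate_set(list(range(n_cands)))
    assert len(select_top_fraction(cs, fraction).candidates) == expected


def test_select_top_fraction_orders_by_cdll_with_stable_ties():
    sizes = [2, 3, 4, 5]
    cs = _candidate_set([-5.0, -1.0, -1.0, -9.0], sizes)
    kept = select_top_fraction(cs, 0.75).candidates
    assert [len(c.phylogeny) for c in kept] == [3, 4, 2]  # ties keep input order


@pytest.mark.parametrize(
    "cdlls,expected",
    [
        ([-100, -120, -140], [1.0, 0.5, 0.0]),
        ([-7, -7, -7], [1.0, 1.0, 1.0]),
        ([0, -10], [1.0, 0.0]),
    ],
)
def test_s50_weights(cdlls, expected):
    assert s50_weights(cdlls) == pytest.approx(expected)


def test_s50_weights_rejects_bad_input():
    with pytest.raises(PhylogenyError):
        s50_weights([])
    with pytest.raises(PhylogenyError):
        s50_weights([1.0, math.inf])


def test_consensus_weighted_mean_clone_count():
    # retained cdlls {-100, -120, -140} -> weights {1, 0.5, 0};
    # clone counts {3, 4, 5} -> (1*3 + 0.5*4) / 1.5 = 10/3
    cs = _candidate_set([-100.0, -120.0, -140.0], sizes=[3, 4, 5])
    out = consensus_summary(cs, fraction=1.0)
    assert out.mean_n_clones == pytest.approx(10 / 3)
    assert out.n_candidates_used == 3


def test_consensus_single_candidate_and_identical_candidates():
    single = CandidateTreeSet("s", [CandidateTree(star_phylogeny(5), -3.0)])
    out = consensus_summary(single)
    assert (out.mean_n_clones, out.mean_tree_score) == (5.0, 0.75)

    same = CandidateTreeSet("s", [CandidateTree(star_phylogeny(4), -2.0)] * 6)
    out = consensus_summary(same, fraction=1.0)
    assert out.mean_n_clones == 4.0
    assert out.mean_tree_score == pytest.approx(tree_score(star_phylogeny(4)))


@settings(deadline=None, max_examples=100)
@given(st.data())
def test_consensus_in_convex_hull_and_order_invariant(data):
    k = data.draw(st.integers(1, 12))
    cdlls = data.draw(
        st.lists(
            st.floats(-500, 0, allow_nan=False), min_size=k, max_size=k, unique=True
        )
    )
    sizes = [data.draw(st.integers(1, 9)) for _ in range(k)]
    cs = _candidate_set(cdlls, sizes)
    out = consensus_summary(cs, fraction=1.0)
    assert min(sizes) - 1e-9 <= out.mean_n_clones <= max(sizes) + 1e-9
    assert 0.0 <= out.mean_tree_score <= 1.0

    perm = data.draw(st.permutations(list(range(k))))
    shuffled = CandidateTreeSet("s1", [cs.candidates[i] for i in perm])
    out2 = consensus_summary(shuffled, fraction=1.0)
    assert out2.mean_n_clones == pytest.approx(out.mean_n_clones)
    assert out2.mean_tree_score == pytest.approx(out.mean_tree_score)


def test_newick_export():
    assert star_phylogeny(3).to_newick() == "(1:1,2:1)0;"
    assert chain_phylogeny(3).to_newick() == "((2:1)1:1)0;"
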