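"""Rooted clonal phylogenies, the Tree score, and likelihood-weighted consensus.

A clonal phylogeny is a rooted tree whose nodes are clones: groups of tumor
cells sharing the same set of somatic mutations, typically inferred by
clustering variant allele frequencies.  The root clone carries the clonal
mutations (present in all cancer cells); every other clone carries subclonal
mutations private to its lineage.

The *Tree score* quantifies how branching a phylogeny is::

    Tree score = 1 - (1/L) * sum_l d(l, root) / (N - 1)

where ``L`` is the number of leaves, ``N`` the number of clones and
``d(l, root)`` the number of edges between leaf ``l`` and the root.  Strictly
linear phylogenies score exactly 0; the perfectly branching star on ``N``
clones attains the maximum ``1 - 1/(N - 1)``.  A nonzero score first becomes
possible at ``N = 3``.

Subclonal-reconstruction tools (e.g. PhyloWGS) emit many candidate trees per
sample, each scored by its complete-data log-likelihood (CDLL).  This module
also implements the consensus over such a candidate set: keep the top
fraction by CDLL, min-max rescale the CDLLs to weights in [0, 1], and report
weighted means of the clone count, Tree score and clonal/subclonal mutation
counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhylogenyError",
    "CloneNode",
    "ClonalPhylogeny",
    "CandidateTree",
    "CandidateTreeSet",
    "ConsensusSummary",
    "leaf_depths",
    "tree_score",
    "count_clones",
    "clonal_subclonal_counts",
    "select_top_fraction",
    "s50_weights",
    "consensus_summary",
]


class PhylogenyError(ValueError):
    """Raised for structurally invalid clonal phylogenies or candidate sets."""


@dataclass(frozen=True)
class CloneNode:
    """One clone: an integer id, its parent (None for the root), the number
    of somatic mutations assigned to it, and an optional cell fraction.

    ``cell_fraction`` may follow either the per-clone or the per-subtree
    (cancer cell fraction) convention; which one applies is recorded by the
    producer, not enforced here.
    """

    clone_id: int
    parent_id: Optional[int]
    n_mutations: int
    cell_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise PhylogenyError(
                f"clone {self.clone_id}: n_mutations must be >= 0, "
                f"got {self.n_mutations}"
            )
        if self.cell_fraction is not None and not (0.0 <= self.cell_fraction <= 1.0):
            raise PhylogenyError(
                f"clone {self.clone_id}: cell_fraction must be in [0, 1], "
                f"got {self.cell_fraction}"
            )


class ClonalPhylogeny:
    """A validated rooted tree of :class:`CloneNode`.

    Construction checks that there is exactly one parentless node, that every
    ``parent_id`` references an existing clone, and that the graph is a
    connected, acyclic rooted tree.
    """

    def __init__(self, nodes: Iterable[CloneNode]):
        nodes = list(nodes)
        if not nodes:
            raise PhylogenyError("a phylogeny needs at least one clone")
        self._nodes: dict[int, CloneNode] = {}
        for n in nodes:
            if n.clone_id in self._nodes:
                raise PhylogenyError(f"duplicate clone_id {n.clone_id}")
            self._nodes[n.clone_id] = n

        roots = [n.clone_id for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise PhylogenyError(
                f"expected exactly one root (parentless clone), found {len(roots)}"
            )
        self.root_id: int = roots[0]

        self._children: dict[int, list[int]] = {n.clone_id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self._nodes:
                    raise PhylogenyError(
                        f"clone {n.clone_id} references missing parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.clone_id)

        # connectivity from the root rules out cycles among non-root clones
        seen = set()
        stack = [self.root_id]
        while stack:
            u = stack.pop()
            seen.add(u)
            stack.extend(self._children[u])
        if len(seen) != len(self._nodes):
            raise PhylogenyError(
                "tree is not connected: "
                f"{len(self._nodes) - len(seen)} clone(s) unreachable from the root"
            )
        if self._nodes[self.root_id].n_mutations == 0 and len(self._nodes) > 1:
            logger.debug(
                "phylogeny has a zero-mutation root (possible non-cancerous root)"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> dict[int, CloneNode]:
        return self._nodes

    def node(self, clone_id: int) -> CloneNode:
        return self._nodes[clone_id]

    def children(self, clone_id: int) -> list[int]:
        return self._children[clone_id]

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClonalPhylogeny):
            return NotImplemented
        return self._nodes == other._nodes

    def leaves(self) -> list[int]:
        return [u for u, ch in self._children.items() if not ch]

    def total_mutations(self) -> int:
        return sum(n.n_mutations for n in self._nodes.values())

    def to_newick(self) -> str:
        """Newick string with clone_id labels and unit branch lengths."""

        def rec(u: int) -> str:
            ch = self._children[u]
            label = str(u)
            if not ch:
                return f"{label}:1"
            return "(" + ",".join(rec(c) for c in ch) + f"){label}:1"

        ch = self._children[self.root_id]
        if not ch:
            return f"{self.root_id};"
        return "(" + ",".join(rec(c) for c in ch) + f"){self.root_id};"


@dataclass(frozen=True)
class CandidateTree:
    """One candidate phylogeny with its complete-data log-likelihood."""

    phylogeny: ClonalPhylogeny
    cdll: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cdll):
            raise PhylogenyError(f"cdll must be finite, got {self.cdll}")


@dataclass
class CandidateTreeSet:
    """The ordered candidate phylogenies harvested for one sample."""

    sample_id: str
    candidates: list[CandidateTree] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise PhylogenyError(f"sample {self.sample_id}: empty candidate set")


@dataclass(frozen=True)
class ConsensusSummary:
    """Likelihood-weighted consensus over a sample's top candidate trees."""

    sample_id: str
    mean_n_clones: float
    mean_tree_score: float
    mean_clonal: float
    mean_subclonal: float
    n_candidates_used: int


# ---------------------------------------------------------------------------
# Tree statistics
# ---------------------------------------------------------------------------

def leaf_depths(tree: ClonalPhylogeny) -> list[tuple[int, int]]:
    """Return ``(leaf_id, depth)`` for every leaf, depth counted in edges.

    A single-clone tree returns its root as a leaf at depth 0.
    """
    out = []
    stack = [(tree.root_id, 0)]
    while stack:
        u, d = stack.pop()
        ch = tree.children(u)
        if not ch:
            out.append((u, d))
        else:
            stack.extend((c, d + 1) for c in ch)
    return out


def tree_score(tree: ClonalPhylogeny) -> float:
    """Branching statistic in [0, 1]; 0 for every linear phylogeny.

    For a single clone (N = 1) the formula is degenerate and the score is 0
    by convention: no branching is expressible.
    """
    n = len(tree)
    if n == 1:
        return 0.0
    depths = leaf_depths(tree)
    mean_depth = sum(d for _, d in depths) / len(depths)
    return 1.0 - mean_depth / (n - 1)


def count_clones(tree: ClonalPhylogeny) -> int:
    return len(tree)


def clonal_subclonal_counts(tree: ClonalPhylogeny) -> tuple[int, int]:
    """(clonal, subclonal) mutation counts.

    Clonal mutations are those grouped in the root clone; every mutation in a
    non-root clone is subclonal.
    """
    clonal = tree.node(tree.root_id).n_mutations
    subclonal = tree.total_mutations() - clonal
    return clonal, subclonal


# ---------------------------------------------------------------------------
# Candidate-set consensus
# ---------------------------------------------------------------------------

def select_top_fraction(
    candidates: CandidateTreeSet, fraction: float = 0.1
) -> CandidateTreeSet:
    """Keep the top ``ceil(fraction * n)`` candidates by CDLL (at least one).

    Sorting is stable: candidates with equal CDLL keep their input order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = max(1, math.ceil(fraction * len(candidates.candidates)))
    ranked = sorted(
        candidates.candidates, key=lambda c: -c.cdll
    )  # stable: ties keep input order
    return CandidateTreeSet(candidates.sample_id, ranked[:n_keep])


def s50_weights(cdlls: Sequence[float]) -> np.ndarray:
    """Min-max rescale log-likelihoods to weights in [0, 1].

    ``w_i = (cdll_i - min) / (max - min)``.  When all CDLLs are equal the
    formula is 0/0; all weights are then set to 1 (uniform), which preserves
    the plain mean.
    """
    arr = np.asarray(cdlls, dtype=float)
    if arr.size == 0:
        raise PhylogenyError("empty CDLL collection")
    if not np.all(np.isfinite(arr)):
        raise PhylogenyError("non-finite CDLL value")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.ones_like(arr)
    return (arr - lo) / (hi - lo)


def consensus_summary(
    candidates: CandidateTreeSet, fraction: float = 0.1
) -> ConsensusSummary:
    """Weighted consensus of clone count, Tree score and mutation burdens.

    Applies :func:`select_top_fraction`, rescales CDLLs with
    :func:`s50_weights`, and returns the weight-averaged statistics.  Under
    the degenerate-range convention the weights can never all be zero.
    """
    top = select_top_fraction(candidates, fraction)
    w = s50_weights([c.cdll for c in top.candidates])
    clones = np.array([count_clones(c.phylogeny) for c in top.candidates], float)
    scores = np.array([tree_score(c.phylogeny) for c in top.candidates], float)
    cs = [clonal_subclonal_counts(c.phylogeny) for c in top.candidates]
    clonal = np.array([c for c, _ in cs], float)
    subclonal = np.array([s for _, s in cs], float)
    wsum = w.sum()
    return ConsensusSummary(
        sample_id=candidates.sample_id,
        mean_n_clones=float((w * clones).sum() / wsum),
        mean_tree_score=float((w * scores).sum() / wsum),
        mean_clonal=float((w * clonal).sum() / wsum),
        mean_subclonal=float((w * subclonal).sum() / wsum),
        n_candidates_used=len(top.candidates),
    )


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def chain_phylogeny(n: int, mutations: Sequence[int] | None = None) -> ClonalPhylogeny:
    """A strictly linear phylogeny on ``n`` clones (ids 0..n-1, root 0)."""
    if mutations is None:
        mutations = [1] * n
    return ClonalPhylogeny(
        CloneNode(i, None if i == 0 else i - 1, int(mutations[i])) for i in range(n)
    )


def star_phylogeny(n: int, mutations: Sequence[int] | None = None) -> ClonalPhylogeny:
    """A root with ``n - 1`` leaf children (ids 0..n-1, root 0)."""
    if mutations is None:
        mutations = [1] * n
    return ClonalPhylogeny(
        CloneNode(i, None if i == 0 else 0, int(mutations[i])) for i in range(n)
    )


def phylogeny_from_parents(
    parents: Sequence[Optional[int]], mutations: Sequence[int] | None = None
) -> ClonalPhylogeny:
    """Build a phylogeny from a parent vector (``parents[i]`` is the parent of
    clone ``i``; exactly one entry must be None)."""
    n = len(parents)
    if mutations is None:
        mutations = [1] * n
    return ClonalPhylogeny(
        CloneNode(i, parents[i], int(mutations[i])) for i in range(n)
    )
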