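"""Discrete-time Galton-Watson model of tumor growth with drivers/passengers.

Each generation, every cell either dies or replicates.  A cell that has
accumulated ``k`` driver mutations dies with probability::

    d(k, s) = (1/2) * (1 - s)^k

and replicates with the complementary probability, so ``s`` (the fitness
parameter) makes drivers advantageous and ``k = 0`` gives a critical process
(expected offspring exactly 1).  On replication, one of the two daughter
cells acquires a new somatic alteration with probability ``mu``; the mutated
daughter founds a new clone whether the alteration is a driver or a
passenger.  The probability that a new alteration is a driver is controlled
by ``driver_mode``:

* ``conditional_K`` (default): P(driver | mutation) = K, motivated by K being
  the fraction of driver genes in the genome (K = 0.025, ~500 driver genes);
* ``conditional_K_mu``: P(driver | mutation) = K * mu, the literal product
  form.  Under this reading drivers are ~mu*K-rare among mutations and
  expansions essentially never happen at exome-scale mutation rates.

The simulation is clone-structured: cells within a clone are exchangeable,
so per-generation dynamics reduce to binomial draws per clone, which keeps
populations of 1e5 cells cheap.  Clones that drop to at most 1% of the final
population (or that went extinct) are removed when the clonal phylogeny is
extracted; mutations of removed intermediate ancestors are collapsed into
their nearest retained descendant, which mirrors what bulk sequencing of the
final tumor would assign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import ClonalPhylogeny, CloneNode, clonal_subclonal_counts, tree_score

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SimClone",
    "SimResult",
    "SimulationExtinct",
    "death_probability",
    "simulate_tumor",
    "extract_phylogeny",
    "parameter_sweep",
]

DRIVER_MODES = ("conditional_K", "conditional_K_mu")


class SimulationExtinct(RuntimeError):
    """Every survival-conditioned attempt went extinct."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the branching-process tumor model.

    ``mu``: per-replication mutation probability.
    ``s``: fitness advantage per driver, in [0, 1).
    ``K``: driver-fraction constant (default 0.025).
    ``n_max`` / ``g_max``: stop once the population reaches ``n_max`` cells or
    ``g_max`` generations have run, whichever comes first.
    ``prevalence_threshold``: clone retention floor used at extraction.
    ``condition_on_survival``: restart extinct runs (fresh seed stream) up to
    ``max_attempts`` times.
    """

    mu: float
    s: float
    K: float = 0.025
    driver_mode: str = "conditional_K"
    n_initial: int = 1
    n_max: int = 100_000
    g_max: int = 2_000
    prevalence_threshold: float = 0.01
    seed: Optional[int] = None
    condition_on_survival: bool = True
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not (0.0 <= self.s < 1.0):
            raise ValueError(f"s must be in [0, 1), got {self.s}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.driver_mode not in DRIVER_MODES:
            raise ValueError(f"driver_mode must be one of {DRIVER_MODES}")
        if not (0.0 < self.prevalence_threshold < 1.0):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        if self.n_initial < 1 or self.n_max < 1 or self.g_max < 0:
            raise ValueError("n_initial, n_max must be >= 1 and g_max >= 0")


@dataclass(frozen=True)
class SimClone:
    """Bookkeeping for one clone (kept even after extinction)."""

    clone_id: int
    parent_id: Optional[int]
    k_drivers: int
    n_private_mutations: int
    cell_count: int


@dataclass
class SimResult:
    """Outcome of one simulated tumor."""

    clones: list[SimClone]
    generations_run: int
    final_population: int
    extinct: bool
    attempts: int
    n_replications: int  # total replication events over the run
    params: SimParams = field(repr=False, default=None)  # type: ignore[assignment]


def death_probability(k: int, s: float) -> float:
    """d(k, s) = (1/2)(1 - s)^k; replication probability is the complement."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if not (0.0 <= s < 1.0):
        raise ValueError(f"s must be in [0, 1), got {s}")
    return 0.5 * (1.0 - s) ** k


def _p_driver(params: SimParams) -> float:
    if params.driver_mode == "conditional_K":
        return min(params.K, 1.0)
    return min(params.K * params.mu, 1.0)


def _run_once(params: SimParams, rng: np.random.Generator) -> SimResult:
    # per-clone state, index == clone_id
    parent: list[Optional[int]] = [None]
    kdrv: list[int] = [0]
    private: list[int] = [0]
    cells: list[int] = [params.n_initial]
    alive: list[int] = [0]

    p_driver = _p_driver(params)
    population = params.n_initial
    n_repl = 0
    gen = 0

    while gen < params.g_max and 0 < population < params.n_max:
        gen += 1
        idx = np.array(alive, dtype=np.int64)
        n = np.array([cells[i] for i in alive], dtype=np.int64)
        k = np.array([kdrv[i] for i in alive], dtype=np.int64)
        d = 0.5 * (1.0 - params.s) ** k
        deaths = rng.binomial(n, d)
        reps = n - deaths
        n_repl += int(reps.sum())
        mutants = rng.binomial(reps, params.mu) if params.mu > 0 else np.zeros_like(reps)
        n_drivers = rng.binomial(mutants, p_driver) if p_driver > 0 else np.zeros_like(mutants)

        # parent clone keeps both daughters of non-mutating replications plus
        # the unmutated sibling of each mutating one
        new_counts = 2 * reps - mutants
        next_alive: list[int] = []
        for j, i in enumerate(idx):
            cells[i] = int(new_counts[j])
            if cells[i] > 0:
                next_alive.append(int(i))
            if mutants[j]:
                nd = int(n_drivers[j])
                for m in range(int(mutants[j])):
                    cid = len(parent)
                    parent.append(int(i))
                    kdrv.append(kdrv[i] + (1 if m < nd else 0))
                    private.append(1)
                    cells.append(1)
                    next_alive.append(cid)
        alive = next_alive
        population = int(new_counts.sum() + mutants.sum())

    clones = [
        SimClone(i, parent[i], kdrv[i], private[i], cells[i])
        for i in range(len(parent))
    ]
    return SimResult(
        clones=clones,
        generations_run=gen,
        final_population=population,
        extinct=population == 0,
        attempts=1,
        n_replications=n_repl,
        params=params,
    )


def simulate_tumor(params: SimParams) -> SimResult:
    """Run the branching process; reproducible given ``params.seed``.

    With ``condition_on_survival`` each extinct run is discarded and retried
    on a fresh, deterministically derived seed stream; ``attempts`` in the
    result records how many runs were needed.  If all ``max_attempts`` runs
    go extinct a :class:`SimulationExtinct` error is raised.
    """
    ss = np.random.SeedSequence(params.seed)
    if not params.condition_on_survival:
        res = _run_once(params, np.random.default_rng(ss))
        return res
    for attempt, child in enumerate(ss.spawn(params.max_attempts), start=1):
        res = _run_once(params, np.random.default_rng(child))
        if not res.extinct:
            res.attempts = attempt
            return res
    raise SimulationExtinct(
        f"all {params.max_attempts} attempts went extinct "
        f"(mu={params.mu:g}, s={params.s:g})"
    )


# ---------------------------------------------------------------------------
# Phylogeny extraction
# ---------------------------------------------------------------------------

def extract_phylogeny(result: SimResult, threshold: float = 0.01) -> ClonalPhylogeny:
    """Clonal phylogeny of clones holding >= ``threshold`` of the final cells.

    Sub-threshold and extinct clones are dropped; each retained non-root
    clone is re-attached to its nearest retained ancestor.  Private mutations
    of a dropped clone are collapsed into its nearest retained descendant
    (ties go to the larger clone, then the smaller id); mutations of dropped
    clones without retained descendants are discarded, as bulk sequencing of
    the final tumor would not see them.  If the retained clones have no
    single retained common ancestor, their most recent common ancestor is
    added back as the root — its mutations are exactly the clonal ones.
    """
    total = result.final_population
    if total <= 0:
        raise SimulationExtinct("cannot extract a phylogeny from an extinct tumor")
    clones = result.clones
    parent = {c.clone_id: c.parent_id for c in clones}
    cellsof = {c.clone_id: c.cell_count for c in clones}

    cut = threshold * total
    retained = {c.clone_id for c in clones if c.cell_count >= cut}
    if not retained:  # >100 clones all under 1%: keep the largest
        retained = {max(clones, key=lambda c: (c.cell_count, -c.clone_id)).clone_id}

    def root_path(u: int) -> list[int]:
        path = [u]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])  # type: ignore[arg-type]
        path.reverse()
        return path  # root ... u

    # MRCA of the retained set = longest common prefix of root-down paths
    paths = [root_path(u) for u in retained]
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        step = {p[depth] for p in paths}
        if len(step) == 1:
            mrca = step.pop()
        else:
            break
    retained.add(mrca)

    # claim dropped clones for their nearest retained descendant
    claims: dict[int, tuple[int, int, int, int]] = {}  # dropped -> (dist, -cells, rid)
    extra: dict[int, int] = {u: 0 for u in retained}
    for r in retained:
        dist = 0
        u = parent[r]
        while u is not None and u not in retained:
            dist += 1
            key = (dist, -cellsof[r], r)
            if u not in claims or key < claims[u]:
                claims[u] = key
            u = parent[u]
    # ancestors strictly above the MRCA are ancestral to every surviving
    # cell: collapse them into the root of the extracted tree
    u = parent[mrca]
    while u is not None:
        claims[u] = (0, 0, mrca)
        u = parent[u]

    privateof = {c.clone_id: c.n_private_mutations for c in clones}
    for dropped, (_, _, rid) in claims.items():
        extra[rid] += privateof[dropped]

    def retained_parent(r: int) -> Optional[int]:
        u = parent[r]
        while u is not None and u not in retained:
            u = parent[u]
        return u

    nodes = [
        CloneNode(
            clone_id=r,
            parent_id=retained_parent(r),
            n_mutations=privateof[r] + extra[r],
            cell_fraction=min(1.0, cellsof[r] / total),
        )
        for r in sorted(retained)
    ]
    return ClonalPhylogeny(nodes)


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

def parameter_sweep(
    mu_grid: Sequence[float],
    s_grid: Sequence[float],
    replicates: int,
    base_params: SimParams,
) -> pd.DataFrame:
    """Simulate ``replicates`` tumors per (mu, s) grid cell.

    Child seeds are derived deterministically from ``(base seed, mu index,
    s index, replicate)``.  Replicates whose survival-conditioned attempts
    all went extinct are kept as rows with ``extinct=True`` and missing
    phylogeny statistics, so survivorship is auditable.
    """
    rows = []
    base_seed = base_params.seed if base_params.seed is not None else 0
    for i, mu in enumerate(mu_grid):
        for j, s in enumerate(s_grid):
            for r in range(replicates):
                child = int(
                    np.random.SeedSequence([base_seed, i, j, r]).generate_state(1)[0]
                    % (2**31)
                )
                params = replace(base_params, mu=float(mu), s=float(s), seed=child)
                row = {"mu": float(mu), "s": float(s), "replicate": r}
                try:
                    res = simulate_tumor(params)
                    phylo = extract_phylogeny(res, params.prevalence_threshold)
                    clonal, subclonal = clonal_subclonal_counts(phylo)
                    row.update(
                        n_clones=len(phylo),
                        tree_score=tree_score(phylo),
                        clonal=clonal,
                        subclonal=subclonal,
                        generations=res.generations_run,
                        attempts=res.attempts,
                        final_population=res.final_population,
                        extinct=False,
                    )
                except SimulationExtinct:
                    row.update(
                        n_clones=np.nan,
                        tree_score=np.nan,
                        clonal=np.nan,
                        subclonal=np.nan,
                        generations=np.nan,
                        attempts=params.max_attempts,
                        final_population=0,
                        extinct=True,
                    )
                rows.append(row)
    return pd.DataFrame(rows)
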