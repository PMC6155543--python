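"""Branching-process simulator: death model, clone bookkeeping, extraction."""

import numpy as np
import pytest

from clonearch import (
    SimClone,
    SimParams,
    SimResult,
    SimulationExtinct,
    clonal_subclonal_counts,
    death_probability,
    extract_phylogeny,
    parameter_sweep,
    simulate_tumor,
    tree_score,
)


# ---------------------------------------------------------------------------
# death probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "k,s,expected",
    [(0, 0.3, 0.5), (0, 0.0, 0.5), (5, 0.0, 0.5), (2, 0.1, 0.405)],
)
def test_death_probability_values(k, s, expected):
    assert death_probability(k, s) == pytest.approx(expected)


def test_death_probability_strictly_decreasing_in_k_and_s():
    for k in range(5):
        assert death_probability(k + 1, 0.2) < death_probability(k, 0.2)
    for s in (0.1, 0.2, 0.4):
        assert death_probability(3, s + 0.05) < death_probability(3, s)


def test_death_probability_rejects_bad_args():
    with pytest.raises(ValueError):
        death_probability(-1, 0.1)
    with pytest.raises(ValueError):
        death_probability(2, 1.0)


# ---------------------------------------------------------------------------
# simulate_tumor
# ---------------------------------------------------------------------------

def test_no_mutation_means_single_clone_forever():
    params = SimParams(mu=0.0, s=0.0, n_initial=50, n_max=10**6, g_max=40,
                       seed=3, condition_on_survival=False)
    res = simulate_tumor(params)
    assert len(res.clones) == 1
    assert res.clones[0].n_private_mutations == 0
    assert res.final_population == sum(c.cell_count for c in res.clones)


def test_certain_mutation_creates_one_clone_per_replication():
    # mu=1 with K=0: every replication spawns a passenger clone
    params = SimParams(mu=1.0, s=0.0, K=0.0, n_initial=4, n_max=10**6, g_max=3,
                       seed=11, condition_on_survival=False)
    res = simulate_tumor(params)
    assert len(res.clones) == 1 + res.n_replications
    assert all(c.n_private_mutations == 1 for c in res.clones[1:])


def test_population_bookkeeping_conserved_and_k_monotone():
    params = SimParams(mu=0.01, s=0.2, n_initial=20, n_max=5000, g_max=100,
                       seed=5, condition_on_survival=False)
    res = simulate_tumor(params)
    assert res.final_population == sum(c.cell_count for c in res.clones)
    by_id = {c.clone_id: c for c in res.clones}
    for c in res.clones:
        if c.parent_id is not None:
            assert c.k_drivers >= by_id[c.parent_id].k_drivers


def test_critical_process_mean_population_is_conserved():
    # k=0 everywhere: expected offspring per cell is exactly 1
    finals = []
    for r in range(400):
        params = SimParams(mu=0.0, s=0.0, n_initial=100, n_max=10**9, g_max=30,
                           seed=r, condition_on_survival=False)
        finals.append(simulate_tumor(params).final_population)
    finals = np.asarray(finals, float)
    se = finals.std(ddof=1) / np.sqrt(len(finals))
    assert abs(finals.mean() - 100.0) <= 3 * se


def test_identical_seeds_give_identical_results():
    params = SimParams(mu=0.05, s=0.1, n_initial=5, n_max=2000, g_max=60, seed=42)
    a, b = simulate_tumor(params), simulate_tumor(params)
    assert a.clones == b.clones
    assert (a.final_population, a.generations_run) == (
        b.final_population, b.generations_run)


def test_survival_conditioning_restarts_and_reports_attempts():
    params = SimParams(mu=0.0, s=0.0, n_initial=1, n_max=10**6, g_max=200,
                       seed=2, condition_on_survival=True, max_attempts=200)
    res = simulate_tumor(params)
    assert not res.extinct
    assert 1 <= res.attempts <= 200


def test_all_attempts_extinct_raises():
    # a single cell at critical growth for many generations dies out fast
    params = SimParams(mu=0.0, s=0.0, n_initial=1, n_max=10**6, g_max=5000,
                       seed=0, condition_on_survival=True, max_attempts=2)
    with pytest.raises(SimulationExtinct):
        simulate_tumor(params)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimParams(mu=1.5, s=0.1)
    with pytest.raises(ValueError):
        SimParams(mu=0.1, s=1.0)
    with pytest.raises(ValueError):
        SimParams(mu=0.1, s=0.1, driver_mode="bogus")


# ---------------------------------------------------------------------------
# extract_phylogeny
# ---------------------------------------------------------------------------

def _result(clones, extinct=False):
    pop = sum(c.cell_count for c in clones)
    return SimResult(clones=list(clones), generations_run=10,
                     final_population=pop, extinct=extinct, attempts=1,
                     n_replications=0)


def test_subthreshold_terminal_clone_is_dropped():
    res = _result([
        SimClone(0, None, 0, 4, 990),
        SimClone(1, 0, 0, 2, 5),     # 0.46% of 1095 -> dropped
        SimClone(2, 0, 0, 3, 100),
    ])
    phylo = extract_phylogeny(res, threshold=0.01)
    assert set(phylo.nodes) == {0, 2}
    assert phylo.node(2).parent_id == 0
    assert phylo.node(0).n_mutations == 4  # dropped terminal's mutations gone


def test_dropped_intermediate_collapses_into_descendant():
    res = _result([
        SimClone(0, None, 0, 7, 2000),
        SimClone(1, 0, 0, 2, 5),     # dropped intermediate
        SimClone(2, 1, 1, 3, 300),
    ])
    phylo = extract_phylogeny(res, threshold=0.01)
    assert set(phylo.nodes) == {0, 2}
    assert phylo.node(2).parent_id == 0
    assert phylo.node(2).n_mutations == 3 + 2  # inherits the dropped clone's


def test_single_surviving_clone_gives_trivial_tree():
    res = _result([SimClone(0, None, 0, 6, 1000), SimClone(1, 0, 0, 1, 0)])
    phylo = extract_phylogeny(res)
    assert len(phylo) == 1 and tree_score(phylo) == 0.0


def test_dead_root_is_restored_as_mrca_and_mutations_conserved():
    # the founder died out; two surviving children force the MRCA back in
    res = _result([
        SimClone(0, None, 0, 5, 0),
        SimClone(1, 0, 0, 2, 600),
        SimClone(2, 0, 1, 3, 400),
    ])
    phylo = extract_phylogeny(res, threshold=0.01)
    assert set(phylo.nodes) == {0, 1, 2}
    assert phylo.node(0).parent_id is None
    clonal, subclonal = clonal_subclonal_counts(phylo)
    assert (clonal, subclonal) == (5, 5)


def test_extract_from_extinct_tumor_raises():
    res = _result([SimClone(0, None, 0, 0, 0)], extinct=True)
    with pytest.raises(SimulationExtinct):
        extract_phylogeny(res)


def test_extracted_phylogeny_mutations_never_exceed_simulated():
    params = SimParams(mu=0.02, s=0.3, n_initial=10, n_max=20000, g_max=200,
                       seed=9, condition_on_survival=True)
    res = simulate_tumor(params)
    assert res.final_population > 0
    phylo = extract_phylogeny(res)
    total_private = sum(c.n_private_mutations for c in res.clones)
    assert phylo.total_mutations() <= total_private
    fracs = [n.cell_fraction for n in phylo.nodes.values()]
    assert all(0.0 <= f <= 1.0 for f in fracs)


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------

def test_sweep_shape_and_zero_mu_column():
    base = SimParams(mu=0.0, s=0.0, n_initial=30, n_max=10**6, g_max=20,
                     seed=1, condition_on_survival=False)
    tab = parameter_sweep([0.0], [0.0, 0.2], 5, base)
    assert len(tab) == 10
    done = tab[~tab.extinct]
    assert (done.n_clones == 1).all()
    assert (done.tree_score == 0.0).all()


def test_sweep_is_deterministic_per_seed():
    base = SimParams(mu=0.01, s=0.1, n_initial=5, n_max=2000, g_max=50,
                     seed=77, condition_on_survival=False)
    a = parameter_sweep([1e-3, 1e-2], [0.1], 3, base)
    b = parameter_sweep([1e-3, 1e-2], [0.1], 3, base)
    assert a.equals(b)
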