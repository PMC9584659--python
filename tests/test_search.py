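import numpy as np
import pytest
from scipy.stats import cauchy, kstest

from hfia import (
    Antibody,
    HFIAConfig,
    Population,
    cauchy_cdf,
    clone,
    init_population,
    lethal_mutation,
    optimize,
    population_update,
    run_hfia,
    sample_standard_cauchy,
    schedule,
    select_elites,
)


def make_config(**kw):
    kw.setdefault("seed", 0)
    return HFIAConfig(**kw)


# ---------------------------------------------------------------------------
# Cauchy machinery

@pytest.mark.parametrize("x,x0,gamma,expected", [
    (0.0, 0.0, 1.0, 0.5),
    (-0.2, -0.2, 2.0, 0.5),
    (1.0, 0.0, 1.0, 0.75),
    (-0.2, 0.0, 1.0, 0.437167),
])
def test_cauchy_cdf_values(x, x0, gamma, expected):
    assert cauchy_cdf(x, x0, gamma) == pytest.approx(expected, abs=5e-7)


def test_cauchy_cdf_matches_scipy():
    xs = np.linspace(-5, 5, 41)
    np.testing.assert_allclose(cauchy_cdf(xs, 1.0, 2.0),
                               cauchy.cdf(xs, loc=1.0, scale=2.0))


def test_cauchy_draws_empirical_quantiles():
    draws = sample_standard_cauchy(100_000, np.random.default_rng(1))
    assert np.mean(draws <= 0) == pytest.approx(0.5, abs=0.01)
    assert np.mean(draws <= 1) == pytest.approx(0.75, abs=0.01)


def test_cauchy_draws_ks_distance():
    draws = sample_standard_cauchy(100_000, np.random.default_rng(2))
    stat = kstest(draws, cauchy.cdf).statistic
    assert stat < 0.01


# ---------------------------------------------------------------------------
# Schedule

@pytest.mark.parametrize("t,Tmax,delta,theta", [
    (0, 50, 0.5, 0.0),
    (50, 50, -0.5, 1.0),
    (25, 50, 0.0, 0.5),
])
def test_schedule_linear_factors(t, Tmax, delta, theta):
    state = schedule(t, Tmax)
    assert state.delta == delta and state.theta == theta


def test_schedule_rejects_out_of_range():
    with pytest.raises(ValueError):
        schedule(51, 50)
    with pytest.raises(ValueError):
        schedule(0, 0)


# ---------------------------------------------------------------------------
# Initialization

def test_init_population_shape_and_repair():
    cfg = make_config(N=10)
    pop = init_population(30, cfg, np.random.default_rng(0))
    assert len(pop.members) == 10
    assert all(ab.code.shape == (30,) and ab.n_active >= 1
               for ab in pop.members)


def test_init_activation_density_matches_cauchy_tail():
    """Gene activation probability is 1 - F(eta) under the threshold rule."""
    cfg = make_config(N=10, eta=-0.2)
    pop = init_population(10_000, cfg, np.random.default_rng(3))
    density = np.mean([ab.code.mean() for ab in pop.members])
    assert density == pytest.approx(1 - cauchy_cdf(-0.2), abs=0.01)


def test_init_extreme_threshold_repairs_to_single_gene():
    cfg = make_config(N=5, eta=1e6)
    pop = init_population(50, cfg, np.random.default_rng(4))
    assert all(ab.n_active == 1 for ab in pop.members)


# ---------------------------------------------------------------------------
# Selection and cloning

def pop_of(fitness_and_codes):
    members = []
    for fit, code in fitness_and_codes:
        members.append(Antibody(code=np.array(code, bool), fitness=fit))
    return Population(members=members)


def test_select_elites_size_and_order():
    cfg = make_config(N=10, c_r=0.5)
    rng = np.random.default_rng(5)
    members = [(float(rng.random()), rng.random(6) < 0.5) for _ in range(10)]
    pop = pop_of(members)
    elite = select_elites(pop, cfg)
    assert len(elite) == 5
    fits = [ab.fitness for ab in elite]
    assert fits == sorted(fits)
    # brute-force oracle: full sort of all members
    expected = sorted(pop.members, key=lambda ab: (ab.fitness, ab.n_active))
    assert [ab.fitness for ab in expected[:5]] == fits


def test_select_elites_ties_prefer_fewer_genes():
    pop = pop_of([(0.5, [1, 1, 1]), (0.5, [1, 0, 0]), (0.5, [1, 1, 0])])
    cfg = make_config(N=3, c_r=0.34)  # pool size 1
    elite = select_elites(pop, cfg)
    assert elite[0].n_active == 1


def test_clone_counts_rank_proportional():
    cfg = make_config(N=10, beta=1.0)
    elite = [Antibody(code=np.ones(4, bool), fitness=0.1 * i)
             for i in range(5)]
    clones = clone(elite, cfg)
    counts = [sum(ab.fitness == e.fitness for ab in clones) for e in elite]
    assert counts == [10, 5, 3, 3, 2]
    assert len(clones) == 23


def test_clone_single_elite_gets_n_copies():
    cfg = make_config(N=10)
    clones = clone([Antibody(code=np.ones(3, bool), fitness=0.2)], cfg)
    assert len(clones) == 10


def test_clones_are_independent_copies():
    cfg = make_config(N=4)
    parent = Antibody(code=np.ones(5, bool), fitness=0.1)
    clones = clone([parent], cfg)
    clones[0].code[:] = False
    assert clones[1].code.all() and parent.code.all()


# ---------------------------------------------------------------------------
# Mutation

def test_lethal_mode_only_deactivates():
    rng = np.random.default_rng(6)
    state = schedule(10, 50, best_improved=True)
    clones = [Antibody(code=np.ones(40, bool), fitness=0.3) for _ in range(20)]
    before = [ab.n_active for ab in clones]
    mutated = lethal_mutation(clones, state, rng)
    for prev, ab in zip(before, mutated):
        assert 1 <= ab.n_active <= prev
        assert ab.fitness is None  # cache invalidated


def test_exploration_mode_flips_every_locus_at_low_threshold():
    state = schedule(50, 50, best_improved=False)

    class AlwaysMutate:
        def standard_cauchy(self, size):
            return np.full(size, 1e9)  # every draw above any delta

        def integers(self, n):
            return 0

    code = np.array([1, 0, 1, 0, 1], bool)
    mutated = lethal_mutation([Antibody(code=code.copy())], state,
                              AlwaysMutate())
    np.testing.assert_array_equal(mutated[0].code, ~code)


def test_mutation_locus_fraction_matches_cauchy_tail():
    """At delta=0.5 a locus mutates with probability 1 - F(0.5)."""
    rng = np.random.default_rng(7)
    state = schedule(0, 50, best_improved=False)  # delta = 0.5, flips
    clones = [Antibody(code=np.zeros(100_000, bool)) for _ in range(1)]
    clones[0].code[0] = True  # avoid the all-zero repair dominating
    mutated = lethal_mutation(clones, state, rng)
    flipped = np.mean(mutated[0].code)
    assert flipped == pytest.approx(1 - cauchy_cdf(0.5), abs=0.01)


def test_mutation_repairs_empty_antibody():
    state = schedule(50, 50, best_improved=True)  # delta=-0.5, heavy deletion

    class DeleteAll:
        def standard_cauchy(self, size):
            return np.full(size, 1e9)

        def integers(self, n):
            return 2

    mutated = lethal_mutation([Antibody(code=np.ones(5, bool))], state,
                              DeleteAll())
    assert mutated[0].n_active == 1 and mutated[0].code[2]


# ---------------------------------------------------------------------------
# Population update and the full loop

def surrogate_eval(mask):
    """Deterministic fitness: prefers few genes with even indices active."""
    idx = np.flatnonzero(mask)
    err = 0.5 * np.mean(idx % 2) if idx.size else 1.0
    return 0.99 * err + 0.01 * idx.size / mask.shape[0]


def test_population_update_keeps_size_and_elitism():
    cfg = make_config(N=8)
    rng = np.random.default_rng(8)
    pop = init_population(20, cfg, rng)
    for ab in pop.members:
        ab.fitness = surrogate_eval(ab.code)
    prev_best = pop.best.fitness
    state = schedule(5, 50)
    mutated = lethal_mutation(clone(select_elites(pop, cfg), cfg), state, rng)
    new = population_update(pop, mutated, state, cfg, surrogate_eval, rng)
    assert len(new.members) == 8
    assert new.best.fitness <= prev_best
    assert new.generation == pop.generation + 1


def test_fresh_antibody_density_shrinks_with_theta():
    """At theta=1, eta=-0.2 newcomers activate at rate 1 - F(0.8)."""
    cfg = make_config(N=10, eta=-0.2)
    rng = np.random.default_rng(9)
    m = 10_000
    pop = init_population(m, cfg, rng)
    for ab in pop.members:
        ab.fitness = 0.0  # parents always survive; fresh set still sampled
    state = schedule(50, 50)
    rng_fresh = np.random.default_rng(10)
    from hfia.search import _threshold_antibodies
    fresh = _threshold_antibodies(cfg.N, m, cfg.eta + state.theta, rng_fresh)
    density = np.mean([ab.code.mean() for ab in fresh])
    assert density == pytest.approx(1 - cauchy_cdf(0.8), abs=0.02)


def test_optimize_trajectory_non_increasing_and_deterministic():
    cfg = make_config(N=6, Tmax=15, seed=3)
    best1, traj1 = optimize(24, surrogate_eval, cfg, np.random.default_rng(3))
    best2, traj2 = optimize(24, surrogate_eval, cfg, np.random.default_rng(3))
    assert traj1 == traj2
    np.testing.assert_array_equal(best1.code, best2.code)
    assert len(traj1) == 16
    assert all(a >= b for a, b in zip(traj1, traj1[1:]))


def test_run_hfia_deterministic_and_well_formed(small_planted):
    ds, _ = small_planted
    cfg = make_config(N=6, Tmax=8, fisher_k=30, seed=5)
    r1 = run_hfia(ds, cfg)
    r2 = run_hfia(ds, cfg)
    assert r1 == r2
    assert r1.n_selected >= 1
    assert len(r1.best_fitness_trajectory) == 9
    traj = r1.best_fitness_trajectory
    assert all(a >= b for a, b in zip(traj, traj[1:]))
    assert r1.reduction_rate == 1 - r1.n_selected / ds.n_features
    assert set(r1.selected_features) <= set(range(ds.n_features))


def test_run_hfia_pass_through_when_filter_exceeds_q(small_planted):
    ds, _ = small_planted
    cfg = make_config(N=4, Tmax=3, fisher_k=10_000, seed=1)
    result = run_hfia(ds, cfg)
    assert result.config_echo["fisher_k"] == 10_000
    assert result.n_total_features == ds.n_features


def test_run_hfia_tmax_zero_returns_best_initial(small_planted):
    ds, _ = small_planted
    cfg = make_config(N=4, Tmax=0, fisher_k=20, seed=2)
    result = run_hfia(ds, cfg)
    assert len(result.best_fitness_trajectory) == 1


def test_config_validation():
    with pytest.raises(ValueError):
        HFIAConfig(N=1)
    with pytest.raises(ValueError):
        HFIAConfig(c_r=0.0)
    with pytest.raises(ValueError):
        HFIAConfig(beta=0.0)
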