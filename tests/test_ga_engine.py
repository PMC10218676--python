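"""GA components: fitness, operators, rates, tabu memory and the main loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaselect import (
    Chromosome,
    GAConfig,
    RateTracker,
    SimulationConfig,
    TabuRegistry,
    adjusted_r2,
    choose_operator,
    crossover,
    fit_linear_ridge,
    fitness,
    init_population,
    mutate,
    run_ga,
    simulate_dataset,
)
from gaselect.ga_engine import CROSSOVER, MUTATION, FitnessFunction, FitnessScore
from gaselect.preprocess import CandidateSet


# ---------------------------------------------------------------------------
# ridge fit and adjusted R²


def test_ridge_recovers_noiseless_linear_target(rng):
    X = rng.normal(size=(50, 1))
    y = 3.0 * X[:, 0] + 1.0
    model = fit_linear_ridge(X, y)
    resid = y - model.predict(X)
    r2 = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
    assert r2 >= 0.999


def test_ridge_near_zero_r2_on_noise():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        model = fit_linear_ridge(X, y)
        resid = y - model.predict(X)
        r2 = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
        assert r2 < 0.1


def test_ridge_handles_duplicated_column(rng):
    X1 = rng.normal(size=(80, 1))
    y = 2.0 * X1[:, 0] + rng.normal(scale=0.1, size=80)
    X2 = np.column_stack([X1, X1])  # perfectly collinear
    m1, m2 = fit_linear_ridge(X1, y), fit_linear_ridge(X2, y)
    mse1 = np.mean((y - m1.predict(X1)) ** 2)
    mse2 = np.mean((y - m2.predict(X2)) ** 2)
    assert mse2 == pytest.approx(mse1, abs=1e-6)


def test_adjusted_r2_exact_cases():
    assert adjusted_r2(1.0, 100, 7) == pytest.approx(1.0, abs=1e-15)
    assert adjusted_r2(0.0, 57, 0) == pytest.approx(0.0, abs=1e-15)
    assert adjusted_r2(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9, abs=1e-12)
    assert np.isnan(adjusted_r2(0.5, 5, 4))  # n - p - 1 = 0 -> invalid signal


# ---------------------------------------------------------------------------
# fitness + tabu


def _training_instance(seed=0, n=80, m=6, k=2, h2=0.7):
    cfg = SimulationConfig(n=n, n_blocks=m, block_size=1, rho=0.0, k_qtl=k, h2=h2, seed=seed)
    G, y, truth = simulate_dataset(cfg)
    return G.codes.astype(float), y, truth


def test_fitness_degenerate_masks_are_worst():
    X, y, _ = _training_instance()
    tabu = TabuRegistry()
    zero = fitness(np.zeros(6, dtype=bool), X, y, tabu)
    assert not zero.valid and zero.key < FitnessScore(r2=0, adj_r2=-5.0, p=1).key
    full = fitness(np.ones(6, dtype=bool), X[:5], y[:5], TabuRegistry())  # p >= n - 1
    assert not full.valid


def test_fitness_tabu_caches_without_refit():
    X, y, _ = _training_instance()
    tabu = TabuRegistry()
    fn = FitnessFunction(X, y, tabu)
    mask = np.array([1, 0, 1, 0, 0, 0], dtype=bool)
    s1 = fn(mask)
    assert fn.n_fits == 1 and tabu.hits == 0
    s2 = fn(mask)
    assert fn.n_fits == 1 and tabu.hits == 1 and s1 == s2


def test_true_support_beats_single_qtl_mask():
    cfg = SimulationConfig(n=500, n_blocks=8, block_size=1, rho=0.0, k_qtl=3, h2=0.8, seed=11)
    G, y, truth = simulate_dataset(cfg)
    X = G.codes.astype(float)
    tabu = TabuRegistry()
    full = np.zeros(8, dtype=bool)
    full[truth.causal_indices] = True
    s_full = fitness(full, X, y, tabu)
    for i in truth.causal_indices:
        single = np.zeros(8, dtype=bool)
        single[i] = True
        assert s_full.adj_r2 > fitness(single, X, y, tabu).adj_r2


# ---------------------------------------------------------------------------
# population initialization


def test_init_population_deterministic():
    cfg = GAConfig(seed=4, pool_size=10)
    free = lambda genes: FitnessScore(r2=0.0, adj_r2=0.0, p=int(genes.sum()))  # noqa: E731
    pools = []
    for _ in range(2):
        pool = init_population(100, cfg, np.random.default_rng(9), free)
        pools.append([tuple(c.genes.nonzero()[0]) for c in pool])
    assert pools[0] == pools[1]
    assert len(set(pools[0])) == 10  # distinct masks


def test_init_population_single_candidate_degenerates():
    X, y, _ = _training_instance(m=6)
    fn = FitnessFunction(X[:, :1], y, TabuRegistry())
    pool = init_population(1, GAConfig(seed=1, pool_size=4), np.random.default_rng(0), fn)
    assert all(c.genes.tolist() == [True] for c in pool)


def test_init_cardinality_uniform_chi_square():
    """Initial mask cardinalities should be uniform on [1, 20]."""
    import scipy.stats

    cfg = GAConfig(seed=0, pool_size=10)
    rng = np.random.default_rng(123)
    X, y, _ = _training_instance(m=6)

    class FreeFitness:
        def __call__(self, genes):
            return FitnessScore(r2=0.0, adj_r2=0.0, p=int(genes.sum()))

    cards = []
    while len(cards) < 1000:
        pool = init_population(100, cfg, rng, FreeFitness())
        cards.extend(c.p for c in pool)
    counts = np.bincount(cards[:1000], minlength=21)[1:]
    chi = scipy.stats.chisquare(counts)
    assert chi.pvalue > 0.01


# ---------------------------------------------------------------------------
# operators


class TableFitness:
    """Exhaustive lookup fitness over a small bit space; registers in tabu."""

    def __init__(self, table, tabu):
        self.table = table  # dict: bit-tuple -> adj_r2
        self.tabu = tabu
        self.n_fits = 0

    def __call__(self, genes):
        key = tuple(int(g) for g in genes)
        cached = self.tabu.lookup(np.asarray(genes, bool))
        if cached is not None:
            return cached
        self.n_fits += 1
        score = FitnessScore(r2=0.0, adj_r2=self.table[key], p=sum(key))
        self.tabu.register(np.asarray(genes, bool), score)
        return score


def test_mutate_edit_distance_bounds(rng):
    X, y, _ = _training_instance(m=6)
    tabu = TabuRegistry()
    fn = FitnessFunction(X, y, tabu)
    c = Chromosome(genes=np.zeros(6, dtype=bool))
    c.score = fn(c.genes)
    for _ in range(20):
        child = mutate(c, fn, 1, tabu, rng)
        if child.noop:
            continue
        dist = int((child.genes != c.genes).sum())
        assert 1 <= dist <= 3
        assert child.p >= 1  # from the all-zero mask any flip is evaluable


def test_mutate_finds_global_optimum_on_exhaustive_table():
    """Repeated mutation alone must reach the 6-bit global optimum."""
    rng_table = np.random.default_rng(77)
    table = {bits: float(rng_table.uniform(0, 0.9)) for bits in itertools.product((0, 1), repeat=6)}
    best_key = max(table, key=table.get)
    for seed in range(10):
        rng = np.random.default_rng(seed)
        tabu = TabuRegistry()
        fn = TableFitness(table, tabu)
        c = Chromosome(genes=np.zeros(6, dtype=bool))
        c.score = fn(c.genes)
        found = False
        for _ in range(200):
            child = mutate(c, fn, 5, tabu, rng)
            if not child.noop and child.score.key > c.score.key:
                c = child
            if tuple(int(g) for g in c.genes) == best_key:
                found = True
                break
        assert found, f"seed {seed} failed to reach the optimum"


def test_crossover_identical_parents_noop(rng):
    X, y, _ = _training_instance(m=6)
    tabu = TabuRegistry()
    fn = FitnessFunction(X, y, tabu)
    g = np.array([1, 0, 1, 0, 0, 0], dtype=bool)
    p1 = Chromosome(genes=g.copy(), score=fn(g))
    p2 = Chromosome(genes=g.copy(), score=p1.score)
    child = crossover(p1, p2, fn, 5, tabu, rng)
    assert child.noop and np.array_equal(child.genes, g)


def test_crossover_agreement_positions_fixed(rng):
    X, y, _ = _training_instance(m=4)
    tabu = TabuRegistry()
    fn = FitnessFunction(X[:, :4], y, tabu)
    gp = Chromosome(genes=np.array([1, 1, 0, 0], dtype=bool))
    gd = Chromosome(genes=np.array([1, 0, 1, 0], dtype=bool))
    gp.score, gd.score = fn(gp.genes), fn(gd.genes)
    for _ in range(20):
        child = crossover(gp, gd, fn, 3, tabu, rng)
        assert child.genes[0] == True and child.genes[3] == False  # noqa: E712
        # every gene inherited from a parent
        assert all(child.genes[i] in (gp.genes[i], gd.genes[i]) for i in range(4))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_crossover_inheritance_property(seed):
    rng = np.random.default_rng(seed)
    m = 10
    gp = Chromosome(genes=rng.random(m) < 0.5)
    gd = Chromosome(genes=rng.random(m) < 0.5)

    class Free:
        def __init__(self):
            self.tabu = TabuRegistry()

        def __call__(self, genes):
            s = FitnessScore(0.0, float(rng.random()), int(genes.sum()))
            self.tabu.register(genes, s)
            return s

    fn = Free()
    child = crossover(gp, gd, fn, 4, fn.tabu, rng)
    assert all(child.genes[i] in (gp.genes[i], gd.genes[i]) for i in range(m))


def test_crossover_combines_qtl_masks():
    """Two single-QTL parents should yield a multi-QTL child quickly."""
    cfg = SimulationConfig(n=200, n_blocks=9, block_size=1, rho=0.0, k_qtl=3, h2=0.8, seed=3)
    G, y, truth = simulate_dataset(cfg)
    X = G.codes.astype(float)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        tabu = TabuRegistry()
        fn = FitnessFunction(X, y, tabu)
        masks = []
        for i in truth.causal_indices[:2]:
            g = np.zeros(9, dtype=bool)
            g[i] = True
            masks.append(Chromosome(genes=g, score=fn(g)))
        gp, gd = masks
        ok = False
        for _ in range(50):
            child = crossover(gp, gd, fn, 5, tabu, rng)
            if not child.noop and child.genes[list(truth.causal_indices[:2])].sum() >= 2:
                ok = True
                break
            if not child.noop and child.score.key > min(gp.score.key, gd.score.key):
                if gp.score.key < gd.score.key:
                    gp = child
                else:
                    gd = child
        hits += ok
    assert hits >= 9


# ---------------------------------------------------------------------------
# adaptive rates


def test_rate_tracker_laws():
    rt = RateTracker(rate_floor=0.2, window=3)
    assert rt.p_cross == 0.5  # uninformative start
    for op in (CROSSOVER, CROSSOVER, MUTATION):
        rt.record(op)
    assert rt.p_cross == pytest.approx(2 / 3)
    rt2 = RateTracker(rate_floor=0.2, window=3)
    for _ in range(3):
        rt2.record(MUTATION)
    assert rt2.p_cross == pytest.approx(0.2)  # floor
    rt3 = RateTracker(rate_floor=0.2, window=3)
    for _ in range(3):
        rt3.record(CROSSOVER)
    assert rt3.p_cross == pytest.approx(0.8)  # ceiling = 1 - floor
    assert rt.p_mut + rt.p_cross == pytest.approx(1.0)


def test_choose_operator_frequency():
    rt = RateTracker(rate_floor=0.2, window=3)
    for op in (CROSSOVER, CROSSOVER, MUTATION):
        rt.record(op)
    rng = np.random.default_rng(42)
    draws = sum(choose_operator(rt, rng) == CROSSOVER for _ in range(10_000))
    assert draws / 10_000 == pytest.approx(2 / 3, abs=0.02)


# ---------------------------------------------------------------------------
# run_ga


def _ga_instance(seed=0):
    cfg = SimulationConfig(n=120, n_blocks=8, block_size=1, rho=0.0, k_qtl=3, h2=0.8, seed=seed)
    G, y, _ = simulate_dataset(cfg)
    cand = CandidateSet(indices=np.arange(8), scores=np.zeros(8), ld_cutoff=1.0)
    return G, y, cand


def test_run_ga_k0_returns_initial_best():
    G, y, cand = _ga_instance()
    res = run_ga(G, y, cand, GAConfig(seed=2, iterations=0))
    assert res.trace.size == 0
    assert res.fitness_calls <= 10  # only the initial pool


def test_run_ga_trace_nondecreasing_and_budget():
    G, y, cand = _ga_instance()
    cfg = GAConfig(seed=5, iterations=150, operator_budget=4, pool_size=6)
    res = run_ga(G, y, cand, cfg)
    assert np.all(np.diff(res.trace) >= 0)
    assert res.fitness_calls <= cfg.operator_budget * cfg.iterations + cfg.pool_size
    assert res.score.valid
    ids = {l.id for l in res.selected_loci}
    assert ids == {G.loci[cand.indices[j]].id for j in np.flatnonzero(res.best_mask)}


def test_run_ga_deterministic_under_seed():
    G, y, cand = _ga_instance()
    cfg = GAConfig(seed=9, iterations=100)
    r1, r2 = run_ga(G, y, cand, cfg), run_ga(G, y, cand, cfg)
    assert np.array_equal(r1.best_mask, r2.best_mask)
    assert np.array_equal(r1.trace, r2.trace)
    assert r1.fitness_calls == r2.fitness_calls


def test_ga_config_validation():
    with pytest.raises(ValueError):
        GAConfig(seed=1, pool_size=1)
    with pytest.raises(ValueError):
        GAConfig(seed=1, rate_floor=0.6)
    with pytest.raises(ValueError):
        GAConfig(seed=1, operator_budget=0)
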