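"""Tabu-augmented steady-state genetic algorithm over binary SNP masks.

A chromosome is a bit vector over the candidate SNPs; its fitness is the
adjusted R² of a Bayesian ridge regression fitted on the masked training
columns,

    R²_adj = 1 - (1 - R²) (n - 1) / (n - p - 1),

where n is the training sample count and p the number of set bits.  The
penalty on p implements the secondary objective of selecting as few
features as possible.  A tabu registry caches the score of every mask
ever evaluated within a run, so no model is ever refitted for a
revisited mask, and operators skip known masks without spending budget.

Mutation flips 1-3 uniformly chosen bits; crossover inherits each gene
from either parent with probability 1/2.  Each operator application may
evaluate up to ``operator_budget`` (L) fresh variants and proposes the
best.  The steady-state pool of size S replaces its worst member when an
offspring strictly improves on it (ties broken toward fewer features),
and the operator responsible is recorded: the crossover probability for
subsequent turns is the fraction of crossover entries among the last
``window`` improvements, clamped to [rate_floor, 1 - rate_floor].

Total model fits per run are bounded by L*K + S for K iterations.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from math import inf

import numpy as np
from sklearn.linear_model import BayesianRidge

from .data_io import GenotypeMatrix, Locus
from .preprocess import CandidateSet

log = logging.getLogger("gaselect")

__all__ = [
    "GAConfig",
    "Chromosome",
    "FitnessScore",
    "TabuRegistry",
    "RateTracker",
    "FitnessFunction",
    "SelectionResult",
    "fit_linear_ridge",
    "adjusted_r2",
    "fitness",
    "init_population",
    "mutate",
    "crossover",
    "choose_operator",
    "run_ga",
]

MUTATION = "mutation"
CROSSOVER = "crossover"

#: Sentinel fitness for degenerate masks (no features, or p >= n - 1).
WORST_ADJ_R2 = -inf


@dataclass(frozen=True)
class GAConfig:
    """Search hyperparameters.

    iterations
        K, the maximum number of operator applications (outer-loop bound).
    pool_size
        S, the number of chromosomes kept in the steady-state parent pool.
    operator_budget
        L, the maximum fresh fitness evaluations per operator application.
    rate_floor
        Lower clamp on both operator probabilities; neither mutation nor
        crossover may fall below this share.
    window
        Number of recent improvements consulted when setting the
        crossover probability.
    runs
        Independent GA repetitions whose selected sets are intersected.
    init_max_bits
        Initial masks draw their cardinality uniformly from
        [1, min(init_max_bits, n_candidates)].
    seed
        Root seed for the run; mandatory, no default.
    """

    seed: int
    iterations: int = 5000
    pool_size: int = 10
    operator_budget: int = 10
    rate_floor: float = 0.2
    window: int = 3
    runs: int = 3
    init_max_bits: int = 20

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.operator_budget < 1:
            raise ValueError("operator_budget must be >= 1")
        if not 0.0 < self.rate_floor <= 0.5:
            raise ValueError("rate_floor must lie in (0, 0.5]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.init_max_bits < 1:
            raise ValueError("init_max_bits must be >= 1")


@dataclass(frozen=True)
class FitnessScore:
    r2: float
    adj_r2: float
    p: int
    valid: bool = True

    @property
    def key(self) -> tuple[float, int]:
        """Ordering key: maximize adjusted R², then minimize feature count."""
        return (self.adj_r2 if self.valid else WORST_ADJ_R2, -self.p)


@dataclass
class Chromosome:
    """A binary feature mask plus its cached score."""

    genes: np.ndarray  # bool vector over the candidate set
    score: FitnessScore | None = None
    noop: bool = False  # set when an operator could not produce a fresh variant

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=bool)

    @property
    def p(self) -> int:
        return int(self.genes.sum())


class TabuRegistry:
    """Memory of every mask scored this run; lookup never triggers a refit."""

    def __init__(self) -> None:
        self._visited: dict[bytes, FitnessScore] = {}
        self.hits: int = 0

    @staticmethod
    def key(genes: np.ndarray) -> bytes:
        return np.packbits(np.asarray(genes, dtype=bool)).tobytes()

    def __len__(self) -> int:
        return len(self._visited)

    def __contains__(self, genes: np.ndarray) -> bool:
        return self.key(genes) in self._visited

    def lookup(self, genes: np.ndarray) -> FitnessScore | None:
        score = self._visited.get(self.key(genes))
        if score is not None:
            self.hits += 1
        return score

    def register(self, genes: np.ndarray, score: FitnessScore) -> None:
        self._visited[self.key(genes)] = score

    @property
    def n_valid(self) -> int:
        """Distinct masks whose scoring required an actual model fit."""
        return sum(1 for s in self._visited.values() if s.valid)


@dataclass
class RateTracker:
    """Adaptive operator probabilities driven by recent improvement sources."""

    rate_floor: float = 0.2
    window: int = 3
    recent: deque = field(default_factory=lambda: deque(maxlen=3))

    def __post_init__(self) -> None:
        self.recent = deque(self.recent, maxlen=self.window)

    @property
    def p_cross(self) -> float:
        if not self.recent:
            return 0.5
        c = sum(1 for op in self.recent if op == CROSSOVER)
        return float(np.clip(c / self.window, self.rate_floor, 1.0 - self.rate_floor))

    @property
    def p_mut(self) -> float:
        return 1.0 - self.p_cross

    def record(self, op: str) -> None:
        if op not in (MUTATION, CROSSOVER):
            raise ValueError(f"unknown operator {op!r}")
        self.recent.append(op)


# ---------------------------------------------------------------------------
# fitness


def fit_linear_ridge(X: np.ndarray, y: np.ndarray) -> BayesianRidge:
    """Fit a linear model with automatically tuned L2 shrinkage.

    Bayesian ridge tunes the penalty by evidence maximization, never
    forces coefficients exactly to zero (no L1 behaviour), and is
    deterministic given (X, y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x p with n matching y")
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need n >= 2 and p >= 1")
    model = BayesianRidge()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter on tiny fits
        model.fit(X, y)
    return model


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R² penalized for model size: 1 - (1 - R²)(n - 1)/(n - p - 1).

    Returns NaN (an invalid-score signal, not an exception) when
    n - p - 1 <= 0; callers map it to the worst possible fitness.
    """
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _degenerate_score(p: int) -> FitnessScore:
    return FitnessScore(r2=float("nan"), adj_r2=WORST_ADJ_R2, p=p, valid=False)


def fitness(
    genes: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    tabu: TabuRegistry,
) -> FitnessScore:
    """Score one mask: in-sample adjusted R² of the ridge fit on masked columns.

    Revisited masks return their cached score without refitting.  Masks
    with p = 0 or p >= n - 1 get the sentinel worst score (still
    registered, so they are never re-examined).
    """
    genes = np.asarray(genes, dtype=bool)
    cached = tabu.lookup(genes)
    if cached is not None:
        return cached
    n = int(np.asarray(y).size)
    p = int(genes.sum())
    if p == 0 or p >= n - 1:
        score = _degenerate_score(p)
    else:
        Xm = np.asarray(X, dtype=float)[:, genes]
        yv = np.asarray(y, dtype=float)
        model = fit_linear_ridge(Xm, yv)
        resid = yv - model.predict(Xm)
        tss = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        score = FitnessScore(r2=r2, adj_r2=adjusted_r2(r2, n, p), p=p)
    tabu.register(genes, score)
    return score


class FitnessFunction:
    """Callable fitness bound to one training set and tabu registry.

    Counts actual model fits, which tabu caching keeps equal to the
    number of distinct non-degenerate masks ever scored.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, tabu: TabuRegistry) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.tabu = tabu
        self.n_fits = 0

    def __call__(self, genes: np.ndarray) -> FitnessScore:
        fresh = genes not in self.tabu
        score = fitness(genes, self.X, self.y, self.tabu)
        if fresh and score.valid:
            self.n_fits += 1
        return score


# ---------------------------------------------------------------------------
# operators


def init_population(
    candidates: CandidateSet | int,
    cfg: GAConfig,
    rng: np.random.Generator,
    fitness_fn,
) -> list[Chromosome]:
    """Draw S initial masks with cardinality uniform in [1, min(init_max_bits, m)].

    Masks are distinct when the search space allows; otherwise duplicates
    are admitted with a warning.  All are scored immediately.
    """
    m = len(candidates) if isinstance(candidates, CandidateSet) else int(candidates)
    if m < 1:
        raise ValueError("candidate set must be non-empty")
    max_bits = min(cfg.init_max_bits, m)
    pool: list[Chromosome] = []
    seen: set[bytes] = set()
    attempts = 0
    while len(pool) < cfg.pool_size:
        card = int(rng.integers(1, max_bits + 1))
        genes = np.zeros(m, dtype=bool)
        genes[rng.choice(m, size=card, replace=False)] = True
        key = TabuRegistry.key(genes)
        attempts += 1
        if key in seen and attempts < 100 * cfg.pool_size:
            continue
        if key in seen:
            log.warning("search space too small for %d distinct initial masks; admitting duplicates", cfg.pool_size)
        seen.add(key)
        pool.append(Chromosome(genes=genes, score=fitness_fn(genes)))
    return pool


def mutate(
    c: Chromosome,
    fitness_fn,
    L: int,
    tabu: TabuRegistry,
    rng: np.random.Generator,
) -> Chromosome:
    """Propose the best of up to L fresh variants of ``c``.

    Each variant flips 1-3 uniformly chosen gene positions (count drawn
    uniformly).  Variants already in the tabu registry are skipped
    without a model fit.  If every attempt hits tabu, ``c`` is returned
    unchanged with ``noop`` set.
    """
    m = c.genes.size
    best: Chromosome | None = None
    for _ in range(L):
        k = int(rng.integers(1, min(3, m) + 1))
        pos = rng.choice(m, size=k, replace=False)
        genes = c.genes.copy()
        genes[pos] = ~genes[pos]
        if genes in tabu:
            continue
        score = fitness_fn(genes)
        if best is None or score.key > best.score.key:
            best = Chromosome(genes=genes, score=score)
    if best is None:
        return Chromosome(genes=c.genes.copy(), score=c.score, noop=True)
    return best


def crossover(
    gp: Chromosome,
    gd: Chromosome,
    fitness_fn,
    L: int,
    tabu: TabuRegistry,
    rng: np.random.Generator,
) -> Chromosome:
    """Propose the best of up to L uniform-inheritance children of two parents.

    Each child gene is copied from either parent with probability 1/2,
    so positions where the parents agree are fixed.  Identical parents
    short-circuit to a no-op copy; children already in tabu are skipped
    without a fit.
    """
    if gp.genes.size != gd.genes.size:
        raise ValueError("parents must have equal gene length")
    if np.array_equal(gp.genes, gd.genes):
        return Chromosome(genes=gp.genes.copy(), score=gp.score, noop=True)
    best: Chromosome | None = None
    for _ in range(L):
        take_p = rng.random(gp.genes.size) < 0.5
        genes = np.where(take_p, gp.genes, gd.genes)
        if genes in tabu:
            continue
        score = fitness_fn(genes)
        if best is None or score.key > best.score.key:
            best = Chromosome(genes=genes, score=score)
    if best is None:
        better = gp if (gp.score and gd.score and gp.score.key >= gd.score.key) else gd
        return Chromosome(genes=better.genes.copy(), score=better.score, noop=True)
    return best


def choose_operator(rt: RateTracker, rng: np.random.Generator) -> str:
    """Sample crossover vs mutation from the tracker's current probabilities."""
    return CROSSOVER if rng.random() < rt.p_cross else MUTATION


# ---------------------------------------------------------------------------
# main loop


@dataclass
class SelectionResult:
    """Outcome of one GA run: best mask, its loci and score, and accounting."""

    best_mask: np.ndarray
    selected_loci: list[Locus]
    score: FitnessScore
    trace: np.ndarray  # best adjusted R² after each iteration
    fitness_calls: int
    tabu_hits: int
    seed: int
    candidate_ids: tuple[str, ...]  # locus ids of the candidate set, rank order


def run_ga(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    candidates: CandidateSet,
    cfg: GAConfig,
) -> SelectionResult:
    """Steady-state GA search over masks of the candidate SNPs.

    Each iteration visits one pool member (round-robin), applies a single
    operator chosen from the adaptive rates (crossover partner drawn
    uniformly among the other members), and replaces the pool's worst
    member if the offspring strictly improves on it.  Stops after
    ``cfg.iterations`` rounds, or early once adjusted R² reaches 1.
    """
    rng = np.random.default_rng(cfg.seed)
    X = G_train.codes[:, candidates.indices].astype(float)
    y = np.asarray(y_train, dtype=float)
    tabu = TabuRegistry()
    fitness_fn = FitnessFunction(X, y, tabu)
    L, S = cfg.operator_budget, cfg.pool_size

    pool = init_population(candidates, cfg, rng, fitness_fn)
    rt = RateTracker(rate_floor=cfg.rate_floor, window=cfg.window)

    def best_idx() -> int:
        return max(range(len(pool)), key=lambda i: pool[i].score.key)

    def worst_idx() -> int:
        return min(range(len(pool)), key=lambda i: pool[i].score.key)

    trace: list[float] = []
    for it in range(cfg.iterations):
        champion = pool[best_idx()]
        if champion.score.valid and champion.score.adj_r2 >= 1.0:
            break  # perfect fit; nothing left to optimize
        member = pool[it % S]
        op = choose_operator(rt, rng)
        if op == CROSSOVER:
            partner_idx = int(rng.integers(S - 1))
            partner_idx += partner_idx >= (it % S)
            child = crossover(member, pool[partner_idx], fitness_fn, L, tabu, rng)
        else:
            child = mutate(member, fitness_fn, L, tabu, rng)
        w = worst_idx()
        if not child.noop and child.score.key > pool[w].score.key:
            pool[w] = child
            rt.record(op)
        trace.append(pool[best_idx()].score.adj_r2)

    champion = pool[best_idx()]
    assert fitness_fn.n_fits <= L * cfg.iterations + S, "fitness-call budget exceeded"
    loci = [G_train.loci[candidates.indices[j]] for j in np.flatnonzero(champion.genes)]
    return SelectionResult(
        best_mask=champion.genes.copy(),
        selected_loci=loci,
        score=champion.score,
        trace=np.asarray(trace, dtype=float),
        fitness_calls=fitness_fn.n_fits,
        tabu_hits=tabu.hits,
        seed=cfg.seed,
        candidate_ids=tuple(G_train.loci[i].id for i in candidates.indices),
    )
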