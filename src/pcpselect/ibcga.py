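"""Inheritable bi-objective combinatorial GA for feature-subset selection.

The search space is C(n, r): subsets of exactly r properties out of n,
jointly with two 4-bit SVM hyper-parameter genes (gamma and C codes).  A
chromosome is n binary genes with exactly r ones plus the two parameter
codes.  Every operator (initialization, orthogonal-array crossover with
repair, swap mutation, inheritance) preserves the exact-r invariant.

Recombination is orthogonal-array (OA) crossover from orthogonal
experimental design: gene positions are split into contiguous blocks, each
block (and each parameter gene) is a two-level factor — take it from parent
1 or parent 2 — and a strength-2 OA prescribes which factor combinations to
evaluate.  Per-factor main effects estimated from those evaluations then
assemble a "reasoned" child from each factor's better level, a
divide-and-conquer alternative to blind recombination.

Moving from subset size r to r+1 is by inheritance: every individual flips
one random 0 to 1, so the population for C(n, r+1) starts from good C(n, r)
solutions and one run sweeps r = r_start .. r_end.

Default control parameters: r_start=10, r_end=30, population 50, crossover
probability 0.8, mutation probability 0.05, 30 independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .svm_eval import SvmParams, make_folds

#: fitness oracle signature: (genes bool vector, gamma_code, cost_code) -> float
FitnessFn = Callable[[np.ndarray, int, int], float]


@dataclass
class Chromosome:
    genes: np.ndarray  # bool, length n
    gamma_code: int
    cost_code: int
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=bool)

    @property
    def r(self) -> int:
        return int(self.genes.sum())

    def selected(self) -> np.ndarray:
        return np.nonzero(self.genes)[0]

    def key(self) -> tuple:
        return (self.genes.tobytes(), self.gamma_code, self.cost_code)

    def params(self) -> SvmParams:
        return SvmParams.from_codes(self.gamma_code, self.cost_code)

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.gamma_code, self.cost_code, self.fitness)


@dataclass
class GAConfig:
    r_start: int = 10
    r_end: int = 30
    pop_size: int = 50
    p_c: float = 0.8
    p_m: float = 0.05
    runs: int = 30
    stop_idle: int = 10
    max_gen: int = 60
    oa_factors: int = 5  # gene-block factors; +2 parameter factors -> L8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.r_start <= self.r_end:
            raise ValueError("need 1 <= r_start <= r_end")
        if not (0 <= self.p_c <= 1 and 0 <= self.p_m <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SolutionSet:
    """Best chromosome per subset size r from one GA run."""

    best: dict[int, Chromosome] = field(default_factory=dict)
    run_seed: int = 0
    fitness_trace: dict[int, list[float]] = field(default_factory=dict)

    def sizes(self) -> list[int]:
        return sorted(self.best)


@dataclass
class MEDReport:
    """Main-effect-difference ranking of the features in one solution."""

    feature_ids: list
    med: np.ndarray
    ranks: np.ndarray  # 1 = largest MED

    def ordered(self) -> list:
        order = np.argsort(self.ranks)
        return [(self.feature_ids[i], float(self.med[i]), int(self.ranks[i])) for i in order]


class CachedFitness:
    """Memoize a fitness oracle on (genes, gamma_code, cost_code).

    ``reseed`` marks a new evaluation batch: oracles whose value depends on
    a random element (CV folds) redraw it and the memo is cleared, so every
    chromosome within one batch is scored on identical folds while no single
    fold assignment can be overfitted across the whole run.
    """

    def __init__(self, fn: FitnessFn, reseed_fn: Callable[[int], None] | None = None):
        self._fn = fn
        self._reseed_fn = reseed_fn
        self._cache: dict[tuple, float] = {}
        self.calls = 0  # underlying evaluations, cache hits excluded

    def __call__(self, genes: np.ndarray, gamma_code: int, cost_code: int) -> float:
        key = (np.asarray(genes, dtype=bool).tobytes(), gamma_code, cost_code)
        if key not in self._cache:
            self.calls += 1
            self._cache[key] = self._fn(genes, gamma_code, cost_code)
        return self._cache[key]

    def reseed(self, seed: int) -> None:
        if self._reseed_fn is not None:
            self._reseed_fn(seed)
            self._cache.clear()


def feature_subset_fitness(
    X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> CachedFitness:
    """Fitness oracle: pooled 5-CV SVM accuracy on the selected columns.

    Within one evaluation batch a single stratified fold assignment is used
    for every chromosome, so competing subsets are compared on identical
    splits; :meth:`CachedFitness.reseed` redraws the folds between batches
    (the GA calls it once per generation), preventing the search from
    overfitting any particular split.  The RBF kernel is evaluated from
    cached per-feature squared-difference matrices (the Gram matrix of a
    column subset is ``exp(-gamma * sum_j D2_j)``), which makes the
    thousands of nearly-identical subset evaluations a GA performs much
    cheaper than refitting from raw columns; the result is identical to
    :func:`pcpselect.svm_eval.cv_fitness` on the same folds.
    """
    # the GA evaluates thousands of subsets, so the per-call validation cost
    # of the estimator API dominates; the low-level libsvm binding gives
    # bit-identical C-SVC results (asserted against cv_fitness in the tests)
    from sklearn.svm import _libsvm as libsvm

    libsvm.set_verbosity_wrap(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    yf = y.astype(np.float64)
    splits = make_folds(y, folds, seed)
    # per-feature squared differences: D2[j, a, b] = (X[a, j] - X[b, j])^2
    D2 = (X.T[:, :, None] - X.T[:, None, :]) ** 2

    def fn(genes: np.ndarray, gamma_code: int, cost_code: int) -> float:
        cols = np.nonzero(np.asarray(genes, dtype=bool))[0]
        if cols.size == 0:
            return 0.0
        params = SvmParams.from_codes(gamma_code, cost_code)
        K = np.exp(-params.gamma * D2[cols].sum(axis=0))
        correct = 0
        for train, test in splits:
            support, SV, nSV, coef, intercept, *_ = libsvm.fit(
                K[np.ix_(train, train)], yf[train],
                svm_type=0, kernel="precomputed", C=params.cost,
            )
            pred = libsvm.predict(
                K[np.ix_(test, train)], support, SV, nSV, coef, intercept,
                svm_type=0, kernel="precomputed",
            )
            correct += int((pred.astype(int) == y[test]).sum())
        return correct / len(y)

    def reseed(new_seed: int) -> None:
        nonlocal splits
        splits = make_folds(y, folds, new_seed)

    return CachedFitness(fn, reseed_fn=reseed)


# ---------------------------------------------------------------------------
# orthogonal array


def build_oa(k: int) -> np.ndarray:
    """Two-level strength-2 orthogonal array with k columns (Sylvester type).

    Returns an M x k 0/1 array with M = 2^ceil(log2(k + 1)) rows; entry
    (i, j) is the parity of the bitwise AND of the row index i and the
    column word j + 1.  Every column is balanced and every pair of columns
    contains each of the four level pairs equally often.
    """
    if k < 2:
        raise ValueError("need at least 2 factors")
    M = 1 << int(np.ceil(np.log2(k + 1)))
    rows = np.arange(M)[:, None]
    words = np.arange(1, k + 1)[None, :]
    return np.array(
        [[bin(int(i & w)).count("1") & 1 for w in words[0]] for i in rows[:, 0]],
        dtype=int,
    )


def _repair(genes: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Restore popcount r by random compensating flips."""
    genes = genes.copy()
    ones = np.nonzero(genes)[0]
    if ones.size > r:
        off = rng.choice(ones, size=ones.size - r, replace=False)
        genes[off] = False
    elif ones.size < r:
        zeros = np.nonzero(~genes)[0]
        on = rng.choice(zeros, size=r - ones.size, replace=False)
        genes[on] = True
    return genes


def _gene_blocks(n: int, k: int) -> list[np.ndarray]:
    """Partition positions 0..n-1 into k contiguous blocks."""
    return [np.asarray(b, dtype=int) for b in np.array_split(np.arange(n), k)]


def oa_crossover(
    p1: Chromosome,
    p2: Chromosome,
    k: int,
    eval_fn: FitnessFn,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Orthogonal-array crossover with main-effect reasoning.

    Factors are k contiguous gene blocks plus the two 4-bit parameter genes.
    Each OA row assembles a candidate taking every factor from parent 1
    (level 0) or parent 2 (level 1); candidates are repaired to popcount r
    and evaluated.  Returns (best evaluated candidate, reasoned child built
    from each factor's better level).
    """
    if p1.r != p2.r:
        raise ValueError(f"parents must share subset size, got {p1.r} != {p2.r}")
    r = p1.r
    n = p1.genes.size
    k = min(k, n)
    blocks = _gene_blocks(n, k)
    total = k + 2  # + gamma factor + cost factor
    oa = build_oa(total)

    def assemble(levels: np.ndarray) -> Chromosome:
        genes = np.empty(n, dtype=bool)
        for b, block in enumerate(blocks):
            src = p2 if levels[b] else p1
            genes[block] = src.genes[block]
        genes = _repair(genes, r, rng)
        gamma = (p2 if levels[k] else p1).gamma_code
        cost = (p2 if levels[k + 1] else p1).cost_code
        return Chromosome(genes, gamma, cost)

    candidates = []
    fits = np.empty(len(oa))
    for i, row in enumerate(oa):
        c = assemble(row)
        c.fitness = eval_fn(c.genes, c.gamma_code, c.cost_code)
        fits[i] = c.fitness
        candidates.append(c)

    # per-factor main effects: mean fitness at each level
    best_levels = np.empty(total, dtype=int)
    for f in range(total):
        at0 = fits[oa[:, f] == 0].mean()
        at1 = fits[oa[:, f] == 1].mean()
        best_levels[f] = 0 if at0 >= at1 else 1
    child2 = assemble(best_levels)
    child2.fitness = eval_fn(child2.genes, child2.gamma_code, child2.cost_code)
    child1 = candidates[int(np.argmax(fits))]
    return child1, child2


# ---------------------------------------------------------------------------
# GA operators


def init_population(n: int, r: int, cfg: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """Population of pop_size chromosomes, each with exactly r ones."""
    if r > n:
        raise ValueError(f"r={r} exceeds n={n}")
    pop = []
    for _ in range(cfg.pop_size):
        genes = np.zeros(n, dtype=bool)
        genes[rng.choice(n, size=r, replace=False)] = True
        pop.append(Chromosome(genes, int(rng.integers(16)), int(rng.integers(16))))
    return pop


def _mutate(c: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Swap one selected/unselected pair; resample one parameter gene."""
    genes = c.genes.copy()
    ones = np.nonzero(genes)[0]
    zeros = np.nonzero(~genes)[0]
    if ones.size and zeros.size:
        genes[rng.choice(ones)] = False
        genes[rng.choice(zeros)] = True
    gamma, cost = c.gamma_code, c.cost_code
    if rng.random() < 0.5:
        gamma = int(rng.integers(16))
    else:
        cost = int(rng.integers(16))
    return Chromosome(genes, gamma, cost)


def _evaluate(pop: list[Chromosome], eval_fn: FitnessFn) -> None:
    for c in pop:
        if c.fitness is None:
            c.fitness = eval_fn(c.genes, c.gamma_code, c.cost_code)


def evolve_r(
    population: list[Chromosome],
    cfg: GAConfig,
    eval_fn: FitnessFn,
    rng: np.random.Generator,
    trace: list[float] | None = None,
) -> tuple[Chromosome, list[Chromosome]]:
    """Evolve one subset size to convergence; returns (best-ever, final pop).

    Loop: tournament selection (size 2, with replacement) into a mating
    pool, OA crossover on p_c * pop_size parents, swap mutation on
    p_m * pop_size individuals sparing the best, elitist reinsertion of the
    best-ever chromosome.  Stops when the best fitness has not improved for
    ``stop_idle`` generations or after ``max_gen`` generations.
    """
    pop = [c.copy() for c in population]
    _evaluate(pop, eval_fn)
    best = max(pop, key=lambda c: c.fitness).copy()
    if trace is not None:
        trace.append(best.fitness)
    idle = 0
    reseedable = hasattr(eval_fn, "reseed")
    for gen in range(cfg.max_gen):
        if reseedable and gen > 0:
            # new evaluation batch: fresh CV folds for the whole generation
            eval_fn.reseed(int(rng.integers(2**31 - 1)))
            for c in pop:
                c.fitness = None
            _evaluate(pop, eval_fn)
        # tournament selection, size 2, with replacement
        pool = []
        for _ in range(cfg.pop_size):
            i, j = rng.integers(len(pop)), rng.integers(len(pop))
            pool.append(pop[i] if pop[i].fitness >= pop[j].fitness else pop[j])
        new_pop = [c.copy() for c in pool]

        n_parents = int(cfg.p_c * cfg.pop_size) & ~1  # even count
        order = rng.permutation(cfg.pop_size)
        for a in range(0, n_parents, 2):
            i, j = order[a], order[a + 1]
            c1, c2 = oa_crossover(new_pop[i], new_pop[j], cfg.oa_factors, eval_fn, rng)
            new_pop[i], new_pop[j] = c1, c2

        _evaluate(new_pop, eval_fn)
        elite = int(np.argmax([c.fitness for c in new_pop]))
        n_mut = int(cfg.p_m * cfg.pop_size)
        if n_mut:
            mutable = [i for i in range(cfg.pop_size) if i != elite]
            for i in rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False):
                new_pop[i] = _mutate(new_pop[i], rng)
        _evaluate(new_pop, eval_fn)

        # elitism: best-ever survives
        gen_best = max(new_pop, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best.copy()
            idle = 0
        else:
            idle += 1
            worst = int(np.argmin([c.fitness for c in new_pop]))
            new_pop[worst] = best.copy()
        pop = new_pop
        if trace is not None:
            trace.append(best.fitness)
        if idle >= cfg.stop_idle:
            break
    return best, pop


def inherit(pop: list[Chromosome], rng: np.random.Generator) -> list[Chromosome]:
    """Flip one random 0 -> 1 in every individual (r grows by one)."""
    out = []
    for c in pop:
        genes = c.genes.copy()
        zeros = np.nonzero(~genes)[0]
        if zeros.size == 0:
            raise ValueError("cannot inherit: chromosome already all-ones")
        genes[rng.choice(zeros)] = True
        out.append(Chromosome(genes, c.gamma_code, c.cost_code))
    return out


def run_ibcga(n: int, cfg: GAConfig, eval_fn: FitnessFn, seed: int | None = None) -> SolutionSet:
    """One full IBCGA run sweeping r = r_start .. r_end with inheritance."""
    run_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    sol = SolutionSet(run_seed=run_seed)
    pop = init_population(n, cfg.r_start, cfg, rng)
    for r in range(cfg.r_start, cfg.r_end + 1):
        trace: list[float] = []
        best, pop = evolve_r(pop, cfg, eval_fn, rng, trace=trace)
        sol.best[r] = best
        sol.fitness_trace[r] = trace
        if r < cfg.r_end:
            pop = inherit(pop, rng)
    return sol


def run_ensemble(
    n: int, cfg: GAConfig, eval_factory: Callable[[int], FitnessFn]
) -> list[SolutionSet]:
    """R independent IBCGA runs with deterministically derived child seeds.

    ``eval_factory(run_index)`` supplies each run's fitness oracle (letting
    callers share or re-draw CV folds per run).
    """
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=cfg.runs)
    return [
        run_ibcga(n, cfg, eval_factory(t), seed=int(seeds[t])) for t in range(cfg.runs)
    ]


# ---------------------------------------------------------------------------
# main-effect ranking


def med_ranking(
    feature_ids: list,
    eval_subset: Callable[[np.ndarray], float],
) -> MEDReport:
    """Rank a solution's m features by main effect difference (MED).

    Each feature is a two-level factor: kept (level 0) or removed (level 1).
    Every OA row's kept-subset is evaluated; MED_j is the absolute difference
    between the mean fitness with feature j kept and with it removed.  Rank 1
    is the largest MED; ties broken by feature id.
    """
    m = len(feature_ids)
    if m < 2:
        raise ValueError("MED ranking needs at least 2 features")
    oa = build_oa(m)
    fits = np.empty(len(oa))
    for i, row in enumerate(oa):
        keep = np.nonzero(row == 0)[0]
        fits[i] = eval_subset(keep) if keep.size else 0.0
    med = np.empty(m)
    for j in range(m):
        med[j] = abs(fits[oa[:, j] == 0].mean() - fits[oa[:, j] == 1].mean())
    order = sorted(range(m), key=lambda j: (-med[j], str(feature_ids[j])))
    ranks = np.empty(m, dtype=int)
    for pos, j in enumerate(order):
        ranks[j] = pos + 1
    return MEDReport(feature_ids=list(feature_ids), med=med, ranks=ranks)


def solution_set_tsv(sol: SolutionSet, accessions: list[str]) -> str:
    """TSV: r, fitness, gamma, cost, selected accessions."""
    lines = ["r\tfitness\tgamma\tcost\tselected"]
    for r in sol.sizes():
        c = sol.best[r]
        sel = ",".join(accessions[i] for i in c.selected())
        p = c.params()
        lines.append(f"{r}\t{c.fitness:.6f}\t{p.gamma:g}\t{p.cost:g}\t{sel}")
    return "\n".join(lines) + "\n"
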