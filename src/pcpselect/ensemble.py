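"""Aggregation and interpretation of repeated feature-selection runs.

A stochastic subset search run twice rarely returns the same feature set, so
the pipeline performs R independent runs and asks which selection is *robust*
rather than merely lucky.  Each run contributes one candidate set (its
best-fitness solution); features are scored by their appearance frequency
f(p) across the R sets, and each run t by the mean frequency of its own
features,

    S_t = (1 / m_t) * sum_{p in set t} f(p),

so a run whose features recur everywhere scores near 1.  The *accurate* pick
S_a is the run with the highest fitness, the *robust* pick S_r the run with
the highest score.  Further reports: per-cluster appearance counts, a
replacement scan for near-duplicate properties that could stand in for a
selected one without hurting accuracy, and a compact one-feature-per-cluster
set found by categorical search.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .aaindex import PropertyTable, zscore_profiles
from .ibcga import GAConfig, SolutionSet, build_oa


@dataclass
class Candidate:
    """One run's contribution: its best feature set and fitness."""

    features: tuple[int, ...]  # indices into the property table
    fitness: float
    r: int
    gamma_code: int = 7
    cost_code: int = 7


@dataclass
class EnsembleReport:
    candidates: list[Candidate]
    appearance_freq: dict[int, float]
    scores: np.ndarray  # S_t per run
    accurate_pick: int  # run index S_a
    robust_pick: int  # run index S_r

    @property
    def runs(self) -> int:
        return len(self.candidates)

    def robust(self) -> Candidate:
        return self.candidates[self.robust_pick]

    def accurate(self) -> Candidate:
        return self.candidates[self.accurate_pick]


def candidate_of_run(sol: SolutionSet) -> Candidate:
    """The run's best X_r by fitness; ties go to the smaller r (parsimony)."""
    if not sol.best:
        raise ValueError("empty solution set")
    best_r = max(sorted(sol.best), key=lambda r: (sol.best[r].fitness, -r))
    c = sol.best[best_r]
    return Candidate(
        features=tuple(int(i) for i in c.selected()),
        fitness=float(c.fitness),
        r=best_r,
        gamma_code=c.gamma_code,
        cost_code=c.cost_code,
    )


def appearance_frequencies(candidates: Sequence[Candidate]) -> dict[int, float]:
    """f(p) = share of the R candidate sets that contain feature p."""
    R = len(candidates)
    freq: dict[int, float] = {}
    for cand in candidates:
        for p in set(cand.features):
            freq[p] = freq.get(p, 0.0) + 1.0
    return {p: c / R for p, c in freq.items()}


def appscore(candidates: Sequence[Candidate]) -> np.ndarray:
    """S_t = mean appearance frequency of the t-th set's features."""
    if not candidates:
        raise ValueError("need at least one candidate set")
    freq = appearance_frequencies(candidates)
    scores = np.empty(len(candidates))
    for t, cand in enumerate(candidates):
        if not cand.features:
            raise ValueError(f"run {t}: empty candidate set")
        scores[t] = np.mean([freq[p] for p in cand.features])
    return scores


def ensemble_report(candidates: Sequence[Candidate]) -> EnsembleReport:
    scores = appscore(candidates)
    fits = np.array([c.fitness for c in candidates])
    return EnsembleReport(
        candidates=list(candidates),
        appearance_freq=appearance_frequencies(candidates),
        scores=scores,
        accurate_pick=int(np.argmax(fits)),  # first index wins ties
        robust_pick=int(np.argmax(scores)),
    )


def cluster_frequency(
    candidates: Sequence[Candidate], cluster_of: Sequence[int]
) -> dict[int, int]:
    """Per cluster, the number of runs whose set touches that cluster."""
    counts: dict[int, int] = {}
    for cand in candidates:
        hit = {int(cluster_of[p]) for p in cand.features}
        for c in hit:
            counts[c] = counts.get(c, 0) + 1
    return counts


@dataclass
class Replacement:
    p1: str  # candidate replacement accession
    p2: str  # selected accession it replaces
    distance: float
    delta_accuracy: float
    promising: bool


def replacement_scan(
    selected: Sequence[int],
    table: PropertyTable,
    eval_features: Callable[[tuple[int, ...]], float],
    d_max: float | None = None,
    acc_drop_max: float = 0.03,
) -> list[Replacement]:
    """Scan for near-duplicate properties that can replace a selected one.

    For every property P1 outside the selected set and every selected P2
    within z-scored Euclidean distance ``d_max`` of it, P2 is swapped for P1
    and the subset re-evaluated; P1 is *promising* when the accuracy drop
    stays within ``acc_drop_max``.  ``d_max`` defaults to the 5th percentile
    of all pairwise distances in the table.
    """
    Z = zscore_profiles(table)
    selected = [int(i) for i in selected]
    sel_set = set(selected)
    baseline = eval_features(tuple(sorted(selected)))
    if d_max is None:
        from scipy.spatial.distance import pdist

        d_max = float(np.percentile(pdist(Z), 5))
    out: list[Replacement] = []
    for p1 in range(table.n):
        if p1 in sel_set:
            continue
        for p2 in selected:
            dist = float(np.linalg.norm(Z[p1] - Z[p2]))
            if dist > d_max:
                continue
            swapped = tuple(sorted(sel_set - {p2} | {p1}))
            delta = baseline - eval_features(swapped)
            out.append(
                Replacement(
                    p1=table[p1].accession,
                    p2=table[p2].accession,
                    distance=dist,
                    delta_accuracy=delta,
                    promising=delta <= acc_drop_max,
                )
            )
    return out


def replacements_tsv(reps: list[Replacement]) -> str:
    lines = ["p1\tp2\tdistance\tdelta_accuracy\tpromising"]
    for r in reps:
        lines.append(
            f"{r.p1}\t{r.p2}\t{r.distance:.6f}\t{r.delta_accuracy:.6f}\t{int(r.promising)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# one feature per cluster (compact set)


def per_cluster_select(
    cluster_ids: Sequence[int],
    table: PropertyTable,
    eval_features: Callable[[tuple[int, ...], int, int], float],
    cfg: GAConfig | None = None,
    exhaustive_limit: int = 64,
) -> tuple[list[int], float, tuple[int, int]]:
    """Pick one property from each listed cluster maximizing fitness.

    The genotype is categorical — one gene per cluster whose levels are the
    cluster's members, plus the two 4-bit SVM parameter genes.  Search spaces
    up to ``exhaustive_limit`` feature combinations are enumerated outright
    (parameter codes held at the defaults); larger spaces use the
    OA-reasoned categorical GA.

    Returns (feature indices, fitness, (gamma_code, cost_code)).
    """
    cfg = cfg or GAConfig(r_start=1, r_end=1, pop_size=20, max_gen=30, stop_idle=5)
    members = []
    for cid in cluster_ids:
        mem = [i for i, rec in enumerate(table) if rec.cluster_id == cid]
        if not mem:
            raise ValueError(f"cluster {cid} has no members")
        members.append(mem)

    space = int(np.prod([len(m) for m in members]))
    if space <= exhaustive_limit:
        best_combo, best_fit = None, -np.inf
        for combo in product(*members):
            fit = eval_features(tuple(combo), 7, 7)
            if fit > best_fit:
                best_combo, best_fit = combo, fit
        return list(best_combo), float(best_fit), (7, 7)
    return _categorical_ga(members, eval_features, cfg)


def _categorical_ga(
    members: list[list[int]],
    eval_features: Callable[[tuple[int, ...], int, int], float],
    cfg: GAConfig,
) -> tuple[list[int], float, tuple[int, int]]:
    """OA-reasoned GA over categorical genes (one member index per cluster)."""
    rng = np.random.default_rng(cfg.seed)
    c = len(members)
    sizes = np.array([len(m) for m in members])

    cache: dict[tuple, float] = {}

    def fitness(geno: np.ndarray, gamma: int, cost: int) -> float:
        feats = tuple(members[i][geno[i]] for i in range(c))
        key = (feats, gamma, cost)
        if key not in cache:
            cache[key] = eval_features(feats, gamma, cost)
        return cache[key]

    pop = [
        (rng.integers(sizes), int(rng.integers(16)), int(rng.integers(16)))
        for _ in range(cfg.pop_size)
    ]
    fits = [fitness(g, ga, co) for g, ga, co in pop]
    best_i = int(np.argmax(fits))
    best = (pop[best_i][0].copy(), pop[best_i][1], pop[best_i][2], fits[best_i])
    oa = build_oa(c + 2)
    idle = 0
    for _ in range(cfg.max_gen):
        new_pop = []
        for _ in range(cfg.pop_size // 2):
            i, j = rng.integers(len(pop)), rng.integers(len(pop))
            a = pop[i] if fits[i] >= fits[j] else pop[j]
            i, j = rng.integers(len(pop)), rng.integers(len(pop))
            b = pop[i] if fits[i] >= fits[j] else pop[j]
            row_fits = []
            rows = []
            for row in oa:
                geno = np.where(row[:c] == 0, a[0], b[0])
                gamma = (b if row[c] else a)[1]
                cost = (b if row[c + 1] else a)[2]
                rows.append((geno, gamma, cost))
                row_fits.append(fitness(geno, gamma, cost))
            # reasoned child from per-factor main effects
            rf = np.array(row_fits)
            lv = [
                0 if rf[oa[:, f] == 0].mean() >= rf[oa[:, f] == 1].mean() else 1
                for f in range(c + 2)
            ]
            geno = np.where(np.array(lv[:c]) == 0, a[0], b[0])
            gamma = (b if lv[c] else a)[1]
            cost = (b if lv[c + 1] else a)[2]
            new_pop.append(rows[int(np.argmax(rf))])
            new_pop.append((geno, gamma, cost))
        # mutation: resample one gene of a few individuals
        for idx in rng.choice(len(new_pop), size=max(1, int(cfg.p_m * len(new_pop))), replace=False):
            geno, gamma, cost = new_pop[idx]
            geno = geno.copy()
            g = int(rng.integers(c))
            geno[g] = int(rng.integers(sizes[g]))
            new_pop[idx] = (geno, gamma, cost)
        pop = new_pop[: cfg.pop_size]
        fits = [fitness(g, ga, co) for g, ga, co in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best[3]:
            best = (pop[gen_best][0].copy(), pop[gen_best][1], pop[gen_best][2], fits[gen_best])
            idle = 0
        else:
            idle += 1
        if idle >= cfg.stop_idle:
            break
    feats = [members[i][best[0][i]] for i in range(c)]
    return feats, float(best[3]), (best[1], best[2])
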