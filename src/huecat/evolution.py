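"""Evolutionary search for category borders using learning speed as fitness.

A genome is a set of 7 circular border positions.  Each candidate is
scored by how *quickly* a probe head learns to classify colors drawn
from two narrow bands placed just inside each border pair: if the
borders align with the representation's categories, each class's two
bands fall inside one category and the short training succeeds; borders
crossing a category boundary force the head to generalize across a
discontinuity and learn slower.  Selection is rank-tiered with elitism,
recombination merges nearby borders across two parents, and a small
mutation keeps exploration alive until it is switched off for the final
generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import HueBand, circular_distance, circular_median
from .probes import TrainConfig, TrainingError, train_probe_head

__all__ = [
    "BorderSet",
    "EvolutionConfig",
    "GenerationRecord",
    "random_border_set",
    "bands_from_borders",
    "ClassBands",
    "OracleFitness",
    "ProbeFitness",
    "select_parent",
    "recombine_parents",
    "mutate_borders",
    "step_generation",
    "run_evolution",
    "EvolutionResult",
    "summarize_replicates",
]


@dataclass(frozen=True)
class BorderSet:
    """An ordered set of circular border positions (the evolution genome)."""

    positions: tuple

    def __post_init__(self):
        pos = tuple(sorted(float(p) % 1.0 for p in self.positions))
        if len(set(pos)) != len(pos):
            raise ValueError("border positions must be pairwise distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_borders(self) -> int:
        return len(self.positions)

    def as_array(self) -> np.ndarray:
        return np.array(self.positions)

    def spans(self) -> np.ndarray:
        """Circular width of each category (border i to border i+1)."""
        p = self.as_array()
        return (np.roll(p, -1) - p) % 1.0


@dataclass(frozen=True)
class EvolutionConfig:
    pop_size: int = 100
    n_elite: int = 10
    n_borders: int = 7
    tier_fractions: tuple = (0.55, 0.30, 0.15)
    merge_threshold: float = 0.05
    mutation_rate: float = 0.025
    mutation_sd: float = 0.025
    n_generations: int = 40
    mutation_off_after: int = 30
    fitness_epochs: int = 3
    n_replicates: int = 12
    min_category_span: float = 0.02
    init_min_separation: float = 0.02

    def __post_init__(self):
        if abs(sum(self.tier_fractions) - 1.0) > 1e-9:
            raise ValueError("tier fractions must sum to 1")
        if self.n_elite >= self.pop_size:
            raise ValueError("n_elite must be smaller than pop_size")

    @property
    def n_offspring(self) -> int:
        return self.pop_size - self.n_elite


@dataclass
class GenerationRecord:
    """Audit snapshot of one generation (ranked best-first)."""

    generation: int
    fitness: np.ndarray
    population: list  # ranked BorderSets

    def best(self) -> tuple:
        return self.population[0], float(self.fitness[0])


def random_border_set(
    rng: np.random.Generator, n_borders: int = 7, min_separation: float = 0.02
) -> BorderSet:
    """I.i.d. uniform borders, redrawn until pairwise separated."""
    for _ in range(1000):
        pos = np.sort(rng.uniform(0, 1, size=n_borders))
        gaps = (np.roll(pos, -1) - pos) % 1.0
        if gaps.min() >= min_separation:
            return BorderSet(tuple(pos))
    raise RuntimeError("could not draw a separated border set")


@dataclass(frozen=True)
class ClassBands:
    """The two training bands of one class, just inside its border pair."""

    left: HueBand
    right: HueBand

    def sample(self, rng: np.random.Generator):
        """Uniform draw from the union of the two (equal-width) bands."""
        band = self.left if rng.random() < 0.5 else self.right
        return band.sample(rng)


def bands_from_borders(
    bs: BorderSet,
    gap_frac: float = 0.05,
    band_frac: float = 0.10,
    min_span: float = 0.02,
) -> list:
    """Per-class band pairs from a border set.

    Each class spans two adjacent borders.  With span ``s``, the left
    band covers ``[left + 0.05 s, left + 0.15 s]`` and the right band
    ``[right - 0.15 s, right - 0.05 s]``: a 5%-of-span gap insulates the
    bands from the borders and each band is 10% of the span wide.
    """
    pos = bs.as_array()
    spans = bs.spans()
    if spans.min() < min_span:
        raise ValueError(
            f"degenerate category: span {spans.min():.4f} below minimum {min_span}"
        )
    out = []
    for i in range(bs.n_borders):
        left, s = pos[i], spans[i]
        hw = band_frac * s / 2.0
        lc = (left + (gap_frac + band_frac / 2.0) * s) % 1.0
        rc = (left + s - (gap_frac + band_frac / 2.0) * s) % 1.0
        out.append(ClassBands(left=HueBand(lc, hw), right=HueBand(rc, hw)))
    return out


class OracleFitness:
    """Analytic learning-speed ceiling against planted categories.

    Models a readout on a perfectly categorical representation: every
    training sample is reduced to the planted category its hue falls in,
    and the best the readout can do is assign each category to the class
    holding the most band mass there.  The fitness is that classifier's
    Bayes accuracy, ``mean_class m[class, cat(class)]`` with the
    category-to-class assignment maximizing total correct mass.  It
    equals 1 exactly when every class's bands lie inside one planted
    category and no two classes share one -- i.e. when the genome
    matches the planted borders (up to the insulation gaps).  Unlike a
    pure per-class purity score, crowding several borders into one
    category is penalized, as it is for the trained-head fitness.
    """

    def __init__(self, planted_borders, min_span: float = 0.02):
        self.planted = np.sort(np.asarray(planted_borders, dtype=float) % 1.0)
        self.min_span = min_span

    @staticmethod
    def _interval_overlap(a0, a1, b0, b1):
        """Overlap length of circular arcs [a0, a1) and [b0, b1), lengths < 1."""
        la = (a1 - a0) % 1.0
        lb = (b1 - b0) % 1.0
        # positions of b relative to a0
        start = (b0 - a0) % 1.0
        total = 0.0
        # the b-arc may wrap relative to a; split at the wrap point
        for s, l in (((start), min(lb, 1.0 - start)), ((0.0), max(0.0, lb - (1.0 - start)))):
            lo = max(0.0, s)
            hi = min(la, s + l)
            total += max(0.0, hi - lo)
        return total

    def class_category_mass(self, bs: BorderSet) -> np.ndarray:
        """``m[class, cat]``: fraction of each class's band mass per category."""
        class_bands = bands_from_borders(bs, min_span=self.min_span)
        planted = self.planted
        n_cat = len(planted)
        m = np.zeros((len(class_bands), n_cat))
        for k, cb in enumerate(class_bands):
            for band in (cb.left, cb.right):
                b0 = (band.center - band.half_width) % 1.0
                b1 = (band.center + band.half_width) % 1.0
                for c in range(n_cat):
                    m[k, c] += self._interval_overlap(
                        planted[c], planted[(c + 1) % n_cat], b0, b1
                    )
            m[k] /= cb.left.width + cb.right.width
        return m

    def __call__(self, bs: BorderSet) -> float:
        try:
            m = self.class_category_mass(bs)
        except ValueError:
            return 0.0
        # each category predicts its majority class; accuracy is the mean
        # correctly-assigned mass over (equally weighted) classes
        return float(m.max(axis=0).sum() / m.shape[0])


class ProbeFitness:
    """Learning-speed fitness: short probe training on the band stimuli.

    The score is the validation accuracy of a probe head trained for
    ``fitness_epochs`` on word stimuli drawn from the genome's band
    pairs.  Each evaluation derives its seed from (run seed, generation,
    member index) for reproducibility.
    """

    def __init__(self, extractor, cfg: EvolutionConfig | None = None,
                 train_cfg: TrainConfig | None = None, seed: int = 0):
        self.extractor = extractor
        self.cfg = cfg or EvolutionConfig()
        self.train_cfg = train_cfg or TrainConfig(
            n_train_per_class=100, n_val_per_class=20, epochs=self.cfg.fitness_epochs
        )
        self.seed = seed
        self.generation = 0

    def __call__(self, bs: BorderSet, member_index: int = 0) -> float:
        try:
            class_bands = bands_from_borders(bs, min_span=self.cfg.min_category_span)
        except ValueError:
            return 0.0
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, self.generation, member_index])
        )

        class _Bands:
            n_classes = bs.n_borders
            bands = class_bands

        try:
            head = train_probe_head(
                self.extractor, _Bands(), self.train_cfg, rng
            )
        except TrainingError:
            return 0.0
        return head.val_accuracy


def select_parent(ranked: list, rng: np.random.Generator,
                  tier_fractions=(0.55, 0.30, 0.15)) -> BorderSet:
    """Rank-tiered parent draw: best/next/third quartile with given odds.

    The bottom quartile never reproduces.  For populations whose size is
    not a multiple of 4 the tiers scale proportionally.
    """
    n = len(ranked)
    q = n // 4
    if q == 0:
        raise ValueError("population too small for quartile selection")
    tier = rng.choice(3, p=tier_fractions)
    lo = tier * q
    return ranked[lo + int(rng.integers(q))]


def _merge_pool(p1: np.ndarray, p2: np.ndarray, threshold: float,
                rng: np.random.Generator) -> list:
    """Greedy closest-first disjoint merging of cross-parent border pairs."""
    a = list(p1)
    b = list(p2)
    merged = []
    while a and b:
        d = np.array([[circular_distance(x, y) for y in b] for x in a])
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= threshold:
            break
        pair = (a.pop(i), b.pop(j))
        w = np.ones(2)
        ang = 2 * np.pi * np.array(pair)
        mean = (np.arctan2((w * np.sin(ang)).sum(), (w * np.cos(ang)).sum())
                / (2 * np.pi)) % 1.0
        merged.append(float(mean))
    return merged + a + b


def recombine_parents(p1: BorderSet, p2: BorderSet, rng: np.random.Generator,
                      merge_threshold: float = 0.05, n_out: int = 7) -> BorderSet:
    """Merge similar borders across the parents, then draw the child.

    Cross-parent border pairs closer than ``merge_threshold`` are
    replaced, closest first, by their circular mean; from the pooled
    borders ``n_out`` distinct positions are drawn uniformly without
    replacement.  If merging leaves fewer than ``n_out`` distinct
    positions, duplicates are jittered minutely.
    """
    pool = _merge_pool(p1.as_array(), p2.as_array(), merge_threshold, rng)
    pool = sorted(pool)
    # deduplicate exactly coincident positions with a minute jitter
    uniq = []
    for p in pool:
        while p in uniq:
            p = (p + 1e-4) % 1.0
        uniq.append(p)
    if len(uniq) < n_out:
        raise RuntimeError("merged pool smaller than the genome size")
    chosen = rng.choice(len(uniq), size=n_out, replace=False)
    return BorderSet(tuple(np.array(uniq)[chosen]))


def mutate_borders(bs: BorderSet, rng: np.random.Generator,
                   rate: float = 0.025, sd: float = 0.025,
                   enabled: bool = True) -> BorderSet:
    """Shift each border, with probability ``rate``, by a wrapped normal step."""
    if not enabled:
        return bs
    pos = bs.as_array()
    hit = rng.random(len(pos)) < rate
    shift = rng.normal(0.0, sd, size=len(pos))
    pos = (pos + hit * shift) % 1.0
    while len(np.unique(pos)) < len(pos):
        pos = np.where(
            np.concatenate(([False], np.diff(np.sort(pos)) == 0))[np.argsort(np.argsort(pos))],
            (pos + 1e-4) % 1.0, pos,
        )
    return BorderSet(tuple(pos))


def step_generation(population: list, fitness: np.ndarray,
                    rng: np.random.Generator, cfg: EvolutionConfig,
                    mutation_enabled: bool = True) -> list:
    """Elites plus freshly recombined (and possibly mutated) offspring."""
    if len(population) != cfg.pop_size:
        raise ValueError("population size mismatch")
    order = np.argsort(-np.asarray(fitness), kind="stable")
    ranked = [population[i] for i in order]
    nxt = ranked[: cfg.n_elite]
    while len(nxt) < cfg.pop_size:
        pa = select_parent(ranked, rng, cfg.tier_fractions)
        pb = select_parent(ranked, rng, cfg.tier_fractions)
        child = recombine_parents(pa, pb, rng, cfg.merge_threshold, cfg.n_borders)
        child = mutate_borders(child, rng, cfg.mutation_rate, cfg.mutation_sd,
                               enabled=mutation_enabled)
        nxt.append(child)
    return nxt


@dataclass
class EvolutionResult:
    population: list  # final population, ranked best-first
    fitness: np.ndarray  # aligned with population
    records: list  # GenerationRecord per generation

    def top(self, k: int = 10) -> list:
        return self.population[:k]


def run_evolution(fitness_fn, cfg: EvolutionConfig | None = None,
                  seed: int = 0) -> EvolutionResult:
    """Full evolutionary run: init, iterate generations, rank, audit.

    ``fitness_fn`` is called as ``fitness_fn(border_set)`` (an optional
    ``member_index`` keyword is passed when accepted, for derived
    seeding).  Mutation is active through generation
    ``cfg.mutation_off_after`` and disabled afterwards.
    """
    cfg = cfg or EvolutionConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEE0]))
    population = [
        random_border_set(rng, cfg.n_borders, cfg.init_min_separation)
        for _ in range(cfg.pop_size)
    ]
    records = []

    def evaluate(pop, generation):
        if hasattr(fitness_fn, "generation"):
            fitness_fn.generation = generation
        out = np.empty(len(pop))
        for i, bs in enumerate(pop):
            try:
                out[i] = fitness_fn(bs, member_index=i)
            except TypeError:
                out[i] = fitness_fn(bs)
        return out

    fitness = evaluate(population, 0)
    for gen in range(cfg.n_generations):
        order = np.argsort(-fitness, kind="stable")
        records.append(GenerationRecord(
            generation=gen,
            fitness=fitness[order].copy(),
            population=[population[i] for i in order],
        ))
        mutation_on = gen < cfg.mutation_off_after
        population = step_generation(population, fitness, rng, cfg,
                                     mutation_enabled=mutation_on)
        new_fitness = np.empty(cfg.pop_size)
        new_fitness[: cfg.n_elite] = records[-1].fitness[: cfg.n_elite]
        tail = evaluate(population[cfg.n_elite :], gen + 1)
        new_fitness[cfg.n_elite :] = tail
        fitness = new_fitness
    order = np.argsort(-fitness, kind="stable")
    records.append(GenerationRecord(
        generation=cfg.n_generations,
        fitness=fitness[order].copy(),
        population=[population[i] for i in order],
    ))
    return EvolutionResult(
        population=[population[i] for i in order],
        fitness=fitness[order],
        records=records,
    )


def summarize_replicates(top_sets: list) -> dict:
    """Pooled per-ordinal circular medians over replicate top solutions.

    ``top_sets`` is a flat list of BorderSets (e.g. 12 replicates x top
    10 = 120 solutions).  Borders are ordered left-to-right from the
    fixed anchor 0; per ordinal position the circular median and a
    dispersion (RMS circular deviation from the median) are returned.
    """
    if not top_sets:
        raise ValueError("no solutions to summarize")
    n = top_sets[0].n_borders
    if any(bs.n_borders != n for bs in top_sets):
        raise ValueError("solutions have unequal border counts")
    mat = np.stack([bs.as_array() for bs in top_sets])  # (S, n) sorted rows
    medians = np.empty(n)
    sds = np.empty(n)
    for j in range(n):
        med = circular_median(mat[:, j])
        medians[j] = med
        sds[j] = float(np.sqrt(np.mean(circular_distance(mat[:, j], med) ** 2)))
    return {"median": medians, "sd": sds, "n_solutions": len(top_sets)}
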