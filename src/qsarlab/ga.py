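"""Genetic-algorithm descriptor selection wrapped around NIPALS PLS.

Each chromosome is a binary mask over descriptor columns.  Fitness is the
leave-one-out Q² of a PLS model built on the masked columns, with the
latent-variable count chosen per chromosome by the Haaland–Thomas rule.
Selection is by tournament, variation by uniform crossover and per-bit
mutation, and elitism guarantees the best fitness is monotone
non-decreasing over generations.  A parsimony tie-break prefers fewer
descriptors when Q² is equal within 1e-6.  Everything is deterministic
under a fixed seed; fitness values are cached per descriptor subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import DescriptorTable
from .exceptions import ConfigError, SpecificationError
from .pls import PLSModel, PLSNipals, loo_q2_pls

Q2_TIE_TOL = 1e-6


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the GA search (all logged into the result)."""

    population: int = 64
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float | None = None   # None → 1/p per bit
    elitism: int = 2
    tournament: int = 3
    min_descriptors: int = 3
    max_descriptors: int = 15
    max_lv: int = 10
    alpha: float = 0.25
    fitness: str = "q2_loo"
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ConfigError("population must be ≥ 2")
        for name in ("crossover_rate",):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ConfigError("mutation_rate must lie in [0, 1]")
        if not (1 <= self.min_descriptors <= self.max_descriptors):
            raise ConfigError("need 1 ≤ min_descriptors ≤ max_descriptors")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ConfigError("elitism must lie in [0, population)")
        if self.fitness != "q2_loo":
            raise ConfigError(f"unknown fitness {self.fitness!r}")


@dataclass
class GAResult:
    best_names: tuple[str, ...]
    best_model: PLSModel
    best_fitness: float
    trajectory: list[float]                       # best fitness per generation
    hall_of_fame: list[tuple[float, tuple[str, ...]]] = field(default_factory=list)
    config: GAConfig | None = None

    def to_dict(self) -> dict:
        return {"best_names": list(self.best_names),
                "best_fitness": self.best_fitness,
                "n_components": self.best_model.n_components,
                "coef": self.best_model.coef.tolist(),
                "intercept": self.best_model.intercept,
                "trajectory": self.trajectory,
                "hall_of_fame": [
                    {"fitness": f, "names": list(nm)}
                    for f, nm in self.hall_of_fame],
                "config": None if self.config is None else vars(self.config)}


def _better(fit_a: float, size_a: int, fit_b: float, size_b: int) -> bool:
    """Is (fit_a, size_a) strictly better?  Parsimony breaks near-ties."""
    if fit_a > fit_b + Q2_TIE_TOL:
        return True
    if fit_b > fit_a + Q2_TIE_TOL:
        return False
    return size_a < size_b


class _Fitness:
    """LOO-Q² fitness with per-subset caching."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: GAConfig):
        self.X, self.y, self.cfg = X, y, cfg
        self.cache: dict[bytes, tuple[float, int]] = {}

    def __call__(self, chrom: np.ndarray) -> tuple[float, int]:
        key = np.packbits(chrom).tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        cols = np.nonzero(chrom)[0]
        q2, n_lv, _ = loo_q2_pls(self.X[:, cols], self.y,
                                 max_lv=min(self.cfg.max_lv, len(cols)),
                                 alpha=self.cfg.alpha)
        self.cache[key] = (q2, n_lv)
        return q2, n_lv


def _repair(chrom: np.ndarray, rng: np.random.Generator, cfg: GAConfig) -> np.ndarray:
    """Force the descriptor count into [min, max] (and never all-zero)."""
    p = len(chrom)
    on = int(chrom.sum())
    if on == 0:
        chrom[rng.integers(p)] = True
        on = 1
    lo, hi = min(cfg.min_descriptors, p), min(cfg.max_descriptors, p)
    if on < lo:
        off = np.nonzero(~chrom)[0]
        chrom[rng.choice(off, size=lo - on, replace=False)] = True
    elif on > hi:
        idx = np.nonzero(chrom)[0]
        chrom[rng.choice(idx, size=on - hi, replace=False)] = False
    return chrom


def ga_select(data: DescriptorTable, cfg: GAConfig = GAConfig()) -> GAResult:
    """Run the GA-PLS descriptor search on a training table."""
    if not data.has_activity:
        raise SpecificationError("GA-PLS needs an activity column")
    names = np.array(data.descriptor_names, dtype=object)
    X = data.values
    y = data.activity.to_numpy()
    p = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / p
    fitness = _Fitness(X, y, cfg)

    def random_chrom():
        k = int(rng.integers(min(cfg.min_descriptors, p),
                             min(cfg.max_descriptors, p) + 1))
        chrom = np.zeros(p, dtype=bool)
        chrom[rng.choice(p, size=k, replace=False)] = True
        return chrom

    pop = [random_chrom() for _ in range(cfg.population)]
    fits = [fitness(c)[0] for c in pop]

    def tournament():
        idx = rng.integers(0, cfg.population, size=cfg.tournament)
        best = idx[0]
        for i in idx[1:]:
            if _better(fits[i], int(pop[i].sum()), fits[best],
                       int(pop[best].sum())):
                best = i
        return pop[best].copy()

    trajectory: list[float] = []
    hall: list[tuple[float, tuple[str, ...]]] = []
    for _ in range(cfg.generations):
        order = sorted(range(cfg.population),
                       key=lambda i: (-fits[i], int(pop[i].sum())))
        elite = [pop[i].copy() for i in order[:cfg.elitism]]
        children = list(elite)
        while len(children) < cfg.population:
            a, b = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(p) < 0.5
                a, b = (np.where(mask, a, b), np.where(mask, b, a))
            for child in (a, b):
                flip = rng.random(p) < mut
                child ^= flip
                children.append(_repair(child, rng, cfg))
                if len(children) == cfg.population:
                    break
        pop = children
        fits = [fitness(c)[0] for c in pop]
        gen_best = max(range(cfg.population),
                       key=lambda i: (fits[i], -int(pop[i].sum())))
        trajectory.append(fits[gen_best])
        hall.append((fits[gen_best],
                     tuple(names[np.nonzero(pop[gen_best])[0]])))

    best_i = max(range(cfg.population),
                 key=lambda i: (fits[i], -int(pop[i].sum())))
    best_cols = np.nonzero(pop[best_i])[0]
    best_names = tuple(names[best_cols])
    _, n_lv = fitness(pop[best_i])
    best_model = PLSNipals(n_components=n_lv, selected=list(best_names)).fit(
        data).model_
    return GAResult(best_names=best_names, best_model=best_model,
                    best_fitness=fits[best_i], trajectory=trajectory,
                    hall_of_fame=hall, config=cfg)


class GAPLS:
    """Estimator facade over :func:`ga_select` (fit/predict interface)."""

    def __init__(self, config: GAConfig = GAConfig()):
        self.config = config

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: DescriptorTable, y=None):
        table = X if y is None else X.with_activity(y)
        self.result_ = ga_select(table, self.config)
        self.selected_ = self.result_.best_names
        self.model_ = self.result_.best_model
        self.n_components_ = self.model_.n_components
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def frozen(self) -> PLSNipals:
        return PLSNipals(n_components=self.n_components_,
                         selected=list(self.selected_))

    def with_seed(self, seed: int) -> "GAPLS":
        return GAPLS(replace(self.config, seed=seed))


def pls_predict(model: PLSModel, candidates: DescriptorTable) -> np.ndarray:
    """Apply a fitted PLS model's affine regression vector to new compounds."""
    return model.predict(candidates)
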