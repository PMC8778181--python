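"""Genetic-algorithm search over the 126 metric weights.

A chromosome is a real vector of 126 genes in [0, 10], laid out as the 59
per-node lambda weights for r, the 59 for phi, the three hierarchy weights
k1..k3 for r, the three for phi, and finally k_r and k_phi.  Fitness is the
cross-validated nearest-prototype classification accuracy under the decoded
metric.  The search is a standard real-coded GA: tournament selection
(size 3), uniform crossover, per-gene Gaussian mutation clipped to bounds,
and one-elite carryover (so the best-so-far fitness never decreases).  The
all-ones chromosome — the plain unweighted metric — is always injected into
generation 0, anchoring the search at the default metric's fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EncodingError
from .lattice_metric import N_GENES, MetricParams
from .pose_prototypes import cross_validate

GENE_LOW, GENE_HIGH = 0.0, 10.0


def decode(genes) -> MetricParams:
    """Map a 126-gene chromosome onto :class:`MetricParams` (bijective)."""
    g = np.asarray(genes, dtype=float)
    if g.shape != (N_GENES,):
        raise EncodingError(f"chromosome must carry {N_GENES} genes, got shape {g.shape}")
    if np.any(g < GENE_LOW) or np.any(g > GENE_HIGH) or not np.all(np.isfinite(g)):
        raise EncodingError(f"genes must lie in [{GENE_LOW}, {GENE_HIGH}]")
    return MetricParams(
        lambda_r=g[0:59],
        lambda_phi=g[59:118],
        k_r123=g[118:121],
        k_phi123=g[121:124],
        k_r=float(g[124]),
        k_phi=float(g[125]),
    )


def encode(params: MetricParams) -> np.ndarray:
    """Inverse of :func:`decode`."""
    return np.concatenate(
        [
            params.lambda_r,
            params.lambda_phi,
            params.k_r123,
            params.k_phi123,
            [params.k_r, params.k_phi],
        ]
    )


@dataclass
class GAConfig:
    """Search settings.  The documented full scale is population 500 for 50
    generations; reduce both for desk-scale experiments."""

    population: int = 500
    generations: int = 50
    folds: int = 10
    seed: int = 0
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_sigma: float = 0.5
    mutation_rate: float = 1.0 / N_GENES
    elite: int = 1

    def __post_init__(self):
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not 0 < self.tournament_size <= self.population:
            raise ConfigurationError("tournament size must be in [1, population]")


def optimize(trees, labels, cfg: GAConfig):
    """Run the GA; returns (best MetricParams, per-generation history).

    History is a list of ``{"generation", "best", "mean"}`` records; the
    ``best`` series is non-decreasing thanks to elitism.  Fully
    deterministic for a given (data, cfg) pair.
    """
    trees = list(trees)
    labels = list(labels)
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def fitness(genes: np.ndarray) -> float:
        key = genes.tobytes()
        if key not in cache:
            cache[key] = cross_validate(trees, labels, decode(genes), folds=cfg.folds, seed=cfg.seed)
        return cache[key]

    pop = rng.uniform(GENE_LOW, GENE_HIGH, size=(cfg.population, N_GENES))
    pop[0] = np.ones(N_GENES)  # anchor at the plain unweighted metric
    fits = np.array([fitness(ind) for ind in pop])

    history = []
    for gen in range(cfg.generations):
        order = np.argsort(-fits, kind="stable")
        elites = pop[order[: cfg.elite]].copy()

        # tournament selection
        draws = rng.integers(0, cfg.population, size=(cfg.population, cfg.tournament_size))
        winners = draws[np.arange(cfg.population), np.argmax(fits[draws], axis=1)]
        mating = pop[winners].copy()

        # uniform crossover on consecutive pairs
        for i in range(0, cfg.population - 1, 2):
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(N_GENES) < 0.5
                a, b = mating[i].copy(), mating[i + 1].copy()
                mating[i][mask], mating[i + 1][mask] = b[mask], a[mask]

        # per-gene Gaussian mutation, clipped to bounds
        mut_mask = rng.random(mating.shape) < cfg.mutation_rate
        noise = rng.normal(0.0, cfg.mutation_sigma, size=mating.shape)
        mating = np.clip(mating + mut_mask * noise, GENE_LOW, GENE_HIGH)

        mating[: cfg.elite] = elites
        pop = mating
        fits = np.array([fitness(ind) for ind in pop])
        history.append(
            {"generation": gen, "best": float(fits.max()), "mean": float(fits.mean())}
        )

    best = pop[int(np.argmax(fits))]
    return decode(best), history
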