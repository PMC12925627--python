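"""Centromere-transition simulations.

A genome carries ``n`` centromeres, each of ancestral type A or new type B.
At every step one centromere is chosen uniformly at random and, regardless
of its current type, set to A with the *retention probability* ``p`` and to
B otherwise.  ``p = 0.5`` is pure drift; ``p < 0.5`` is selection for the
new type.  Single-lineage runs (haploid: 16 centromeres; diploid: 32) track
the final number of B centromeres over many replicates; the exact final
distribution is available from an (n+1)-state Markov-chain oracle.

Population runs hold 100 diploid individuals (16 chromosome pairs).  Each
iteration mutates one random chromatid of one random individual as above
and, when meiosis is enabled, every individual then reassorts every
chromosome: one of its own chromatids is kept (chosen uniformly) and the
other is drawn uniformly, with replacement, from the population-wide pool
of 2N chromatids at that chromosome (synchronous update).  The outcome per
replicate is the number of individuals whose 32 centromeres are all type B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default RNG seed used when a config does not supply one.
DEFAULT_SEED = 715


@dataclass
class SimConfig:
    """Parameters of one simulation experiment."""

    retention_prob: float
    ploidy: str = "haploid"  # haploid | diploid | population
    n_centromeres: int = 16
    steps: int = 1000
    replicates: int = 10_000
    population_size: int = 100
    meiosis: bool = False
    seed: int = DEFAULT_SEED
    #: reproduce the historical integer scheme (draws from 0..999 compared
    #: with round(1000*p)) instead of a real uniform draw
    integer_draws: bool = False
    #: when True the meiosis partner chromatid is drawn from the pool
    #: excluding the focal individual's own two chromatids
    meiosis_exclude_self: bool = False
    #: mutation events per population iteration.  The default (1) mutates a
    #: single chromatid in the whole population per step; at that supply a
    #: 500-step run can introduce at most 500 variant alleles for the 3,200
    #: chromatid slots of the default population, so full individual
    #: transitions are unreachable in either condition.  Contrast experiments
    #: between the meiosis conditions scale this up so the expected number of
    #: hits per chromatid over the run is of order 1.
    mutations_per_step: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention_prob <= 1.0):
            raise ValueError("retention_prob must lie in [0, 1]")
        if self.ploidy not in ("haploid", "diploid", "population"):
            raise ValueError("ploidy must be haploid, diploid or population")
        for name in ("n_centromeres", "steps", "replicates", "population_size",
                     "mutations_per_step"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.ploidy == "population" and self.population_size < 2:
            raise ValueError("population_size must be >= 2")

    @property
    def n_total(self) -> int:
        """Centromeres per individual (chromatid count for diploids)."""
        return self.n_centromeres * (2 if self.ploidy in ("diploid", "population") else 1)


@dataclass
class SimOutcome:
    """Final-state summary over replicates.

    ``final_counts[r]`` is the final number of B centromeres of replicate r
    (lineage runs) or the number of fully transitioned individuals
    (population runs).  ``state_proportions[k]`` is the fraction of
    replicates ending in state k; ``full_transition_proportion`` is the mass
    on the maximal state.
    """

    final_counts: np.ndarray
    n_states: int
    state_proportions: np.ndarray
    full_transition_proportion: float
    config: SimConfig

    @classmethod
    def from_counts(cls, counts: np.ndarray, max_state: int,
                    config: SimConfig) -> "SimOutcome":
        counts = np.asarray(counts, dtype=np.int64)
        props = np.bincount(counts, minlength=max_state + 1) / len(counts)
        return cls(final_counts=counts, n_states=max_state + 1,
                   state_proportions=props,
                   full_transition_proportion=float(props[max_state]),
                   config=config)


def _transition_draw(rng: np.random.Generator, p: float, size,
                     integer_draws: bool) -> np.ndarray:
    """True where the chosen centromere becomes B (i.e. A is *not* retained)."""
    if integer_draws:
        cutoff = int(round(p * 1000))
        return rng.integers(0, 1000, size=size) >= cutoff
    return rng.random(size=size) >= p


def step_lineage(genotype: np.ndarray, p: float, rng: np.random.Generator,
                 integer_draws: bool = False) -> np.ndarray:
    """One mutation step in place: pick one centromere uniformly and set it
    to A with probability ``p``, to B otherwise (0 = A, 1 = B)."""
    idx = int(rng.integers(len(genotype)))
    genotype[idx] = bool(_transition_draw(rng, p, None, integer_draws))
    return genotype


def run_lineage(config: SimConfig) -> SimOutcome:
    """Single-lineage simulation, vectorized across replicates.

    Starts every replicate from the all-A genotype and reports the final
    B-count distribution.  Reproducible from ``config.seed``.
    """
    if config.ploidy == "population":
        raise ValueError("use run_population for population simulations")
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    reps = config.replicates
    state = np.zeros((reps, n), dtype=bool)
    rows = np.arange(reps)
    for _ in range(config.steps):
        idx = rng.integers(0, n, size=reps)
        to_b = _transition_draw(rng, config.retention_prob, reps,
                                config.integer_draws)
        state[rows, idx] = to_b
    return SimOutcome.from_counts(state.sum(axis=1), n, config)


def absorption_times(n: int, p: float, replicates: int, seed: int = DEFAULT_SEED,
                     max_steps: int = 1_000_000,
                     integer_draws: bool = False) -> np.ndarray:
    """Steps until the all-B state is first reached, per replicate.

    Intended for strong selection (small ``p``); at ``p = 0`` the expected
    time is the coupon-collector value ``n * H_n``.  Raises if any replicate
    fails to absorb within ``max_steps``.
    """
    rng = np.random.default_rng(seed)
    state = np.zeros((replicates, n), dtype=bool)
    times = np.zeros(replicates, dtype=np.int64)
    active = np.arange(replicates)
    for step in range(1, max_steps + 1):
        idx = rng.integers(0, n, size=len(active))
        to_b = _transition_draw(rng, p, len(active), integer_draws)
        state[active, idx] = to_b
        done = state[active].all(axis=1)
        if done.any():
            times[active[done]] = step
            active = active[~done]
            if len(active) == 0:
                return times
    raise RuntimeError(f"{len(active)} replicate(s) not absorbed within {max_steps} steps")


def markov_oracle(n: int, p: float, steps: int, start: int = 0) -> np.ndarray:
    """Exact distribution over B-counts after ``steps`` mutation steps.

    From state k (k centromeres of type B): an A centromere is picked with
    probability (n-k)/n and becomes B with probability 1-p; a B centromere
    is picked with probability k/n and becomes A with probability p.
    ``start`` is the initial B-count (0 = the ancestral all-A genotype).
    """
    if n > 64:
        raise ValueError("oracle supports n <= 64")
    if not (0 <= start <= n):
        raise ValueError("start must lie in [0, n]")
    T = np.zeros((n + 1, n + 1), dtype=np.float64)
    for k in range(n + 1):
        up = (n - k) / n * (1.0 - p)
        down = k / n * p
        if k < n:
            T[k, k + 1] = up
        if k > 0:
            T[k, k - 1] = down
        T[k, k] = 1.0 - up - down
    dist = np.zeros(n + 1)
    dist[start] = 1.0
    for _ in range(steps):
        dist = dist @ T
    total = dist.sum()
    assert abs(total - 1.0) < 1e-12
    return dist


def _population_replicate(rng: np.random.Generator, config: SimConfig) -> int:
    N = config.population_size
    nc = config.n_centromeres
    p = config.retention_prob
    state = np.zeros((N, nc, 2), dtype=bool)
    k = config.mutations_per_step
    draws = config.steps * k
    iidx = rng.integers(0, N, size=draws)
    cidx = rng.integers(0, nc, size=draws)
    tidx = rng.integers(0, 2, size=draws)
    to_b = _transition_draw(rng, p, draws, config.integer_draws)
    for s in range(config.steps):
        sl = slice(s * k, (s + 1) * k)
        state[iidx[sl], cidx[sl], tidx[sl]] = to_b[sl]
        if config.meiosis:
            keep = rng.integers(0, 2, size=(N, nc))
            kept = np.take_along_axis(state, keep[:, :, None], axis=2)[:, :, 0]
            pool = state.transpose(1, 0, 2).reshape(nc, 2 * N)
            pick = rng.integers(0, 2 * N, size=(nc, N))
            if config.meiosis_exclude_self:
                own = np.arange(N) * 2  # chromatids 2i, 2i+1 belong to individual i
                bad = (pick == own[None, :]) | (pick == own[None, :] + 1)
                while bad.any():
                    pick[bad] = rng.integers(0, 2 * N, size=int(bad.sum()))
                    bad = (pick == own[None, :]) | (pick == own[None, :] + 1)
            partner = np.take_along_axis(pool, pick, axis=1).T
            state = np.stack([kept, partner], axis=2)
    return int(state.all(axis=(1, 2)).sum())


def run_population(config: SimConfig) -> SimOutcome:
    """Diploid population simulation (with or without meiosis).

    Per replicate: the number of individuals ending with all 2 x n
    centromeres of type B; ``full_transition_proportion`` is the fraction of
    replicates in which the *entire population* fully transitioned.
    """
    if config.ploidy != "population":
        raise ValueError("config.ploidy must be 'population'")
    rng = np.random.default_rng(config.seed)
    counts = np.array([_population_replicate(rng, config)
                       for _ in range(config.replicates)], dtype=np.int64)
    return SimOutcome.from_counts(counts, config.population_size, config)


def genotype_letters(genotype: np.ndarray) -> str:
    """Render a genotype array as an A/B string (display helper)."""
    return "".join("B" if b else "A" for b in np.asarray(genotype).ravel())
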