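"""Forward-time, individual-based simulation of the het-r/het-v system.

The model follows the *Podospora anserina* life cycle in a Wright-Fisher
style population of ``N`` haploid individuals carrying two unlinked
allorecognition loci, *het-r* (alleles ``R``/``r``) and *het-v* (alleles
``V``/``V1``).  Two incompatibility systems are active:

* the **allelic** system — individuals with different *het-v* alleles
  (``V`` vs ``V1``) are vegetatively incompatible and partially sexually
  incompatible;
* the **non-allelic** system — ``R`` interacts with ``V`` carried by a
  different individual, and the ``RV`` combination inside a single
  individual is lethal at germination, so only the genotypes ``rV``,
  ``RV1`` and ``rV1`` are viable.

Vegetative incompatibility grants a rare-allele advantage (negative
frequency-dependent selection, NFDS): a genotype's fitness grows with the
frequency of individuals it is incompatible with.  Sexual incompatibility
is modelled as a prezygotic failure probability per triggered system, and
the lethal ``RV`` offspring class is removed postzygotically.

Reproduction per offspring slot: a mother is drawn with probability
proportional to fitness; with probability ``sigma`` (the selfing rate) the
offspring is the mother's genotype (pseudohomothallic selfing); otherwise
a father is drawn proportionally to fitness and the cross either succeeds
(offspring drawn from the viable segregation distribution) or fails —
prezygotically with probability 1 - prod(1 - iota_sys), or postzygotically
when the zygote is the lethal ``RV`` recombinant — in which case the whole
mating attempt is redrawn, keeping N constant (soft selection).  The
postzygotic failure route is what makes the invader suffer the lethal-
combination cost during outcrossing: an rV x RV1 mating transmits a viable
offspring only 3/4 of the time, so without selfing a rare genotype pays
the cost on almost every mating.  Conditioning on eventual success makes
the per-slot offspring law a fixed categorical distribution over the three
viable genotypes, so a generation is sampled exactly as one multinomial
draw.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HetGenotype",
    "SimParams",
    "PopulationState",
    "SimResult",
    "InvasionModel",
    "VIABLE_GENOTYPES",
    "vegetative_incompatible",
    "nfds_fitness",
    "cross_offspring_distribution",
    "next_generation",
    "run_invasion",
    "parameter_sweep",
    "InvalidGenotypeError",
    "SterilePopulationError",
]

ALLELIC = "allelic"  # V/V1 interaction
NONALLELIC = "nonallelic"  # R/V interaction


class InvalidGenotypeError(ValueError):
    """Raised when a lethal or malformed genotype is used."""


class SterilePopulationError(RuntimeError):
    """Raised when no mating attempt in the population can succeed."""


@dataclass(frozen=True)
class HetGenotype:
    """Haploid two-locus genotype; ``RV`` is lethal and never viable."""

    het_r: str
    het_v: str

    def __post_init__(self) -> None:
        if self.het_r not in ("R", "r"):
            raise InvalidGenotypeError(f"het_r must be 'R' or 'r', got {self.het_r!r}")
        if self.het_v not in ("V", "V1"):
            raise InvalidGenotypeError(f"het_v must be 'V' or 'V1', got {self.het_v!r}")

    @property
    def viable(self) -> bool:
        return not (self.het_r == "R" and self.het_v == "V")

    @property
    def name(self) -> str:
        return self.het_r + self.het_v

    @classmethod
    def from_name(cls, name: str) -> "HetGenotype":
        for r in ("R", "r"):
            for v in ("V", "V1"):
                if r + v == name:
                    return cls(r, v)
        raise InvalidGenotypeError(f"unknown genotype name {name!r}")

    def require_viable(self) -> "HetGenotype":
        if not self.viable:
            raise InvalidGenotypeError("RV is self-incompatible (lethal upon germination)")
        return self


#: The three viable genotypes, in canonical order.
VIABLE_GENOTYPES: tuple[HetGenotype, ...] = (
    HetGenotype("r", "V"),
    HetGenotype("R", "V1"),
    HetGenotype("r", "V1"),
)
GENOTYPE_INDEX: dict[str, int] = {g.name: i for i, g in enumerate(VIABLE_GENOTYPES)}


def vegetative_incompatible(
    g1: HetGenotype, g2: HetGenotype
) -> tuple[bool, frozenset[str]]:
    """Whether two viable individuals are vegetatively incompatible.

    Returns the flag and the set of triggering systems: the allelic
    interaction fires when the *het-v* alleles differ; the non-allelic one
    when one partner carries ``R`` and the other carries ``V``.  Symmetric.
    """
    g1.require_viable()
    g2.require_viable()
    systems = set()
    if g1.het_v != g2.het_v:
        systems.add(ALLELIC)
    if (g1.het_r == "R" and g2.het_v == "V") or (g2.het_r == "R" and g1.het_v == "V"):
        systems.add(NONALLELIC)
    return bool(systems), frozenset(systems)


def _interaction_matrices() -> tuple[np.ndarray, np.ndarray]:
    """0/1 matrices over viable genotypes for each incompatibility system."""
    k = len(VIABLE_GENOTYPES)
    m_all = np.zeros((k, k))
    m_non = np.zeros((k, k))
    for i, gi in enumerate(VIABLE_GENOTYPES):
        for j, gj in enumerate(VIABLE_GENOTYPES):
            _, systems = vegetative_incompatible(gi, gj)
            if ALLELIC in systems:
                m_all[i, j] = 1.0
            if NONALLELIC in systems:
                m_non[i, j] = 1.0
    return m_all, m_non


M_ALLELIC, M_NONALLELIC = _interaction_matrices()


@dataclass(frozen=True)
class SimParams:
    """Parameters of one invasion experiment.

    ``b_nonallelic``/``b_allelic`` are the NFDS intensities of the R/V and
    V/V1 systems; ``prezygotic_nonallelic``/``prezygotic_allelic`` are the
    probabilities that an outcross triggering that system fails before
    zygote formation.
    """

    pop_size: int = 1000
    generations: int = 500
    selfing_rate: float = 0.0
    b_nonallelic: float = 0.5
    b_allelic: float = 0.0
    prezygotic_nonallelic: float = 0.0
    prezygotic_allelic: float = 0.0
    resident: HetGenotype = VIABLE_GENOTYPES[1]  # RV1
    invader: HetGenotype = VIABLE_GENOTYPES[0]  # rV
    invader_fraction: float = 0.05
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "prezygotic_nonallelic", "prezygotic_allelic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.b_nonallelic < 0 or self.b_allelic < 0:
            raise ValueError("balancing-selection intensities must be >= 0")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 < self.invader_fraction < 1.0:
            raise ValueError("invader_fraction must be in (0, 1)")
        self.resident.require_viable()
        self.invader.require_viable()
        if self.resident == self.invader:
            raise ValueError("resident and invader genotypes must differ")


@dataclass
class PopulationState:
    """Counts of the three viable genotypes ``(rV, RV1, rV1)``."""

    counts: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3,) or (self.counts < 0).any():
            raise ValueError("counts must be three non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def nfds_fitness(state: PopulationState, params: SimParams) -> np.ndarray:
    """Fitness of each viable genotype under rare-partner advantage.

    w(g) = 1 + b_nonallelic * x_RV(g) + b_allelic * x_VV1(g), where x_sys(g)
    is the current frequency of individuals incompatible with g under
    system sys.  In a monomorphic population every fitness is 1.
    """
    if state.n == 0:
        raise SterilePopulationError("empty population has no fitness")
    f = state.frequencies
    return (
        1.0
        + params.b_nonallelic * (M_NONALLELIC @ f)
        + params.b_allelic * (M_ALLELIC @ f)
    )


def cross_offspring_distribution(
    mother: HetGenotype, father: HetGenotype, params: SimParams
) -> tuple[float, dict[HetGenotype, float]]:
    """Success probability and viable-offspring law of one mating.

    The loci are unlinked, so each is inherited from either parent with
    probability 1/2; ``RV`` offspring die and the law is renormalized over
    viable genotypes.  A cross triggering prezygotic systems succeeds with
    probability prod(1 - iota_sys); identical parents (a selfing event or
    a within-genotype cross) succeed with probability 1 and reproduce the
    parental genotype.
    """
    mother.require_viable()
    father.require_viable()
    _, systems = vegetative_incompatible(mother, father)
    success = 1.0
    if NONALLELIC in systems:
        success *= 1.0 - params.prezygotic_nonallelic
    if ALLELIC in systems:
        success *= 1.0 - params.prezygotic_allelic
    dist: dict[HetGenotype, float] = {}
    for r_allele in {mother.het_r, father.het_r}:
        p_r = 1.0 if mother.het_r == father.het_r else 0.5
        for v_allele in {mother.het_v, father.het_v}:
            p_v = 1.0 if mother.het_v == father.het_v else 0.5
            child = HetGenotype(r_allele, v_allele)
            if child.viable:
                dist[child] = dist.get(child, 0.0) + p_r * p_v
    total = sum(dist.values())
    if total > 0:
        dist = {g: p / total for g, p in dist.items()}
    return success, dist


def viable_offspring_fraction(mother: HetGenotype, father: HetGenotype) -> float:
    """Probability that a zygote of this cross is not the lethal RV class."""
    p_r = 0.5 if mother.het_r != father.het_r else (1.0 if mother.het_r == "R" else 0.0)
    p_v = 0.5 if mother.het_v != father.het_v else (1.0 if mother.het_v == "V" else 0.0)
    return 1.0 - p_r * p_v


def _cross_tensors(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """(attempt success[m,f], viable offspring law[m,f,o]) over genotypes.

    Attempt success is prezygotic success times the viable zygote
    fraction: a lethal RV zygote aborts the attempt, which is then
    redrawn like any other failed cross.
    """
    k = len(VIABLE_GENOTYPES)
    succ = np.zeros((k, k))
    off = np.zeros((k, k, k))
    for i, m in enumerate(VIABLE_GENOTYPES):
        for j, f in enumerate(VIABLE_GENOTYPES):
            s, dist = cross_offspring_distribution(m, f, params)
            succ[i, j] = s * viable_offspring_fraction(m, f)
            for g, p in dist.items():
                off[i, j, GENOTYPE_INDEX[g.name]] = p
    return succ, off


def _offspring_law(counts: np.ndarray, params: SimParams,
                   succ: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Exact per-offspring-slot genotype law under redraw-on-failure."""
    state = PopulationState(counts)
    w = nfds_fitness(state, params)
    p = counts * w
    p = p / p.sum()
    sigma = params.selfing_rate
    self_part = sigma * p
    pair = p[:, None] * p[None, :] * succ
    cross_part = (1.0 - sigma) * np.einsum("mf,mfo->o", pair, off)
    mass = sigma + (1.0 - sigma) * pair.sum()
    if mass <= 0.0:
        raise SterilePopulationError(
            "no mating attempt can succeed in the current population"
        )
    return (self_part + cross_part) / mass


def next_generation(
    state: PopulationState,
    params: SimParams,
    rng: np.random.Generator,
    _tensors: tuple[np.ndarray, np.ndarray] | None = None,
) -> PopulationState:
    """Sample the next generation of N offspring (soft selection).

    Equivalent to drawing each offspring independently with fitness-
    proportional parents and redrawing failed mating attempts: the per-slot
    law is computed in closed form and N offspring are drawn multinomially,
    so population size is conserved exactly and no ``RV`` individual is
    ever produced.
    """
    succ, off = _tensors if _tensors is not None else _cross_tensors(params)
    q = _offspring_law(state.counts, params, succ, off)
    counts = rng.multinomial(state.n, q)
    return PopulationState(counts, generation=state.generation + 1)


@dataclass
class SimResult:
    """Trajectories and outcomes of a replicated invasion experiment."""

    params: SimParams
    trajectories: np.ndarray  # (replicates, generations + 1, 3) frequencies
    final_frequencies: np.ndarray  # (replicates, 3)
    outcomes: list[str]  # lost | invaded-to-polymorphism | fixed
    seeds: list[int]

    @property
    def genotype_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in VIABLE_GENOTYPES)

    def final_frequency(self, genotype: str) -> np.ndarray:
        return self.final_frequencies[:, GENOTYPE_INDEX[genotype]]

    def outcome_proportions(self) -> dict[str, float]:
        n = len(self.outcomes)
        return {
            label: self.outcomes.count(label) / n
            for label in ("lost", "invaded-to-polymorphism", "fixed")
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(replicate, generation, genotype) frequency table."""
        reps, gens, k = self.trajectories.shape
        rep_idx = np.repeat(np.arange(reps), gens * k)
        gen_idx = np.tile(np.repeat(np.arange(gens), k), reps)
        gt_idx = np.tile(np.arange(k), reps * gens)
        names = np.asarray(self.genotype_names)
        return pd.DataFrame(
            {
                "replicate": rep_idx,
                "generation": gen_idx,
                "genotype": names[gt_idx],
                "frequency": self.trajectories.reshape(-1),
            }
        )


def _initial_counts(params: SimParams) -> np.ndarray:
    n_inv = int(round(params.pop_size * params.invader_fraction))
    n_inv = min(max(n_inv, 1), params.pop_size - 1)
    counts = np.zeros(3, dtype=np.int64)
    counts[GENOTYPE_INDEX[params.invader.name]] = n_inv
    counts[GENOTYPE_INDEX[params.resident.name]] = params.pop_size - n_inv
    return counts


def run_invasion(params: SimParams, record_trajectories: bool = True) -> SimResult:
    """Run the replicated invasion experiment described by ``params``.

    Each replicate starts from ``round(N * f0)`` invaders among residents
    and iterates ``generations`` Wright-Fisher steps.  The outcome label
    classifies the invader's final frequency: 0 -> ``lost``; 1 -> ``fixed``;
    otherwise ``invaded-to-polymorphism``.
    """
    succ, off = _cross_tensors(params)
    inv_idx = GENOTYPE_INDEX[params.invader.name]
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.replicates)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    gens = params.generations
    trajs = (
        np.empty((params.replicates, gens + 1, 3)) if record_trajectories else None
    )
    finals = np.empty((params.replicates, 3))
    outcomes: list[str] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = PopulationState(_initial_counts(params))
        if record_trajectories:
            trajs[r, 0] = state.frequencies
        for g in range(gens):
            if (state.counts > 0).sum() == 1:
                # monomorphic populations are absorbing: stop early
                if record_trajectories:
                    trajs[r, g + 1 :] = state.frequencies
                break
            try:
                state = next_generation(state, params, rng, _tensors=(succ, off))
            except SterilePopulationError as exc:
                raise SterilePopulationError(f"replicate {r}: {exc}") from exc
            if record_trajectories:
                trajs[r, g + 1] = state.frequencies
        freqs = state.frequencies
        finals[r] = freqs
        inv_f = freqs[inv_idx]
        if inv_f == 0.0:
            outcomes.append("lost")
        elif inv_f == 1.0:
            outcomes.append("fixed")
        else:
            outcomes.append("invaded-to-polymorphism")
    if trajs is None:
        trajs = np.empty((params.replicates, 0, 3))
    return SimResult(params, trajs, finals, outcomes, seeds)


class InvasionModel:
    """Model-object wrapper around :func:`run_invasion`.

    ``InvasionModel(**param_overrides).run()`` returns a :class:`SimResult`.
    """

    def __init__(self, params: SimParams | None = None, **overrides):
        base = params if params is not None else SimParams()
        self.params = replace(base, **overrides) if overrides else base

    def run(self, record_trajectories: bool = True) -> SimResult:
        return run_invasion(self.params, record_trajectories=record_trajectories)


def parameter_sweep(
    base: SimParams,
    grid: Mapping[str, Sequence],
    master_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep a parameter grid, 100 replicates per combination by default.

    ``grid`` maps SimParams field names (e.g. ``selfing_rate``,
    ``b_allelic``, ``prezygotic_allelic``, ``invader``) to value lists; the
    non-allelic intensity is typically held fixed in ``base``.  Returns a
    tidy table with one row per (combination, replicate, genotype) and a
    per-combination summary of final-frequency quantiles.  Deterministic
    given the master seed: combination i runs with seed master_seed + i.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    if master_seed is None:
        master_seed = base.seed
    keys = list(grid.keys())
    rows = []
    for i, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        overrides = dict(zip(keys, values))
        params = replace(base, seed=int(master_seed) + i, **overrides)
        result = run_invasion(params, record_trajectories=False)
        for rep in range(params.replicates):
            for gt_i, gt in enumerate(result.genotype_names):
                row = {k: _grid_value(v) for k, v in overrides.items()}
                row.update(
                    replicate=rep,
                    genotype=gt,
                    final_frequency=result.final_frequencies[rep, gt_i],
                )
                rows.append(row)
    tidy = pd.DataFrame(rows)
    summary = (
        tidy.groupby(keys + ["genotype"], sort=False)["final_frequency"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
        .reset_index()
    )
    return tidy, summary


def _grid_value(v):
    return v.name if isinstance(v, HetGenotype) else v
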