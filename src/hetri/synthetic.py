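"""Synthetic inputs for the whole pipeline.

Generates everything the analysis stages consume, with known truth:
neutral coalescent alignments (so the diversity estimators have closed-
form expectations), two-group SNP matrices with a planted divergence
island, negative-binomial coverage tracks with artifact regions, repeat
annotations and block-structured mating-outcome matrices.

The neutral generator emulates a low-diversity, highly selfing fungal
population (genome-wide pi around 5e-4); the two-group generator emulates
a pair of reproductively isolated groups whose differentiation is confined
to one fully diverged island (the het-v region analogue) plus a weaker
secondary island (the het-r region analogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np

from .popgen import VariantMatrix

__all__ = [
    "NeutralSimParams",
    "TwoGroupParams",
    "CoverageModel",
    "generate_neutral_alignment",
    "generate_two_group_snps",
    "generate_coverage",
    "generate_mating_matrix",
]


@dataclass(frozen=True)
class NeutralSimParams:
    """Kingman-coalescent alignment parameters.

    ``theta_per_site`` is the scaled mutation rate, equal to the expected
    per-site heterozygosity: E[pi] = theta and E[S] = theta * L * a_n.
    """

    n_samples: int = 10
    seq_length: int = 1_000_000
    theta_per_site: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be >= 0")


def generate_neutral_alignment(params: NeutralSimParams) -> VariantMatrix:
    """Simulate one neutral locus under the standard coalescent.

    A single Kingman tree (no recombination) with infinite-sites Poisson
    mutations on branches, via msprime with haploid samples, unit
    population size and per-site rate theta/2 so that the pairwise
    coalescence time E[T2] = 1 gives E[pi] = theta exactly.
    """
    chrom = "chr1"
    if params.theta_per_site == 0.0:
        return VariantMatrix(
            samples=[f"s{i}" for i in range(params.n_samples)],
            chrom_lengths={chrom: params.seq_length},
        )
    seed = params.seed % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples=params.n_samples,
        ploidy=1,
        population_size=1.0,
        sequence_length=params.seq_length,
        recombination_rate=0.0,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.theta_per_site / 2.0,
        random_seed=seed,
        discrete_genome=False,
        model=msprime.BinaryMutationModel(),
    )
    positions = []
    rows = []
    last_pos = 0
    for var in mts.variants():
        if len(var.alleles) != 2:
            continue  # drop the rare multi-hit site
        pos = int(np.floor(var.site.position)) + 1
        if pos <= last_pos:
            continue  # collision after flooring; drop (negligible at low theta)
        positions.append(pos)
        last_pos = pos
        rows.append(var.genotypes.astype(np.int8))
    gt = (
        np.vstack(rows)
        if rows
        else np.empty((0, params.n_samples), dtype=np.int8)
    )
    return VariantMatrix(
        samples=[f"s{i}" for i in range(params.n_samples)],
        chrom_lengths={chrom: params.seq_length},
        positions={chrom: np.asarray(positions, dtype=np.int64)},
        genotypes={chrom: gt},
    )


@dataclass(frozen=True)
class TwoGroupParams:
    """Two-group SNP landscape with a planted divergence island.

    Background sites follow the neutral frequency spectrum independently
    of group labels; island sites are fixed differences between groups;
    secondary-island sites are differentiated to approximately
    ``island2_fst_target`` (Hudson Fst in expectation).
    """

    n_per_group: tuple[int, int] = (20, 20)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr2": 400_000, "chr5": 400_000}
    )
    background_diversity: float = 5e-4
    island_chrom: str = "chr5"
    island_span: tuple[int, int] = (150_000, 250_000)
    island_n_sites: int = 150
    island2_chrom: str | None = "chr2"
    island2_span: tuple[int, int] = (180_000, 220_000)
    island2_n_sites: int = 40
    island2_fst_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs at least one sample")
        if not 0.0 <= self.island2_fst_target <= 1.0:
            raise ValueError("island2_fst_target must lie in [0, 1]")
        spans = [(self.island_chrom, self.island_span)]
        if self.island2_chrom is not None:
            spans.append((self.island2_chrom, self.island2_span))
        for chrom, (lo, hi) in spans:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"island chromosome {chrom!r} not in chrom_lengths")
            if not (1 <= lo <= hi <= self.chrom_lengths[chrom]):
                raise ValueError(f"island span {lo}-{hi} outside {chrom}")


def _neutral_background_sites(
    rng: np.random.Generator, length: int, n: int, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """iid neutral sites: S ~ Poisson(theta L a_n), count j w.p. (1/j)/a_n."""
    a_n = np.sum(1.0 / np.arange(1, n))
    s = rng.poisson(theta * length * a_n)
    s = min(s, length)
    if s == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, n), dtype=np.int8)
    pos = np.sort(rng.choice(length, size=s, replace=False)) + 1
    counts = rng.choice(
        np.arange(1, n), size=s, p=(1.0 / np.arange(1, n)) / a_n
    )
    gt = np.zeros((s, n), dtype=np.int8)
    for i, j in enumerate(counts):
        carriers = rng.choice(n, size=j, replace=False)
        gt[i, carriers] = 1
    return pos, gt


def generate_two_group_snps(
    params: TwoGroupParams,
) -> tuple[VariantMatrix, dict[str, str]]:
    """Generate the planted two-group SNP matrix and its truth labels.

    Returns (matrix, labels) with labels in {"rV-group", "RV1-group"}.
    Island sites are fixed ref in group 1 and alt in group 2; the weaker
    island draws group allele frequencies (0.5 +/- delta) with delta
    chosen so the expected Hudson Fst matches ``island2_fst_target``.
    """
    rng = np.random.default_rng(params.seed)
    n1, n2 = params.n_per_group
    n = n1 + n2
    samples = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    labels = {s: ("rV-group" if s.startswith("g1_") else "RV1-group") for s in samples}

    positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    for chrom, length in params.chrom_lengths.items():
        pos, gt = _neutral_background_sites(
            rng, length, n, params.background_diversity
        )
        # The islands model regions of complete (or near-complete) lineage
        # sorting: background polymorphism is excluded from their spans so
        # within-island variation is purely between-group.
        for span_chrom, (lo, hi) in (
            (params.island_chrom, params.island_span),
            (params.island2_chrom or "", params.island2_span),
        ):
            if span_chrom == chrom and pos.size:
                outside = (pos < lo) | (pos > hi)
                pos, gt = pos[outside], gt[outside]
        extra_pos: list[np.ndarray] = []
        extra_gt: list[np.ndarray] = []
        if chrom == params.island_chrom and params.island_n_sites > 0:
            lo, hi = params.island_span
            ipos = np.sort(
                rng.choice(np.arange(lo, hi + 1), size=params.island_n_sites,
                           replace=False)
            )
            igt = np.zeros((params.island_n_sites, n), dtype=np.int8)
            igt[:, n1:] = 1  # fixed difference between groups
            extra_pos.append(ipos)
            extra_gt.append(igt)
        if (
            chrom == params.island2_chrom
            and params.island2_n_sites > 0
            and params.island2_fst_target > 0
        ):
            lo, hi = params.island2_span
            t = params.island2_fst_target
            delta = np.sqrt(t / (8.0 - 4.0 * t)) if t < 1 else 0.5
            ipos = np.sort(
                rng.choice(np.arange(lo, hi + 1), size=params.island2_n_sites,
                           replace=False)
            )
            igt = np.zeros((params.island2_n_sites, n), dtype=np.int8)
            for i in range(params.island2_n_sites):
                p1, p2 = 0.5 + delta, 0.5 - delta
                if rng.random() < 0.5:
                    p1, p2 = p2, p1
                igt[i, :n1] = rng.random(n1) < p1
                igt[i, n1:] = rng.random(n2) < p2
            extra_pos.append(ipos)
            extra_gt.append(igt)
        if extra_pos:
            all_pos = np.concatenate([pos, *extra_pos])
            all_gt = np.concatenate([gt, *extra_gt], axis=0)
            all_pos, unique_idx = np.unique(all_pos, return_index=True)
            order = np.argsort(all_pos)
            pos = all_pos[order]
            gt = all_gt[unique_idx][order]
        positions[chrom] = pos
        genotypes[chrom] = gt
    matrix = VariantMatrix(
        samples=samples,
        chrom_lengths=dict(params.chrom_lengths),
        positions=positions,
        genotypes=genotypes,
    )
    return matrix, labels


@dataclass(frozen=True)
class CoverageModel:
    """Per-site sequencing depth model.

    Depth is negative-binomial with variance mean + dispersion * mean^2
    (``dispersion = 0`` gives constant depth).  ``artifact_regions`` are
    (chrom, start0, end0, multiplier) tuples — 0-based half-open — whose
    mean depth is scaled, emulating collapsed repeats (multiplier > 1) or
    mapping dropouts (< 1).
    """

    mean_depth: float = 80.0
    dispersion: float = 0.1
    artifact_regions: tuple[tuple[str, int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for chrom, start0, end0, mult in self.artifact_regions:
            if start0 < 0 or end0 <= start0 or mult < 0:
                raise ValueError(f"invalid artifact region ({chrom}, {start0}, {end0}, {mult})")


def generate_coverage(
    model: CoverageModel,
    chrom_lengths: dict[str, int],
    samples: Sequence[str],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample, per-chromosome integer depth tracks."""
    rng = np.random.default_rng(model.seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample in samples:
        tracks: dict[str, np.ndarray] = {}
        for chrom, length in chrom_lengths.items():
            mean = np.full(length, float(model.mean_depth))
            for a_chrom, start0, end0, mult in model.artifact_regions:
                if a_chrom == chrom:
                    if end0 > length:
                        raise ValueError(
                            f"artifact region ({start0}, {end0}) outside {chrom}"
                        )
                    mean[start0:end0] *= mult
            if model.dispersion == 0:
                depth = np.round(mean).astype(np.int32)
            else:
                # NB with var = m + disp m^2: shape r = 1/disp, p = r/(r+m)
                r = 1.0 / model.dispersion
                p = r / (r + mean)
                depth = rng.negative_binomial(r, p).astype(np.int32)
            tracks[chrom] = depth
        out[sample] = tracks
    return out


def generate_mating_matrix(
    group_labels: Sequence[str],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Block-structured mating-outcome matrix (codes 1-6).

    Within-group crosses are fully fertile (code 1); between-group crosses
    draw uniformly from the sterile codes 4-6.  A ``noise_rate`` fraction
    of off-diagonal cells is redrawn uniformly from 1-6 (non-symmetric
    noise allowed).  The diagonal is NaN (self crosses are ignored).
    """
    labels = list(group_labels)
    groups = set(labels)
    if len(groups) < 2:
        raise ValueError("need at least two distinct groups")
    counts = {g: labels.count(g) for g in groups}
    if min(counts.values()) < 2:
        raise ValueError("each group needs at least two strains")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(labels)
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    codes = np.where(same, 1, rng.integers(4, 7, size=(n, n))).astype(float)
    if noise_rate > 0:
        flip = rng.random((n, n)) < noise_rate
        codes = np.where(flip, rng.integers(1, 7, size=(n, n)), codes)
    np.fill_diagonal(codes, np.nan)
    return codes
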