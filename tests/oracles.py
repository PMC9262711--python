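"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions (pairwise loops, explicit
enumeration), deliberately ignoring the vectorised implementations it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Diversity estimators (site x sample matrices, haploid 0/1/-1)


def bf_pi_total(gt: np.ndarray) -> float:
    """Sum over sites of the mean pairwise difference."""
    total = 0.0
    for site in gt:
        called = [g for g in site if g != MISSING]
        n = len(called)
        if n < 2:
            continue
        diffs = sum(
            1 for a, b in itertools.combinations(called, 2) if a != b
        )
        total += diffs / (n * (n - 1) / 2)
    return total


def bf_segregating(gt: np.ndarray) -> int:
    s = 0
    for site in gt:
        called = {g for g in site if g != MISSING}
        if len(called) == 2:
            s += 1
    return s


def bf_harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def bf_theta_w_total(gt: np.ndarray) -> float:
    """Sum of 1/a_{n_i} over segregating sites (per-site correction)."""
    total = 0.0
    for site in gt:
        called = [g for g in site if g != MISSING]
        if len(called) >= 2 and len(set(called)) == 2:
            total += 1.0 / bf_harmonic(len(called))
    return total


def bf_tajimas_d(gt: np.ndarray) -> float:
    """Tajima's D for complete haploid data, constants transcribed anew."""
    n = gt.shape[1]
    assert (gt != MISSING).all(), "oracle assumes complete data"
    s = bf_segregating(gt)
    if s == 0:
        return float("nan")
    pi_total = bf_pi_total(gt)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1.0))


def bf_dxy_total(gt: np.ndarray, g1: list[int], g2: list[int]) -> float:
    """Sum over sites of the mean between-group pairwise difference,
    counting only sites where both groups have >= 2 calls."""
    total = 0.0
    for site in gt:
        c1 = [site[i] for i in g1 if site[i] != MISSING]
        c2 = [site[i] for i in g2 if site[i] != MISSING]
        if len(c1) < 2 or len(c2) < 2:
            continue
        diffs = sum(a != b for a in c1 for b in c2)
        total += diffs / (len(c1) * len(c2))
    return total


def bf_hudson_fst(gt: np.ndarray, g1: list[int], g2: list[int]) -> float:
    """1 - sum(Hw)/sum(Hb), Hw the mean of the two within-group per-site
    pairwise differences, summed over sites where both groups have >= 2
    calls."""
    hw_sum = 0.0
    hb_sum = 0.0
    for site in gt:
        c1 = [site[i] for i in g1 if site[i] != MISSING]
        c2 = [site[i] for i in g2 if site[i] != MISSING]
        if len(c1) < 2 or len(c2) < 2:
            continue

        def mean_pairwise(vals):
            pairs = list(itertools.combinations(vals, 2))
            return sum(a != b for a, b in pairs) / len(pairs)

        hw_sum += 0.5 * (mean_pairwise(c1) + mean_pairwise(c2))
        hb_sum += sum(a != b for a in c1 for b in c2) / (len(c1) * len(c2))
    if hb_sum == 0:
        return float("nan")
    return 1.0 - hw_sum / hb_sum


def bf_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on the complete overlap."""
    ok = (np.asarray(x) != MISSING) & (np.asarray(y) != MISSING)
    xs = np.asarray(x)[ok].astype(float)
    ys = np.asarray(y)[ok].astype(float)
    if xs.size < 2 or len(set(xs)) < 2 or len(set(ys)) < 2:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Simulator: exact next-generation per-slot law by enumeration


def bf_offspring_law(
    genotype_names: list[str],
    counts: dict[str, int],
    sigma: float,
    b_nonallelic: float,
    b_allelic: float,
    iota_nonallelic: float,
    iota_allelic: float,
) -> np.ndarray:
    """Enumerate all mating events over individuals.

    Works on genotype name strings ('rV', 'RV1', 'rV1'); treats a lethal
    'RV' zygote as a failed attempt; conditions on eventual success
    (geometric redraw).  Returns the per-slot probability vector over
    ``genotype_names``.
    """

    def alleles(name):
        r = "R" if name.startswith("R") else "r"
        v = "V1" if name.endswith("V1") else "V"
        return r, v

    def incompatible_systems(a, b):
        ra, va = alleles(a)
        rb, vb = alleles(b)
        systems = set()
        if va != vb:
            systems.add("allelic")
        if (ra == "R" and vb == "V") or (rb == "R" and va == "V"):
            systems.add("nonallelic")
        return systems

    individuals = [g for g in genotype_names for _ in range(counts.get(g, 0))]
    freqs = {g: counts.get(g, 0) / len(individuals) for g in genotype_names}
    fitness = {}
    for g in genotype_names:
        x_non = sum(
            freqs[h] for h in genotype_names
            if "nonallelic" in incompatible_systems(g, h)
        )
        x_all = sum(
            freqs[h] for h in genotype_names
            if "allelic" in incompatible_systems(g, h)
        )
        fitness[g] = 1.0 + b_nonallelic * x_non + b_allelic * x_all
    total_w = sum(fitness[g] for g in individuals)

    law = {g: 0.0 for g in genotype_names}
    mass = 0.0
    for mother in individuals:
        p_m = fitness[mother] / total_w
        # selfing branch: always succeeds, clones the parent
        law[mother] += sigma * p_m
        mass += sigma * p_m
        for father in individuals:
            p_f = fitness[father] / total_w
            systems = incompatible_systems(mother, father)
            s_pre = 1.0
            if "nonallelic" in systems:
                s_pre *= 1.0 - iota_nonallelic
            if "allelic" in systems:
                s_pre *= 1.0 - iota_allelic
            rm, vm = alleles(mother)
            rf, vf = alleles(father)
            for r_allele in (rm, rf):
                for v_allele in (vm, vf):
                    child = (
                        ("R" if r_allele == "R" else "r")
                        + ("V1" if v_allele == "V1" else "V")
                    )
                    p_child = 0.25
                    w = (1.0 - sigma) * p_m * p_f * s_pre * p_child
                    if child == "RV":
                        continue  # lethal zygote: attempt fails, no mass
                    law[child] += w
                    mass += w
    return np.array([law[g] / mass for g in genotype_names])
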