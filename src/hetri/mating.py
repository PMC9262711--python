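"""Mating-compatibility coding, Gower dissimilarity, PAM and PCoA.

Pairwise cross outcomes between strains are coded on a six-level scale
(1 = mature fruiting bodies on both partners ... 6 = no perithecia on
either), giving a possibly non-symmetric strains x strains matrix.  Each
strain's row of codes is treated as an observation vector; Gower's
range-normalised dissimilarity turns it into a symmetric matrix that is
clustered with partitioning around medoids (PAM).  The cluster count is
chosen by maximum average silhouette width (with the Gap statistic as a
second diagnostic) and the configuration is embedded by classical scaling
(PCoA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "OUTCOME_CATEGORIES",
    "code_matings",
    "gower_dissimilarity",
    "ClusterSolution",
    "pam_cluster",
    "choose_k",
    "PCoAEmbedding",
    "pcoa",
    "concordance",
]

#: Per-direction observation categories of one cross.
OUTCOME_CATEGORIES = ("mature", "perithecial_abortion", "none")

# (sorted category pair) -> code
_CODE_TABLE = {
    ("mature", "mature"): 1,
    ("mature", "perithecial_abortion"): 2,
    ("mature", "none"): 3,
    ("perithecial_abortion", "perithecial_abortion"): 4,
    ("perithecial_abortion", "none"): 5,
    ("none", "none"): 6,
}


def code_matings(observations: pd.DataFrame) -> pd.DataFrame:
    """Code raw cross observations into the 1-6 outcome matrix.

    ``observations`` has columns strain_a, strain_b, outcome_a, outcome_b,
    where outcome_x is the per-partner result in
    :data:`OUTCOME_CATEGORIES`: both mature -> 1; mature + perithecial
    abortion -> 2; mature + none -> 3; both abortion -> 4; abortion +
    none -> 5; both none -> 6.  Returns a strains x strains DataFrame with
    NaN for unobserved cells and the diagonal.
    """
    bad = observations[
        ~observations["outcome_a"].isin(OUTCOME_CATEGORIES)
        | ~observations["outcome_b"].isin(OUTCOME_CATEGORIES)
    ]
    if len(bad):
        cells = ", ".join(
            f"({r.strain_a}, {r.strain_b})" for r in bad.itertuples()
        )
        raise ValueError(f"unrecognized observation categories in cells: {cells}")
    strains = sorted(
        set(observations["strain_a"]) | set(observations["strain_b"])
    )
    mat = pd.DataFrame(np.nan, index=strains, columns=strains)
    for row in observations.itertuples():
        key = tuple(
            sorted((row.outcome_a, row.outcome_b), key=OUTCOME_CATEGORIES.index)
        )
        mat.loc[row.strain_a, row.strain_b] = _CODE_TABLE[key]
    return mat


def gower_dissimilarity(
    matrix: pd.DataFrame | np.ndarray,
    symmetrize: bool = False,
    ordinal: bool = False,
    max_missing: float = 0.5,
) -> pd.DataFrame:
    """Gower dissimilarity between strains (rows as observations).

    Each strain's variables are its outcome codes against every partner;
    codes are treated as interval-scaled by default (range-normalised
    absolute differences, the numeric-column behaviour of the usual
    routine), or rank-transformed when ``ordinal``.  Missing variables are
    excluded pairwise; strains missing more than ``max_missing`` of their
    cells are dropped with a warning.  ``symmetrize`` first replaces the
    code matrix by the mean of itself and its transpose.
    """
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(
            matrix,
            index=[f"s{i}" for i in range(matrix.shape[0])],
            columns=[f"s{i}" for i in range(matrix.shape[0])],
        )
    x = matrix.to_numpy(dtype=float).copy()
    if x.shape[0] == x.shape[1]:
        np.fill_diagonal(x, np.nan)  # self crosses carry no information
    if symmetrize:
        x = np.where(
            np.isnan(x), x.T, np.where(np.isnan(x.T), x, 0.5 * (x + x.T))
        )
    names = list(matrix.index)
    frac_missing = np.isnan(x).mean(axis=1)
    keep = frac_missing <= max_missing
    if not keep.all():
        import warnings

        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping strains with > {max_missing:.0%} missing cells: {dropped}")
        x = x[keep][:, keep]
        names = [n for n, k in zip(names, keep) if k]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two strains")
    if ordinal:
        for jcol in range(x.shape[1]):
            col = x[:, jcol]
            ok = ~np.isnan(col)
            ranks = pd.Series(col[ok]).rank().to_numpy()
            col[ok] = ranks
    col_min = np.nanmin(x, axis=0)
    col_max = np.nanmax(x, axis=0)
    rng = col_max - col_min
    valid_var = rng > 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(x[i]) & ~np.isnan(x[j]) & valid_var
            if not shared.any():
                # fall back to shared variables even if zero-range
                shared_any = ~np.isnan(x[i]) & ~np.isnan(x[j])
                if not shared_any.any():
                    raise ValueError(
                        f"strains {names[i]!r} and {names[j]!r} share no observed variables"
                    )
                d[i, j] = d[j, i] = 0.0
                continue
            diffs = np.abs(x[i, shared] - x[j, shared]) / rng[shared]
            d[i, j] = d[j, i] = float(diffs.mean())
    return pd.DataFrame(d, index=names, columns=names)


@dataclass
class ClusterSolution:
    """One PAM solution plus the model-selection diagnostics."""

    k: int
    medoids: list[int]
    labels: np.ndarray
    cost: float
    silhouette: float | None = None
    gap: float | None = None


def _pam_cost(d: np.ndarray, medoids: Sequence[int]) -> tuple[float, np.ndarray]:
    sub = d[:, list(medoids)]
    assign = np.argmin(sub, axis=1)
    return float(sub[np.arange(d.shape[0]), assign].sum()), assign


def pam_cluster(dissimilarity: pd.DataFrame | np.ndarray, k: int) -> ClusterSolution:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Deterministic: ties between candidate medoids break toward the lowest
    index.  The returned medoid set is locally optimal (no single swap
    lowers the total dissimilarity-to-medoid cost).
    """
    d = (
        dissimilarity.to_numpy(dtype=float)
        if isinstance(dissimilarity, pd.DataFrame)
        else np.asarray(dissimilarity, dtype=float)
    )
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n ({n})")

    # BUILD: first medoid minimises total dissimilarity; then greedy adds.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best_cost, best_cand = np.inf, None
        current = np.min(d[:, medoids], axis=1)
        for cand in range(n):
            if cand in medoids:
                continue
            cost = float(np.minimum(current, d[:, cand]).sum())
            if cost < best_cost - 1e-15:
                best_cost, best_cand = cost, cand
        medoids.append(best_cand)
    cost, assign = _pam_cost(d, medoids)

    # SWAP: apply the best improving (medoid, candidate) swap until none.
    improved = True
    while improved:
        improved = False
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                trial_cost, _ = _pam_cost(d, trial)
                if trial_cost < best[0] - 1e-12:
                    best = (trial_cost, mi, cand)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost, assign = _pam_cost(d, medoids)
            improved = True
    order = np.argsort(medoids)
    medoids = [medoids[i] for i in order]
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[a] for a in assign]) + 1  # labels 1..k
    cost, _ = _pam_cost(d, medoids)
    return ClusterSolution(k=k, medoids=medoids, labels=labels, cost=cost)


def _within_dispersion(d2: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani W_k = sum_r sum_{i,i' in C_r} d_{ii'} / (2 n_r)."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size:
            w += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return w


def choose_k(
    dissimilarity: pd.DataFrame,
    coded_matrix: pd.DataFrame | np.ndarray | None = None,
    k_max: int = 6,
    b_ref: int = 100,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by silhouette, with Gap as a second rule.

    Silhouette: k in 2..k_max maximising the average silhouette width of
    the PAM solution on ``dissimilarity`` (authoritative).  Gap: Tibshirani
    statistic on the coded observation matrix (PAM on Euclidean distances)
    with ``b_ref`` uniform reference sets over per-variable ranges and the
    one-standard-error rule; reported alongside (k = 1 allowed there).
    Returns (chosen k, diagnostics DataFrame with silhouette and gap per k).
    """
    n = len(dissimilarity)
    if n < 4:
        raise ValueError("need at least four strains to choose k")
    k_max = min(k_max, n - 1)
    d = dissimilarity.to_numpy(dtype=float)

    sil: dict[int, float] = {}
    for k in range(2, k_max + 1):
        sol = pam_cluster(dissimilarity, k)
        sil[k] = float(silhouette_score(d, sol.labels, metric="precomputed"))
    k_sil = max(sil, key=lambda k: (sil[k], -k))

    gap_table: dict[int, tuple[float, float]] = {}
    k_gap = None
    if coded_matrix is not None:
        x = (
            coded_matrix.to_numpy(dtype=float)
            if isinstance(coded_matrix, pd.DataFrame)
            else np.asarray(coded_matrix, dtype=float)
        ).copy()
        if x.shape[0] == x.shape[1]:
            np.fill_diagonal(x, np.nan)
        col_mean = np.nanmean(x, axis=0)
        inds = np.where(np.isnan(x))
        x[inds] = np.take(col_mean, inds[1])
        rng = np.random.default_rng(seed)
        lo, hi = x.min(axis=0), x.max(axis=0)

        def log_wk(data: np.ndarray, k: int) -> float:
            dist = np.sqrt(
                np.maximum(
                    ((data[:, None, :] - data[None, :, :]) ** 2).sum(-1), 0.0
                )
            )
            if k == 1:
                labels = np.ones(data.shape[0], dtype=int)
            else:
                labels = pam_cluster(dist, k).labels
            return float(np.log(_within_dispersion(dist, labels) + 1e-300))

        for k in range(1, k_max + 1):
            obs = log_wk(x, k)
            refs = np.array(
                [
                    log_wk(rng.uniform(lo, hi, size=x.shape), k)
                    for _ in range(b_ref)
                ]
            )
            gap = float(refs.mean() - obs)
            s_k = float(refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / b_ref))
            gap_table[k] = (gap, s_k)
        for k in range(1, k_max):
            if gap_table[k][0] >= gap_table[k + 1][0] - gap_table[k + 1][1]:
                k_gap = k
                break
        if k_gap is None:
            k_gap = k_max

    diag = pd.DataFrame(
        {
            "k": list(range(1, k_max + 1)),
            "silhouette": [sil.get(k, np.nan) for k in range(1, k_max + 1)],
            "gap": [gap_table.get(k, (np.nan, np.nan))[0] for k in range(1, k_max + 1)],
            "gap_se": [gap_table.get(k, (np.nan, np.nan))[1] for k in range(1, k_max + 1)],
        }
    )
    diag.attrs["k_silhouette"] = k_sil
    diag.attrs["k_gap"] = k_gap
    return k_sil, diag


@dataclass
class PCoAEmbedding:
    """Classical-scaling embedding on positive-eigenvalue axes."""

    coordinates: pd.DataFrame  # strains x axes
    eigenvalues: np.ndarray  # positive eigenvalues, decreasing
    variance_fractions: np.ndarray
    n_negative: int


def pcoa(dissimilarity: pd.DataFrame, n_axes: int | None = None) -> PCoAEmbedding:
    """Principal coordinates analysis (classical multidimensional scaling).

    Double-centres -0.5 * J D^2 J, eigendecomposes, and scales the
    eigenvectors by sqrt of the positive eigenvalues; negative eigenvalues
    (non-Euclidean input) are dropped and counted.  Requires a symmetric
    zero-diagonal matrix.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric (use gower_dissimilarity first)")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    n_negative = int((evals < -1e-10 * max(abs(evals).max(), 1.0)).sum())
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        evals_pos = evals_pos[:n_axes]
    varfrac = (
        evals_pos / evals[pos].sum() if pos.any() else np.zeros(0)
    )
    cols = [f"Axis{i + 1}" for i in range(coords.shape[1])]
    return PCoAEmbedding(
        coordinates=pd.DataFrame(coords, index=dissimilarity.index, columns=cols),
        eigenvalues=evals_pos,
        variance_fractions=varfrac[: coords.shape[1]],
        n_negative=n_negative,
    )


def concordance(
    cluster_labels: Mapping[str, int | str],
    genotype_labels: Mapping[str, str],
) -> tuple[pd.DataFrame, float]:
    """Agreement between mating clusters and genotype-derived RI groups.

    Builds the confusion matrix over the shared samples with rows permuted
    to maximise the diagonal, and reports the adjusted Rand index as the
    chance-corrected agreement.
    """
    shared = sorted(set(cluster_labels) & set(genotype_labels))
    if not shared:
        raise ValueError("no samples shared between the two labelings")
    a = pd.Categorical([str(cluster_labels[s]) for s in shared])
    b = pd.Categorical([str(genotype_labels[s]) for s in shared])
    table = pd.crosstab(
        pd.Series(a, name="cluster"), pd.Series(b, name="genotype")
    )
    # permute cluster rows to maximise the diagonal
    cost = -table.to_numpy()
    if table.shape[0] <= table.shape[1]:
        rows, cols = linear_sum_assignment(cost)
        order = list(rows[np.argsort(cols)])
        order += [i for i in range(table.shape[0]) if i not in order]
        table = table.iloc[order[: table.shape[0]]]
    ari = float(adjusted_rand_score(b.codes, a.codes))
    return table, ari
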