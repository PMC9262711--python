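"""Windowed diversity and differentiation scan over haploid SNP matrices.

Implements the sliding-window statistics used to detect the differentiated
island separating the two reproductively isolated (RI) groups: per-window
nucleotide diversity (pi), Watterson's theta, Tajima's D, Hudson-type Fst
and Dxy, all corrected for callable window length; a per-sample
coverage-quantile masking rule; an Fst permutation null; and SNP PCA with
RI-group assignment from PC1.

Coordinates: VCF/variant positions are 1-based; windows are 1-based
inclusive ``[start, start + length - 1]``; BED-style inputs are 0-based
half-open and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # missing haploid call in genotype matrices

__all__ = [
    "VariantMatrix",
    "CallabilityMask",
    "WindowSpec",
    "GroupAssignment",
    "harmonic_number",
    "mask_sites",
    "pi_window",
    "theta_w_window",
    "tajimas_d_window",
    "fst_dxy_window",
    "window_scan",
    "fst_permutation_null",
    "pca_snps",
    "assign_ri_from_pc1",
]


@dataclass
class VariantMatrix:
    """Biallelic haploid site-by-sample matrix, one block per chromosome.

    ``genotypes[chrom]`` has shape (n_sites, n_samples) with entries
    0 (ref), 1 (alt) or -1 (missing); ``positions[chrom]`` is the matching
    1-based, strictly increasing position vector.
    """

    samples: list[str]
    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    ref: dict[str, np.ndarray] = field(default_factory=dict)
    alt: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chrom_lengths:
            pos = np.asarray(self.positions.get(chrom, np.empty(0, dtype=np.int64)))
            gt = np.asarray(
                self.genotypes.get(
                    chrom, np.empty((0, len(self.samples)), dtype=np.int8)
                )
            )
            if pos.size and not (np.diff(pos) > 0).all():
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if gt.shape != (pos.size, len(self.samples)):
                raise ValueError(f"{chrom}: genotype shape does not match positions")
            self.positions[chrom] = pos.astype(np.int64)
            self.genotypes[chrom] = gt.astype(np.int8)
            if chrom not in self.ref:
                self.ref[chrom] = np.full(pos.size, "A", dtype="U1")
            if chrom not in self.alt:
                self.alt[chrom] = np.full(pos.size, "T", dtype="U1")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(p.size for p in self.positions.values()))

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with start <= pos <= end (1-based inclusive)."""
        pos = self.positions[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return np.arange(lo, hi)


@dataclass
class CallabilityMask:
    """Per-chromosome boolean usable flags (True = callable site).

    Masked positions are excluded from the effective window length and
    their variant calls are treated as missing.
    """

    usable: dict[str, np.ndarray]

    @classmethod
    def all_usable(cls, chrom_lengths: Mapping[str, int]) -> "CallabilityMask":
        return cls({c: np.ones(l, dtype=bool) for c, l in chrom_lengths.items()})

    @classmethod
    def from_intervals(
        cls,
        chrom_lengths: Mapping[str, int],
        masked_bed: Mapping[str, Iterable[tuple[int, int]]],
    ) -> "CallabilityMask":
        """Build from 0-based half-open masked intervals (BED convention)."""
        usable = {c: np.ones(l, dtype=bool) for c, l in chrom_lengths.items()}
        for chrom, intervals in masked_bed.items():
            if chrom not in usable:
                continue
            length = chrom_lengths[chrom]
            for start0, end0 in intervals:
                if start0 < 0 or end0 > length or start0 > end0:
                    raise ValueError(
                        f"interval ({start0}, {end0}) outside {chrom} of length {length}"
                    )
                usable[chrom][start0:end0] = False
        return cls(usable)

    def to_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Masked intervals as 0-based half-open (BED) tuples."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, flags in self.usable.items():
            bad = ~flags
            edges = np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0]))
            out[chrom] = [
                (int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)
            ]
        return out

    def effective_length(self, chrom: str, start: int, end: int) -> int:
        """Callable bp in the 1-based inclusive window [start, end]."""
        flags = self.usable[chrom]
        end = min(end, flags.size)
        if start > end:
            return 0
        return int(flags[start - 1 : end].sum())

    def usable_sites(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        flags = self.usable[chrom]
        return flags[np.asarray(positions) - 1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (defaults: 10 kb windows, 1 kb steps)."""

    length: int = 10_000
    step: int = 1_000
    min_effective: int = 5_000

    def __post_init__(self) -> None:
        if self.step > self.length:
            raise ValueError("step must be <= window length")
        if self.min_effective > self.length:
            raise ValueError("min_effective must be <= window length")

    def starts(self, chrom_length: int) -> np.ndarray:
        return np.arange(1, chrom_length + 1, self.step)


@dataclass
class GroupAssignment:
    """Sample -> RI group label, with a provenance record."""

    labels: dict[str, str]
    provenance: str = "unspecified"

    GROUPS = ("rV-group", "RV1-group")
    UNASSIGNED = "unassigned"

    def indices(self, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        g1 = np.array(
            [i for i, s in enumerate(samples) if self.labels.get(s) == self.GROUPS[0]]
        )
        g2 = np.array(
            [i for i, s in enumerate(samples) if self.labels.get(s) == self.GROUPS[1]]
        )
        return g1, g2


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's denominator)."""
    return float(np.sum(1.0 / np.arange(1, n)))


# ---------------------------------------------------------------------------
# Coverage-quantile masking


def mask_sites(
    coverage: Mapping[str, Mapping[str, np.ndarray]],
    repeats: Mapping[str, Iterable[tuple[int, int]]],
    chrom_lengths: Mapping[str, int],
    low_q: float = 0.25,
    high_q: float = 0.985,
) -> CallabilityMask:
    """Coverage/repeat masking rule.

    Per sample, the genome-wide depth distribution defines 'bad' sites as
    those with depth strictly below its ``low_q`` quantile or strictly
    above its ``high_q`` quantile (empirical type-7 quantiles; strict
    inequalities, so constant coverage flags nothing).  The final mask is
    the intersection of bad-in-every-sample sites with the repeat
    annotation (0-based half-open intervals).
    """
    if not coverage:
        raise ValueError("coverage must contain at least one sample")
    if not (0.0 < low_q < 1.0 and 0.0 < high_q < 1.0):
        raise ValueError("quantiles must lie in (0, 1)")

    bad_all = {c: np.ones(l, dtype=bool) for c, l in chrom_lengths.items()}
    for sample, tracks in coverage.items():
        depths = np.concatenate(
            [np.asarray(tracks[c], dtype=float) for c in chrom_lengths]
        )
        lo = np.quantile(depths, low_q)
        hi = np.quantile(depths, high_q)
        for chrom in chrom_lengths:
            d = np.asarray(tracks[chrom], dtype=float)
            bad_all[chrom] &= (d < lo) | (d > hi)

    repeat_flags = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for chrom, intervals in repeats.items():
        if chrom not in repeat_flags:
            continue
        for start0, end0 in intervals:
            repeat_flags[chrom][start0:end0] = True

    usable = {
        c: ~(bad_all[c] & repeat_flags[c]) for c in chrom_lengths
    }
    return CallabilityMask(usable)


# ---------------------------------------------------------------------------
# Per-window estimators


def _window_site_data(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    chrom: str,
    start: int,
    end: int,
) -> tuple[np.ndarray, int]:
    """(genotypes at usable sites in window, effective length)."""
    idx = matrix.sites_in(chrom, start, end)
    if idx.size:
        keep = mask.usable_sites(chrom, matrix.positions[chrom][idx])
        idx = idx[keep]
    l_eff = mask.effective_length(chrom, start, end)
    return matrix.genotypes[chrom][idx], l_eff


def _site_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (non-missing calls n, alt count j); n<2 sites are dropped."""
    called = gt != MISSING
    n = called.sum(axis=1)
    j = np.where(called, gt, 0).sum(axis=1)
    ok = n >= 2
    if (~ok).any():
        logger.debug("skipping %d sites with < 2 calls", int((~ok).sum()))
    return n[ok], j[ok]


def pi_window(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    chrom: str,
    start: int,
    end: int,
    min_effective: int = 0,
) -> float:
    """Per-site nucleotide diversity over the callable window length.

    pi = sum_i 2 j_i (n_i - j_i) / (n_i (n_i - 1)) / L_eff over usable
    sites; windows shorter than ``min_effective`` callable bp are missing
    (NaN).
    """
    gt, l_eff = _window_site_data(matrix, mask, chrom, start, end)
    if l_eff < max(min_effective, 1):
        return float("nan")
    n, j = _site_counts(gt)
    total = np.sum(2.0 * j * (n - j) / (n * (n - 1.0)))
    return float(total / l_eff)


def theta_w_window(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    chrom: str,
    start: int,
    end: int,
    min_effective: int = 0,
) -> float:
    """Watterson's theta per site: S / (a_n * L_eff).

    With missing data the harmonic correction is applied per segregating
    site (sum of 1/a_{n_i}), which reduces to S/(a_n L_eff) for complete
    calls.
    """
    gt, l_eff = _window_site_data(matrix, mask, chrom, start, end)
    if l_eff < max(min_effective, 1):
        return float("nan")
    n, j = _site_counts(gt)
    seg = (j > 0) & (j < n)
    if not seg.any():
        return 0.0
    a = np.array([harmonic_number(int(ni)) for ni in n[seg]])
    return float(np.sum(1.0 / a) / l_eff)


def _tajima_constants(n: int) -> tuple[float, float]:
    """Tajima (1989) normalising constants e1, e2 for sample size n."""
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d_window(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    chrom: str,
    start: int,
    end: int,
) -> float:
    """Tajima's D: (pi_total - S/a_n) / sqrt(e1 S + e2 S (S-1)).

    Returns NaN (missing, not zero) when the window has no segregating
    sites.  The constants use the median per-site call count, which is the
    sample size for complete data.
    """
    gt, l_eff = _window_site_data(matrix, mask, chrom, start, end)
    if l_eff < 1 or gt.shape[0] == 0:
        return float("nan")
    n, j = _site_counts(gt)
    seg = (j > 0) & (j < n)
    s = int(seg.sum())
    if s == 0:
        logger.debug("window %s:%d-%d has S=0; Tajima's D missing", chrom, start, end)
        return float("nan")
    n_eff = int(np.median(n[seg]))
    pi_total = float(np.sum(2.0 * j * (n - j) / (n * (n - 1.0))))
    e1, e2 = _tajima_constants(n_eff)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi_total - s / harmonic_number(n_eff)) / np.sqrt(var))


def _hudson_site_components(
    gt: np.ndarray, g1: np.ndarray, g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (mean within-group het Hw, between-group het Hb).

    Hw is the unbiased mean pairwise difference within each group (the
    per-site pi), averaged over the two groups; Hb = p1(1-p2) + p2(1-p1)
    is the per-site Dxy.  Sites where either group has < 2 calls get NaN.
    """
    out_w = np.full(gt.shape[0], np.nan)
    out_b = np.full(gt.shape[0], np.nan)
    sub1, sub2 = gt[:, g1], gt[:, g2]
    n1 = (sub1 != MISSING).sum(axis=1)
    n2 = (sub2 != MISSING).sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    j1 = np.where(sub1 != MISSING, sub1, 0).sum(axis=1)[ok]
    j2 = np.where(sub2 != MISSING, sub2, 0).sum(axis=1)[ok]
    m1, m2 = n1[ok].astype(float), n2[ok].astype(float)
    h1 = 2.0 * j1 * (m1 - j1) / (m1 * (m1 - 1.0))
    h2 = 2.0 * j2 * (m2 - j2) / (m2 * (m2 - 1.0))
    p1, p2 = j1 / m1, j2 / m2
    out_w[ok] = 0.5 * (h1 + h2)
    out_b[ok] = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return out_w, out_b


def fst_dxy_window(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    chrom: str,
    start: int,
    end: int,
    groups: GroupAssignment,
    min_effective: int = 0,
) -> tuple[float, float]:
    """Hudson-type window Fst (ratio of averages) and per-site Dxy.

    Fst = 1 - sum(Hw) / sum(Hb) over usable sites with >= 2 calls in each
    group; Dxy = sum(Hb) / L_eff.  Fst is NaN when no between-group
    heterozygosity is observed.
    """
    g1, g2 = groups.indices(matrix.samples)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both RI groups must contain samples present in the matrix")
    gt, l_eff = _window_site_data(matrix, mask, chrom, start, end)
    if l_eff < max(min_effective, 1):
        return float("nan"), float("nan")
    hw, hb = _hudson_site_components(gt, g1, g2)
    hw_sum = np.nansum(hw)
    hb_sum = np.nansum(hb)
    dxy = float(hb_sum / l_eff)
    fst = float("nan") if hb_sum == 0 else float(1.0 - hw_sum / hb_sum)
    return fst, dxy


def window_scan(
    matrix: VariantMatrix,
    mask: CallabilityMask | None = None,
    spec: WindowSpec = WindowSpec(),
    groups: GroupAssignment | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window scan over every chromosome.

    Returns a DataFrame with one row per window (chrom, start, end, l_eff,
    pi, theta_w, tajima_d and, when ``groups`` is given, fst, dxy and the
    permutation p-value if ``n_perm`` > 0).  Windows whose effective length
    falls below ``spec.min_effective`` carry NaN statistics.
    """
    if mask is None:
        mask = CallabilityMask.all_usable(matrix.chrom_lengths)
    rows = []
    for chrom, length in matrix.chrom_lengths.items():
        for start in spec.starts(length):
            start = int(start)
            end = min(start + spec.length - 1, length)
            l_eff = mask.effective_length(chrom, start, end)
            row: dict = {"chrom": chrom, "start": start, "end": end, "l_eff": l_eff}
            if l_eff < spec.min_effective:
                row.update(pi=np.nan, theta_w=np.nan, tajima_d=np.nan)
                if groups is not None:
                    row.update(fst=np.nan, dxy=np.nan)
            else:
                row["pi"] = pi_window(matrix, mask, chrom, start, end)
                row["theta_w"] = theta_w_window(matrix, mask, chrom, start, end)
                row["tajima_d"] = tajimas_d_window(matrix, mask, chrom, start, end)
                if groups is not None:
                    fst, dxy = fst_dxy_window(matrix, mask, chrom, start, end, groups)
                    row.update(fst=fst, dxy=dxy)
            rows.append(row)
    df = pd.DataFrame(rows)
    if groups is not None and n_perm > 0:
        df["p_perm"] = fst_permutation_null(
            matrix, mask, spec, groups, df, n_perm=n_perm, seed=seed
        )
    return df


def _all_window_fst(
    matrix: VariantMatrix,
    mask: CallabilityMask,
    windows: pd.DataFrame,
    g1: np.ndarray,
    g2: np.ndarray,
) -> np.ndarray:
    """Vectorized per-window Hudson Fst for a fixed grouping."""
    out = np.full(len(windows), np.nan)
    for chrom, sub in windows.groupby("chrom", sort=False):
        pos = matrix.positions[chrom]
        gt_all = matrix.genotypes[chrom]
        keep = mask.usable_sites(chrom, pos) if pos.size else np.zeros(0, bool)
        pos_u, gt_u = pos[keep], gt_all[keep]
        hw, hb = _hudson_site_components(gt_u, g1, g2)
        hw = np.nan_to_num(hw)
        hb = np.nan_to_num(hb)
        cw = np.r_[0.0, np.cumsum(hw)]
        cb = np.r_[0.0, np.cumsum(hb)]
        lo = np.searchsorted(pos_u, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos_u, sub["end"].to_numpy(), side="right")
        hw_sum = cw[hi] - cw[lo]
        hb_sum = cb[hi] - cb[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = 1.0 - hw_sum / hb_sum
        fst[hb_sum == 0] = np.nan
        out[sub.index.to_numpy()] = fst
    return out


def fst_permutation_null(
    matrix: VariantMatrix,
    mask: CallabilityMask | None,
    spec: WindowSpec,
    groups: GroupAssignment,
    windows: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-window one-sided empirical p-value for Fst.

    Samples are randomly rearranged into groups of the observed sizes
    (without replacement) ``n_perm`` times; each permutation is shared
    across all windows.  p = (1 + #{perm Fst >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mask is None:
        mask = CallabilityMask.all_usable(matrix.chrom_lengths)
    if windows is None:
        windows = window_scan(matrix, mask, spec, groups=groups)
    g1, g2 = groups.indices(matrix.samples)
    labelled = np.concatenate([g1, g2])
    observed = _all_window_fst(matrix, mask, windows, g1, g2)
    low_eff = windows["l_eff"].to_numpy() < spec.min_effective
    observed[low_eff] = np.nan

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(windows))
    for _ in range(n_perm):
        perm = rng.permutation(labelled)
        p1, p2 = perm[: g1.size], perm[g1.size :]
        fst_p = _all_window_fst(matrix, mask, windows, p1, p2)
        exceed += np.where(np.isnan(observed), 0, fst_p >= observed - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[np.isnan(observed)] = np.nan
    return p


# ---------------------------------------------------------------------------
# PCA and RI assignment


def pca_snps(
    matrix: VariantMatrix,
    maf_min: float = 0.01,
    require_complete: bool = True,
    scope: str | Sequence[str] = "genome",
    n_components: int = 10,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the 0/1 genotype matrix.

    Sites with missing calls are dropped when ``require_complete``; sites
    with minor allele frequency below ``maf_min`` are dropped.  Columns are
    centred (optionally unit-variance scaled) and decomposed by SVD.
    Returns (scores DataFrame indexed by sample with PC1..PCk columns,
    explained-variance fractions).  Deterministic up to sign.
    """
    chroms = matrix.chroms if scope == "genome" else (
        [scope] if isinstance(scope, str) else list(scope)
    )
    blocks = []
    for chrom in chroms:
        gt = matrix.genotypes[chrom]
        if gt.size == 0:
            continue
        if require_complete:
            gt = gt[(gt != MISSING).all(axis=1)]
        else:
            gt = np.where(gt == MISSING, 0, gt)
        if gt.size == 0:
            continue
        freq = gt.mean(axis=1)
        maf = np.minimum(freq, 1.0 - freq)
        blocks.append(gt[maf >= maf_min])
    if not blocks:
        raise ValueError("no sites pass the PCA filters")
    x = np.concatenate(blocks, axis=0).astype(float).T  # samples x sites
    if x.shape[1] == 0:
        raise ValueError("no sites pass the PCA filters")
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    total_var = np.sum(s**2)
    varfrac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=list(matrix.samples), columns=cols), varfrac


def assign_ri_from_pc1(
    pc1: Mapping[str, float] | pd.Series,
    anchors: Mapping[str, str],
) -> GroupAssignment:
    """Assign RI groups by thresholding PC1 at zero.

    ``anchors`` maps a labelled subset of samples to RI group names; the
    PC1 sign is oriented so that each side inherits its anchor-majority
    label.  A sample sitting exactly at zero stays unassigned.
    """
    pc1 = pd.Series(pc1, dtype=float)
    anchor_labels = set(anchors.values())
    if len(anchor_labels) < 2:
        raise ValueError("anchors must contain both RI group labels")
    labels_sorted = sorted(anchor_labels)
    pos_votes = {lab: 0 for lab in labels_sorted}
    neg_votes = {lab: 0 for lab in labels_sorted}
    for sample, lab in anchors.items():
        if sample not in pc1.index:
            continue
        v = pc1[sample]
        if v > 0:
            pos_votes[lab] += 1
        elif v < 0:
            neg_votes[lab] += 1
    pos_label = max(labels_sorted, key=lambda l: (pos_votes[l], -labels_sorted.index(l)))
    neg_label = max(
        (l for l in labels_sorted if l != pos_label),
        key=lambda l: neg_votes[l],
        default=None,
    )
    labels: dict[str, str] = {}
    for sample, v in pc1.items():
        if v > 0:
            labels[sample] = pos_label
        elif v < 0:
            labels[sample] = neg_label
        else:
            labels[sample] = GroupAssignment.UNASSIGNED
    return GroupAssignment(labels, provenance="PC1-of-chr5")
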