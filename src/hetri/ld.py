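"""Linkage disequilibrium: pairwise r2, decay fitting and LD scans.

r2 is the squared allele-frequency correlation between two biallelic
haploid sites, computed on their pairwise-complete sample overlap.  The
chromosome-wise decay of r2 with physical distance is fitted under the
recombination-drift equilibrium expectation (Hill & Weir), a one-parameter
curve in C = rho * d with rho = 4 Ne c the population-scaled recombination
rate and n the number of sampled sequences:

    E[r2](C) = (10 + C) / ((2 + C)(11 + C))
               * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C)))

At C = 0 and large n this tends to 10/22; as C -> infinity it tends to
1/n.  The fit is exposed statsmodels-style as ``LDDecayModel(...).fit()``
returning :class:`LDDecayResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .popgen import MISSING, VariantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LDRecord",
    "DecayFit",
    "LDDecayModel",
    "LDDecayResults",
    "expected_r2",
    "r2_pair",
    "sample_decay_pairs",
    "fit_decay",
    "binned_ld",
    "thin_sites",
    "thin_and_matrix",
    "locus_ld_scan",
]


@dataclass(frozen=True)
class LDRecord:
    chrom: str
    pos1: int
    pos2: int
    r2: float

    def __post_init__(self) -> None:
        if self.pos1 >= self.pos2:
            raise ValueError("pos1 must be < pos2")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def distance(self) -> int:
        return self.pos2 - self.pos1


def r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Squared allele-frequency correlation of two haploid 0/1 site vectors.

    Computed on the pairwise-complete overlap: r2 = D^2 / (pA qA pB qB)
    with D = pAB - pA pB.  Returns NaN (logged) when the overlap is
    monomorphic at either site or smaller than 2.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.size < 2:
        logger.debug("r2_pair: overlap < 2 calls; undefined")
        return float("nan")
    pa, pb = xs.mean(), ys.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        logger.debug("r2_pair: monomorphic overlap; undefined")
        return float("nan")
    pab = (xs * ys).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _pairwise_r2(gt: np.ndarray) -> np.ndarray:
    """All-pairs r2 matrix of a (sites x samples) 0/1 matrix (no missing)."""
    x = gt.astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / gt.shape[1]
    var = np.diag(cov).copy()
    var[var == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov**2 / np.outer(var, var)
    return r2


def sample_decay_pairs(
    matrix: VariantMatrix,
    windows_per_chrom: int = 30,
    window_len: int = 50_000,
    drop_singletons: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise r2 within randomly placed windows, per chromosome.

    Draws ``windows_per_chrom`` window start positions uniformly (overlaps
    allowed; duplicate site pairs are deduplicated), removes singleton
    sites, and computes r2 for every within-window site pair.  Returns a
    DataFrame (chrom, pos1, pos2, dist, r2).  Chromosomes shorter than the
    window are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, int, int, float]] = []
    for chrom, length in matrix.chrom_lengths.items():
        if length < window_len:
            logger.warning("%s shorter than %d bp; skipped", chrom, window_len)
            continue
        pos = matrix.positions[chrom]
        gt = matrix.genotypes[chrom]
        if drop_singletons and gt.size:
            called = gt != MISSING
            n = called.sum(axis=1)
            j = np.where(called, gt, 0).sum(axis=1)
            mac = np.minimum(j, n - j)
            keep = mac >= 2
            pos, gt = pos[keep], gt[keep]
        seen: set[tuple[int, int]] = set()
        starts = rng.integers(1, length - window_len + 2, size=windows_per_chrom)
        for start in starts:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + window_len - 1, side="right")
            idx = np.arange(lo, hi)
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    key = (int(pos[idx[a]]), int(pos[idx[b]]))
                    if key in seen:
                        continue
                    seen.add(key)
                    r2 = r2_pair(gt[idx[a]], gt[idx[b]])
                    if np.isnan(r2):
                        continue
                    rows.append((chrom, key[0], key[1], key[1] - key[0], r2))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist", "r2"])


def expected_r2(distance: np.ndarray | float, rho_per_bp: float, n: int) -> np.ndarray:
    """Recombination-drift equilibrium expectation of r2 at C = rho * d."""
    c = np.asarray(distance, dtype=float) * rho_per_bp
    base = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    corr = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return base * corr


@dataclass
class DecayFit:
    """Least-squares fit of the LD decay curve."""

    rho_per_bp: float
    n: int
    rss: float
    converged: bool
    d02: float | None  # distance where the fitted curve crosses r2 = 0.2

    def predict(self, distance) -> np.ndarray:
        return expected_r2(distance, self.rho_per_bp, self.n)


def fit_decay(
    records: pd.DataFrame | Sequence[LDRecord],
    n: int,
    rho_starts: Sequence[float] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
) -> DecayFit:
    """Fit rho by bounded nonlinear least squares with multi-start.

    ``records`` needs columns (or attributes) ``dist`` and ``r2``; at least
    10 positive-distance records are required.  Non-convergence is flagged
    on the result rather than raised.  The crossing distance d02 where the
    fitted expectation equals 0.2 is found by root bracketing (None when
    the curve never crosses, e.g. n <= 5).
    """
    if isinstance(records, pd.DataFrame):
        dist = records["dist"].to_numpy(dtype=float)
        r2 = records["r2"].to_numpy(dtype=float)
    else:
        dist = np.array([r.distance for r in records], dtype=float)
        r2 = np.array([r.r2 for r in records], dtype=float)
    ok = (dist > 0) & np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    if dist.size < 10:
        raise ValueError("need at least 10 records with positive distances")

    def resid(log_rho):
        return expected_r2(dist, np.exp(log_rho[0]), n) - r2

    best = None
    for start in rho_starts:
        sol = least_squares(resid, x0=[np.log(start)], xtol=1e-12, ftol=1e-12)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, float(np.exp(sol.x[0])), bool(sol.success))
    rss, rho, converged = best

    d02 = None
    if expected_r2(0.0, rho, n) > 0.2 > 1.0 / n:
        lo, hi = 0.0, 2.0
        while expected_r2(hi, rho, n) > 0.2 and hi < 1e12:
            hi *= 10.0
        if hi < 1e12:
            d02 = float(brentq(lambda d: expected_r2(d, rho, n) - 0.2, lo, hi))
    return DecayFit(rho_per_bp=rho, n=n, rss=rss, converged=converged, d02=d02)


class LDDecayModel:
    """Decay-curve model over distance-r2 records for n sequences."""

    def __init__(self, records: pd.DataFrame, n: int):
        self.records = records
        self.n = n

    def fit(self, **kwargs) -> "LDDecayResults":
        return LDDecayResults(self, fit_decay(self.records, self.n, **kwargs))


class LDDecayResults:
    def __init__(self, model: LDDecayModel, fit: DecayFit):
        self.model = model
        self._fit = fit

    @property
    def rho_per_bp(self) -> float:
        return self._fit.rho_per_bp

    @property
    def d02(self) -> float | None:
        return self._fit.d02

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def rss(self) -> float:
        return self._fit.rss

    def predict(self, distance) -> np.ndarray:
        return self._fit.predict(distance)

    def summary(self) -> str:
        lines = [
            "LD decay fit (recombination-drift equilibrium)",
            f"  records:        {len(self.model.records)}",
            f"  n sequences:    {self.model.n}",
            f"  rho per bp:     {self.rho_per_bp:.6g}",
            f"  residual SS:    {self.rss:.6g}",
            f"  converged:      {self.converged}",
            f"  d(r2=0.2):      "
            + (f"{self.d02:.1f} bp" if self.d02 is not None else "no crossing"),
        ]
        return "\n".join(lines)


def binned_ld(records: pd.DataFrame, bin_width: int = 1000) -> pd.DataFrame:
    """Mean r2 per right-open distance bin [k*w, (k+1)*w).

    Empty bins within the observed distance span are reported with NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    dist = records["dist"].to_numpy(dtype=float)
    r2 = records["r2"].to_numpy(dtype=float)
    idx = (dist // bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": (np.arange(n_bins) + 1) * bin_width,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )


def thin_sites(
    positions: np.ndarray, keep: np.ndarray, min_spacing: int
) -> np.ndarray:
    """Greedy left-to-right thinning: drop sites within min_spacing of the
    last kept site.  ``keep`` pre-filters (e.g. by MAF)."""
    kept: list[int] = []
    last = -np.inf
    for i in np.flatnonzero(keep):
        if positions[i] - last >= min_spacing:
            kept.append(i)
            last = positions[i]
    return np.asarray(kept, dtype=int)


def thin_and_matrix(
    matrix: VariantMatrix,
    chrom: str,
    maf_min: float = 0.02,
    min_spacing: int = 1000,
    region: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinned pairwise r2 matrix for one chromosome (heatmap input).

    Sites below ``maf_min`` are dropped, then greedy 1-kb thinning keeps
    the first site and drops any site closer than ``min_spacing`` to the
    last kept one.  Returns (kept positions, symmetric r2 matrix with unit
    diagonal).  ``region`` optionally restricts to a 1-based inclusive
    span (e.g. to reproduce a chromosome-arm-only analysis).
    """
    pos = matrix.positions[chrom]
    gt = matrix.genotypes[chrom]
    if region is not None:
        sel = (pos >= region[0]) & (pos <= region[1])
        pos, gt = pos[sel], gt[sel]
    if gt.size == 0:
        return np.empty(0, dtype=int), np.empty((0, 0))
    called = gt != MISSING
    n = called.sum(axis=1)
    j = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = j / n
    maf = np.minimum(freq, 1 - freq)
    kept = thin_sites(pos, maf > maf_min, min_spacing)
    if kept.size == 0:
        return np.empty(0, dtype=int), np.empty((0, 0))
    sub = gt[kept]
    r2 = np.empty((kept.size, kept.size))
    for a in range(kept.size):
        r2[a, a] = 1.0
        for b in range(a + 1, kept.size):
            val = r2_pair(sub[a], sub[b])
            r2[a, b] = r2[b, a] = val
    return pos[kept], r2


def locus_ld_scan(
    matrix: VariantMatrix,
    focal: np.ndarray,
    maf_min: float = 0.02,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """r2 between a focal locus genotype vector and every passing SNP.

    ``focal`` is a 0/1 (or -1 missing) vector aligned to the matrix's
    samples, e.g. the het-v allele indicator.  Returns the per-site table
    (chrom, pos, r2) and a genome-wide distribution summary so that named
    locus-locus comparisons can be situated within it.
    """
    focal = np.asarray(focal)
    called = focal[focal != MISSING]
    if called.size == 0 or len(set(called.tolist())) < 2:
        raise ValueError("focal locus is monomorphic")
    rows = []
    for chrom in matrix.chroms:
        pos = matrix.positions[chrom]
        gt = matrix.genotypes[chrom]
        for i in range(pos.size):
            site = gt[i]
            ok = site != MISSING
            if ok.sum() == 0:
                continue
            freq = site[ok].mean()
            if min(freq, 1 - freq) < maf_min:
                continue
            val = r2_pair(focal, site)
            if not np.isnan(val):
                rows.append((chrom, int(pos[i]), val))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "r2"])
    vals = table["r2"].to_numpy()
    summary = {
        "n_sites": int(vals.size),
        "mean": float(np.mean(vals)) if vals.size else float("nan"),
        "median": float(np.median(vals)) if vals.size else float("nan"),
        "q95": float(np.quantile(vals, 0.95)) if vals.size else float("nan"),
        "max": float(np.max(vals)) if vals.size else float("nan"),
    }
    return table, summary
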