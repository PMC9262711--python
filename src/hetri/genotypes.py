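"""Strain-level genotype utilities for the het-r/het-v system.

WD40 repeat counts from amplicon sizes (one repeat is ~126 bp of PCR
product), het-r allele classification (R = exactly 11 repeats in the
reference order), two-locus association, the substrate contingency test,
allele-frequency-through-time summaries and the positional-cloning
recombination arithmetic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .ld import r2_pair

logger = logging.getLogger(__name__)

WD40_BP_PER_REPEAT = 126

__all__ = [
    "StrainRecord",
    "RepeatCall",
    "wd40_repeat_count",
    "classify_het_r",
    "two_locus_r2",
    "substrate_test",
    "allele_trajectories",
    "map_distance_report",
    "MapDistanceReport",
]


@dataclass(frozen=True)
class StrainRecord:
    """One strain of the collection."""

    strain: str
    year: int | None = None
    substrate: str | None = None  # horse | rabbit | cow | sheep | other
    het_r: str = "unknown"  # R | r | unknown
    het_v: str = "unknown"  # V | V1 | unknown
    amplicon_bp: float | None = None

    def __post_init__(self) -> None:
        if self.year is not None and not 1937 <= self.year <= 2100:
            raise ValueError(f"implausible collection year {self.year}")
        if self.het_r not in ("R", "r", "unknown"):
            raise ValueError(f"het_r must be R/r/unknown, got {self.het_r!r}")
        if self.het_v not in ("V", "V1", "unknown"):
            raise ValueError(f"het_v must be V/V1/unknown, got {self.het_v!r}")


@dataclass(frozen=True)
class RepeatCall:
    amplicon_bp: float
    repeat_count: int
    order_known: bool
    allele: str


def wd40_repeat_count(amplicon_bp: float) -> int:
    """Repeat count = nearest integer to amplicon_bp / 126.

    Exact half-integers round down with a warning (the amplicon size is
    only accurate to a gel band).
    """
    if amplicon_bp <= 0:
        raise ValueError("amplicon size must be positive")
    ratio = amplicon_bp / WD40_BP_PER_REPEAT
    frac = ratio - np.floor(ratio)
    if abs(frac - 0.5) < 1e-9:
        warnings.warn(
            f"amplicon {amplicon_bp} bp sits halfway between repeat counts; rounding down"
        )
        return int(np.floor(ratio))
    return int(np.round(ratio))


def classify_het_r(
    repeat_count: int, order_matches_reference: bool | None = None
) -> str:
    """Classify the het-r allele from its WD40 repeat structure.

    R requires exactly 11 repeats in the reference arrangement; any other
    count, or 11 repeats in a different order, is the non-functional r.
    With the order unknown an 11-repeat allele is a provisional R
    ("R?"), flagged for sequencing.
    """
    if repeat_count != 11:
        return "r"
    if order_matches_reference is None:
        return "R?"
    return "R" if order_matches_reference else "r"


def two_locus_r2(
    records: Sequence[StrainRecord] | pd.DataFrame,
    locus_a: str = "het_r",
    locus_b: str = "het_v",
) -> tuple[float, pd.DataFrame]:
    """r2 between two het loci across strains genotyped at both.

    Delegates to the haplotype r2 of the LD module on allele-indicator
    vectors and returns the 2x2 haplotype count table alongside.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    sub = df[(df[locus_a] != "unknown") & (df[locus_b] != "unknown")]
    sub = sub.dropna(subset=[locus_a, locus_b])
    alleles_a = sorted(sub[locus_a].unique())
    alleles_b = sorted(sub[locus_b].unique())
    if len(alleles_a) != 2 or len(alleles_b) != 2:
        raise ValueError(
            f"both loci must be biallelic among double-genotyped strains "
            f"(saw {alleles_a} and {alleles_b})"
        )
    x = (sub[locus_a] == alleles_a[1]).to_numpy(dtype=np.int8)
    y = (sub[locus_b] == alleles_b[1]).to_numpy(dtype=np.int8)
    table = pd.crosstab(sub[locus_a], sub[locus_b])
    return r2_pair(x, y), table


def substrate_test(
    records: Sequence[StrainRecord] | pd.DataFrame,
    groups: dict[str, str] | None = None,
    substrates: tuple[str, str] = ("horse", "rabbit"),
    yates: bool = False,
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square test of RI group vs dung substrate.

    Builds the 2x2 group x substrate table (RI group from ``groups``
    keyed by strain, else from the het_v allele) and returns
    (chi2, dof, p, table).  Continuity correction is off by default.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if groups is not None:
        df["group"] = df["strain"].map(groups)
    else:
        df["group"] = df["het_v"].map({"V": "rV-group", "V1": "RV1-group"})
    sub = df[df["substrate"].isin(substrates) & df["group"].notna()]
    table = pd.crosstab(sub["group"], sub["substrate"])
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() or (
        table.sum(axis=1) == 0
    ).any():
        raise ValueError(
            "contingency table needs two groups, two substrates and positive "
            "margins; merge categories or collect more strains"
        )
    chi2, p, dof, _ = chi2_contingency(table.to_numpy(), correction=yates)
    return float(chi2), int(dof), float(p), table


def allele_trajectories(
    records: Sequence[StrainRecord] | pd.DataFrame,
    locus: str = "het_v",
    min_per_year: int = 6,
) -> pd.DataFrame:
    """Per-year allele frequencies at one locus.

    Years with fewer than ``min_per_year`` genotyped strains are
    suppressed (the display rule "years with more than five samples").
    Returns a DataFrame (year, allele, frequency, n).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    sub = df[(df[locus] != "unknown") & df[locus].notna() & df["year"].notna()]
    rows = []
    for year, grp in sub.groupby("year"):
        n = len(grp)
        if n < min_per_year:
            continue
        freqs = grp[locus].value_counts(normalize=True)
        for allele, freq in freqs.items():
            rows.append(
                {"year": int(year), "allele": allele, "frequency": float(freq), "n": n}
            )
    return pd.DataFrame(rows, columns=["year", "allele", "frequency", "n"])


@dataclass(frozen=True)
class MapDistanceReport:
    """Recombination-mapping arithmetic between two physical markers."""

    total_progeny: int
    recombinants: int
    physical_bp: int
    percent_recombination: float  # full precision
    kb_per_percent: float | None  # full precision, None when no recombinants

    @property
    def percent_rounded(self) -> float:
        return round(self.percent_recombination, 1)

    @property
    def kb_per_percent_rounded(self) -> float | None:
        return None if self.kb_per_percent is None else round(self.kb_per_percent, 1)


def map_distance_report(
    total_progeny: int, recombinants: int, physical_bp: int
) -> MapDistanceReport:
    """Percent recombination and physical bp per 1% recombination.

    percent = 100 * recombinants / total; kb per 1% = physical_bp /
    percent / 1000.  Values are kept at full precision and rounded to one
    decimal only at the reporting layer; zero recombinants leaves the
    bp-per-percent undefined (None).
    """
    if total_progeny <= 0:
        raise ValueError("total progeny must be positive")
    if not 0 <= recombinants <= total_progeny:
        raise ValueError("recombinants must lie in [0, total]")
    if physical_bp <= 0:
        raise ValueError("physical distance must be positive")
    percent = 100.0 * recombinants / total_progeny
    kb_per_pct = None if percent == 0 else physical_bp / percent / 1000.0
    return MapDistanceReport(
        total_progeny=total_progeny,
        recombinants=recombinants,
        physical_bp=physical_bp,
        percent_recombination=percent,
        kb_per_percent=kb_per_pct,
    )
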