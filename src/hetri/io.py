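"""Standard-format I/O: VCF (haploid GT), BED, coverage TSV, mating CSV.

VCF reading uses cyvcf2 and keeps biallelic SNPs only; writing emits plain
VCFv4.2 text with haploid genotype calls.  BED intervals are 0-based
half-open; all in-memory window coordinates are 1-based inclusive and
converted at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .popgen import MISSING, GroupAssignment, VariantMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_mating_csv",
    "read_mating_csv",
    "read_groups_tsv",
    "write_windows_tsv",
    "read_strain_table",
]


def write_vcf(matrix: VariantMatrix, path: str | os.PathLike) -> None:
    """Write a haploid multi-sample VCFv4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hetri\n")
        for chrom, length in matrix.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for chrom in matrix.chroms:
            pos = matrix.positions[chrom]
            gt = matrix.genotypes[chrom]
            ref = matrix.ref[chrom]
            alt = matrix.alt[chrom]
            for i in range(pos.size):
                calls = "\t".join(
                    "." if g == MISSING else str(int(g)) for g in gt[i]
                )
                fh.write(
                    f"{chrom}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{calls}\n"
                )


def read_vcf(
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int] | None = None,
) -> VariantMatrix:
    """Read a haploid multi-sample VCF into a VariantMatrix.

    Keeps biallelic SNPs only (indels and multiallelic records dropped).
    Chromosome lengths come from the header contig lines unless supplied.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    lengths: dict[str, int] = dict(chrom_lengths or {})
    if not lengths:
        for name, length in zip(vcf.seqnames, vcf.seqlens or []):
            lengths[name] = int(length)
    positions: dict[str, list[int]] = {}
    genotypes: dict[str, list[np.ndarray]] = {}
    refs: dict[str, list[str]] = {}
    alts: dict[str, list[str]] = {}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        chrom = var.CHROM
        arr = var.genotype.array()  # (n_samples, ploidy+1); haploid: allele, phase
        calls = arr[:, 0].astype(np.int8)
        calls[calls < 0] = MISSING
        positions.setdefault(chrom, []).append(var.POS)
        genotypes.setdefault(chrom, []).append(calls)
        refs.setdefault(chrom, []).append(var.REF)
        alts.setdefault(chrom, []).append(var.ALT[0])
    vcf.close()
    for chrom in positions:
        lengths.setdefault(chrom, int(max(positions[chrom])))
    return VariantMatrix(
        samples=samples,
        chrom_lengths=lengths,
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        genotypes={
            c: np.vstack(g).astype(np.int8) for c, g in genotypes.items()
        },
        ref={c: np.asarray(r, dtype="U20") for c, r in refs.items()},
        alt={c: np.asarray(a, dtype="U20") for c, a in alts.items()},
    )


def write_bed(
    intervals: Mapping[str, Iterable[tuple[int, int]]], path: str | os.PathLike
) -> None:
    """Write 0-based half-open intervals as BED3."""
    with open(path, "w") as fh:
        for chrom, ivals in intervals.items():
            for start0, end0 in ivals:
                fh.write(f"{chrom}\t{start0}\t{end0}\n")


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start0, end0 = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start0), int(end0)))
    return out


def write_coverage_tsv(
    coverage: Mapping[str, Mapping[str, np.ndarray]], path: str | os.PathLike
) -> None:
    """Long-format depth table: sample, chrom, pos (1-based), depth."""
    frames = []
    for sample, tracks in coverage.items():
        for chrom, depth in tracks.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "pos": np.arange(1, len(depth) + 1),
                        "depth": np.asarray(depth),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int]
) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (sample, chrom), grp in df.groupby(["sample", "chrom"]):
        track = np.zeros(chrom_lengths[chrom], dtype=np.int32)
        track[grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
        out.setdefault(str(sample), {})[str(chrom)] = track
    for sample in out:
        for chrom, length in chrom_lengths.items():
            out[sample].setdefault(chrom, np.zeros(length, dtype=np.int32))
    return out


def write_mating_csv(matrix, strains: list[str] | None, path: str | os.PathLike) -> None:
    """CSV mating matrix with strain IDs as header row and column."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        if strains is None:
            strains = [f"s{i}" for i in range(matrix.shape[0])]
        df = pd.DataFrame(matrix, index=strains, columns=strains)
    df.to_csv(path)


def read_mating_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_groups_tsv(path: str | os.PathLike) -> GroupAssignment:
    """Two-column TSV (sample, label) -> GroupAssignment."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                     comment="#")
    return GroupAssignment(
        labels=dict(zip(df["sample"].astype(str), df["label"].astype(str))),
        provenance="file",
    )


def write_windows_tsv(windows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Window statistics TSV; missing values written as the string NA."""
    windows.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_strain_table(path: str | os.PathLike) -> pd.DataFrame:
    """Strain genotype table TSV with StrainRecord-style columns."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return df
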