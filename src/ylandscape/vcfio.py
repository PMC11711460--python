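"""Reading and writing the pipeline's on-disk formats.

VCF 4.2 (read through pysam), BED mappability masks (0-based half-open) and
the tab-separated metadata/census tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .matrix import GenotypeMatrix, HET, MISSING

__all__ = ["read_vcf", "write_vcf", "read_bed", "write_bed", "read_census"]

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom}>
##FILTER=<ID=FAIL_QUAL,Description="Failed upstream variant-calling filters">
##INFO=<ID=DP_MEAN,Number=1,Type=Float,Description="Mean read depth across samples">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STRING = {0: "0", 1: "1", MISSING: ".", HET: "0/1"}


def write_vcf(path, gm: GenotypeMatrix, chrom: str = "chrY") -> None:
    """Write a haploid VCF 4.2. Heterozygous-artifact calls (code 2) are
    emitted as diploid "0/1" records."""
    v = gm.variants
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, (vid, row) in enumerate(v.iterrows()):
            info = (
                f"DP_MEAN={row['dp_mean']:.2f};FS={row['fs']:.2f};"
                f"MQ={row['mq']:.2f}"
            )
            gts = "\t".join(_GT_STRING[g] for g in gm.G[i])
            fh.write(
                f"{chrom}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}\t"
                f".\t{row['filter']}\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Load a single-chromosome haploid VCF into a GenotypeMatrix.

    Diploid heterozygous calls are encoded as 2, missing as -1.  Raises
    ValueError when the file lacks a GT FORMAT field.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise ValueError("VCF without GT format field")
    samples = list(vf.header.samples)
    rows, gts = [], []
    for rec in vf:
        alt = rec.alts[0] if rec.alts else "."
        rows.append(
            {
                "id": rec.id or f"{rec.chrom}_{rec.pos}",
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "n_alt": len(rec.alts or ()),
                "filter": ";".join(rec.filter.keys()) or "PASS",
                "dp_mean": float(rec.info.get("DP_MEAN", np.nan)),
                "fs": float(rec.info.get("FS", np.nan)),
                "mq": float(rec.info.get("MQ", np.nan)),
            }
        )
        row = np.empty(len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            alleles = rec.samples[s]["GT"]
            if alleles is None or all(a is None for a in alleles):
                row[j] = MISSING
            elif len(alleles) == 1:
                row[j] = MISSING if alleles[0] is None else min(alleles[0], 1)
            else:  # diploid record among haploid calls
                uniq = {a for a in alleles if a is not None}
                if len(uniq) == 1:
                    row[j] = min(uniq.pop(), 1)
                else:
                    row[j] = HET
        gts.append(row)
    vf.close()
    variants = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["pos", "ref", "alt", "n_alt", "filter", "dp_mean", "fs", "mq"]
    )
    G = np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(variants, G, samples)


def read_bed(path) -> list[tuple[int, int]]:
    """Read BED intervals (0-based half-open) for one chromosome."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"BED interval with end <= start: {line!r}")
            intervals.append((start, end))
    return intervals


def write_bed(path, intervals, chrom: str = "chrY") -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_census(path) -> dict[str, int]:
    """Read a region/population TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(int)))
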