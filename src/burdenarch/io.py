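"""Readers and writers for the pipeline's file formats.

VCF (v4.2, GT-only), TSV tables, GMT gene sets, JSON manifests and TOML
configuration. Reading goes through cyvcf2 (htslib) so that anything a
standard toolchain emits is accepted, including multiallelic records,
which are split into biallelic ones. Writing emits minimal VCFv4.2 text
directly: the matrices here are dense dosage blocks and a vectorized
text writer keeps full-cohort writes fast.

Parsers are strict: malformed lines raise :class:`DataFormatError`
naming the file, line and column.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_gmt",
    "write_gmt",
    "read_table",
    "read_toml",
]

_GT_STRINGS = np.array(["0/0", "0/1", "1/1"])


def write_vcf(path: str | Path, genotypes) -> None:
    """Write a :class:`~burdenarch.cohort.GenotypeMatrix` as VCFv4.2.

    Variants are laid out on a single synthetic contig in plan order;
    the variant id column carries the identity used everywhere else.
    """
    path = Path(path)
    n, m = genotypes.dosages.shape
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1,length=%d>\n' % max(m + 1, 2))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO"]
        if n:  # htslib rejects a FORMAT column with zero samples
            cols += ["FORMAT"] + list(genotypes.sample_ids)
        fh.write("\t".join(cols) + "\n")
        for j in range(m):
            fixed = f"1\t{j + 1}\t{genotypes.variant_ids[j]}\tA\tG\t.\t.\t."
            if n:
                gts = _GT_STRINGS[genotypes.dosages[:, j]]
                fh.write(fixed + "\tGT\t" + "\t".join(gts) + "\n")
            else:
                fh.write(fixed + "\n")


def read_vcf(path: str | Path, clusters: np.ndarray | None = None):
    """Read a VCF into a GenotypeMatrix of alternate-allele dosages.

    Multiallelic records are split into one biallelic record per
    alternate allele (ids suffixed ``_alt<k>`` when the source record
    has no per-allele id).
    """
    from cyvcf2 import VCF

    from .cohort import GenotypeMatrix

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    dosage_cols: list[np.ndarray] = []
    variant_ids: list[str] = []
    split_count = 0
    for rec in vcf:
        vid = rec.ID if rec.ID is not None else f"{rec.CHROM}:{rec.POS}"
        alts = rec.ALT
        if len(alts) <= 1:
            gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            dos = np.where(gt == 3, 2, np.where(gt == 1, 1, 0)).astype(np.int8)
            dosage_cols.append(dos)
            variant_ids.append(vid)
        else:
            split_count += 1
            calls = rec.genotypes  # [allele1, allele2, phased] per sample
            arr = np.array([[c[0], c[1]] for c in calls], dtype=np.int16)
            for k in range(1, len(alts) + 1):
                dos = (arr == k).sum(axis=1).astype(np.int8)
                dosage_cols.append(dos)
                variant_ids.append(f"{vid}_alt{k}")
    vcf.close()
    if dosage_cols:
        dosages = np.column_stack(dosage_cols).astype(np.int8)
    else:
        dosages = np.zeros((len(samples), 0), dtype=np.int8)
    if clusters is None:
        clusters = np.zeros(len(samples), dtype=np.int32)
    return GenotypeMatrix(dosages, samples, variant_ids,
                          np.asarray(clusters))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file (set name, description, member genes...).

    Lines with fewer than three tab-separated fields (i.e. no genes)
    are rejected with the offending line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno}: GMT record has "
                    f"{len(fields)} columns, needs name, description "
                    "and at least one gene")
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise DataFormatError(
                    f"{path}: line {lineno}: gene set '{name}' is empty")
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gmt(path: str | Path, sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_table(path: str | Path, required: tuple[str, ...] = (),
               **kwargs) -> pd.DataFrame:
    """Strict TSV reader: missing required columns raise with names."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_toml(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def format_pvalues(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Serialize P-value columns in 6-significant-digit scientific
    notation for diffable output files."""
    out = df.copy()
    for c in columns:
        if c in out.columns:
            out[c] = out[c].map(
                lambda v: f"{v:.6e}" if pd.notna(v) else "NA")
    return out
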