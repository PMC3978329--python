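"""Reading and writing genotype matrices (minimal VCF and dosage TSV).

The simulator exports cohorts either as a minimal single-contig VCF
(biallelic sites, GT-only FORMAT, 1-based positions, sample names prefixed
``case``/``ctrl`` so the phenotype survives the round trip) or as a plain
tab-separated dosage table with a ``phenotype`` column.  Readers map VCF
GT fields to minor-allele dosages — the minor allele is determined from
the pooled sample, with ties broken toward ALT — reject multi-allelic
sites and missing genotypes (no imputation), and validate dosage values.
"""
from __future__ import annotations

import os
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import GenotypeMatrix

__all__ = [
    "GenotypeDataError",
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_genotypes",
]

_GT_STRINGS = ("0/0", "0/1", "1/1")


class GenotypeDataError(ValueError):
    """A genotype file violates the reader's contract (the message names
    the offending record)."""


def _sample_names(phenotype: np.ndarray) -> list[str]:
    names, n_case, n_ctrl = [], 0, 0
    for y in phenotype:
        if y == 1:
            n_case += 1
            names.append(f"case{n_case:05d}")
        else:
            n_ctrl += 1
            names.append(f"ctrl{n_ctrl:05d}")
    return names


def write_vcf(genotypes: GenotypeMatrix, path: Union[str, os.PathLike]) -> None:
    """Write a minimal biallelic VCF: contig ``1``, positions 1..m, REF A /
    ALT T, unphased GT, ALT counted as the minor allele."""
    names = _sample_names(genotypes.phenotype)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for s in range(genotypes.m):
            gts = "\t".join(_GT_STRINGS[d] for d in genotypes.dosages[:, s])
            fh.write(f"1\t{s + 1}\tvar{s + 1}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _phenotype_from_names(names: Sequence[str]) -> np.ndarray:
    y = np.empty(len(names), dtype=np.int8)
    for i, name in enumerate(names):
        low = name.lower()
        if low.startswith("case"):
            y[i] = 1
        elif low.startswith(("ctrl", "control")):
            y[i] = 0
        else:
            raise GenotypeDataError(
                f"cannot infer phenotype for sample {name!r}: provide an "
                "explicit phenotype mapping or prefix names with "
                "'case'/'ctrl'")
    return y


def read_vcf(path: Union[str, os.PathLike],
             phenotype: Optional[dict[str, int]] = None) -> GenotypeMatrix:
    """Read a biallelic VCF into a minor-allele dosage matrix.

    ``phenotype`` optionally maps sample name to 1 (case) / 0 (control);
    otherwise labels are inferred from ``case``/``ctrl`` name prefixes.
    Multi-allelic sites and missing genotypes raise
    :class:`GenotypeDataError` naming the record.  A site whose ALT turns
    out to be the major allele in the pooled sample is flipped so the
    dosage counts the minor allele (ties keep ALT).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if phenotype is not None:
        try:
            y = np.array([phenotype[s] for s in samples], dtype=np.int8)
        except KeyError as exc:
            raise GenotypeDataError(f"phenotype missing for sample {exc}") from None
    else:
        y = _phenotype_from_names(samples)
    columns = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenotypeDataError(
                f"multi-allelic site {v.CHROM}:{v.POS} ({v.ID}); split or "
                "drop it first")
        gt = np.asarray(v.gt_types)  # gts012: 0/1/2 = alt dosage, 3 = missing
        if np.any(gt == 3):
            missing = [samples[i] for i in np.nonzero(gt == 3)[0]]
            raise GenotypeDataError(
                f"missing genotype at {v.CHROM}:{v.POS} for {missing[:5]}")
        columns.append(gt.astype(np.int8))
    if not columns:
        raise GenotypeDataError(f"no variant records in {path}")
    dosages = np.column_stack(columns)
    # orient each site toward the pooled minor allele (ties keep ALT)
    pooled = dosages.mean(axis=0) / 2.0
    flip = pooled > 0.5
    dosages[:, flip] = 2 - dosages[:, flip]
    return GenotypeMatrix(dosages=dosages, phenotype=y)


def write_dosage_tsv(genotypes: GenotypeMatrix,
                     path: Union[str, os.PathLike]) -> None:
    """Tab-separated table: sample, phenotype, then one 0/1/2 column per
    variant (var1..varm)."""
    df = pd.DataFrame(genotypes.dosages,
                      columns=[f"var{i + 1}" for i in range(genotypes.m)])
    df.insert(0, "phenotype", genotypes.phenotype)
    df.insert(0, "sample", _sample_names(genotypes.phenotype))
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: Union[str, os.PathLike]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "phenotype"):
        if col not in df.columns:
            raise GenotypeDataError(f"dosage TSV lacks required column {col!r}")
    variant_cols = [c for c in df.columns if c not in ("sample", "phenotype")]
    if not variant_cols:
        raise GenotypeDataError("dosage TSV contains no variant columns")
    y = df["phenotype"].to_numpy()
    if not np.isin(y, (0, 1)).all():
        bad = df.loc[~np.isin(y, (0, 1)), "sample"].tolist()
        raise GenotypeDataError(f"phenotype must be 0/1; offending samples: {bad[:5]}")
    d = df[variant_cols].to_numpy()
    if not np.isin(d, (0, 1, 2)).all():
        rows, cols = np.nonzero(~np.isin(d, (0, 1, 2)))
        where = [(df['sample'].iloc[r], variant_cols[c])
                 for r, c in zip(rows[:5], cols[:5])]
        raise GenotypeDataError(f"dosages must be 0/1/2; offending records: {where}")
    return GenotypeMatrix(dosages=d.astype(np.int8), phenotype=y.astype(np.int8))


def read_genotypes(path: Union[str, os.PathLike],
                   format: Optional[str] = None,
                   phenotype: Optional[dict[str, int]] = None) -> GenotypeMatrix:
    """Dispatch on ``format`` ('vcf' or 'dosage_tsv'; inferred from the
    file suffix when omitted)."""
    if format is None:
        suffix = str(path).lower()
        format = "vcf" if suffix.endswith((".vcf", ".vcf.gz")) else "dosage_tsv"
    if format == "vcf":
        return read_vcf(path, phenotype=phenotype)
    if format == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")
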