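"""File formats: phenotype/dosage TSV, minimal VCF, result tables, JSON.

Conventions: genotype TSVs are oriented variants x subjects with the counted
(effect) allele stated per variant; for VCF input the counted allele is ALT
and dosages are ALT-allele counts from the GT field. Positions are 1-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_phenotypes
from .errors import AlignmentError, FormatError

log = logging.getLogger("kinsurv")

_META_COLS = ["snp", "chrom", "pos", "effect_allele", "freq"]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    validate_phenotypes(phenotypes)
    phenotypes.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    validate_phenotypes(df)
    return df


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    meta = gm.variants[_META_COLS].copy()
    dosage = pd.DataFrame(gm.dosages, columns=list(map(str, gm.subjects)))
    pd.concat([meta.reset_index(drop=True), dosage], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV {path} missing metadata columns {missing}")
    subject_cols = [c for c in df.columns if c not in _META_COLS]
    if not subject_cols:
        raise FormatError(f"dosage TSV {path} has no subject columns")
    dosages = df[subject_cols].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, np.array(subject_cols), df[_META_COLS].copy())


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT fields; requires integer (hard-call) dosages.

    REF is written as 'C' and ALT as the counted allele recorded in the
    variant table, so reading the file back counts the same allele.
    """
    d = gm.dosages
    finite = np.isfinite(d)
    if not np.all(np.rint(d[finite]) == d[finite]):
        raise FormatError("VCF output requires integer dosages; use the dosage TSV instead")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.subjects))
            + "\n"
        )
        for v in range(gm.n_variants):
            row = gm.variants.iloc[v]
            alt = str(row["effect_allele"])
            ref = "C" if alt != "C" else "G"
            calls = [
                gt_map[int(x)] if np.isfinite(x) else "./." for x in d[v]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT-based dosages of the ALT allele from a (plain-text) VCF.

    Missing genotypes are mean-imputed per variant, with the imputation count
    logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = np.array(vcf.samples)
    rows, meta = [], []
    n_imputed = 0
    for variant in vcf:
        g = variant.gt_types.astype(float)  # 0/1/2 = dosage, 3 = missing with gts012
        missing = g == 3
        if missing.any():
            n_imputed += int(missing.sum())
            g[missing] = np.nan
            if not missing.all():
                g[missing.astype(bool)] = np.nanmean(g)
        rows.append(g)
        meta.append(
            {
                "snp": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "effect_allele": variant.ALT[0] if variant.ALT else ".",
                "freq": np.nan,
            }
        )
    if not rows:
        raise FormatError(f"no variants found in {path}")
    if n_imputed:
        log.info("mean-imputed %d missing genotype calls from %s", n_imputed, path)
    return GenotypeMatrix(np.vstack(rows), subjects, pd.DataFrame(meta))


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('tsv' or 'vcf'; inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise FormatError(f"unknown genotype format {fmt!r}")


def align_genotypes(gm: GenotypeMatrix, phenotypes: pd.DataFrame) -> GenotypeMatrix:
    """Restrict the genotype matrix to subjects present in the phenotypes."""
    ids = pd.Index(phenotypes["subject_id"].astype(str).unique())
    present = ids.intersection(pd.Index(np.asarray(gm.subjects, dtype=str)))
    if len(present) == 0:
        raise AlignmentError("no overlap between genotype and phenotype subject ids")
    return gm.subset_subjects(present.to_numpy())


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
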