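"""In-memory containers shared across the package.

The phenotype side of the analysis lives in a plain pandas DataFrame with one
row per *parent record* (so up to two rows per genotyped subject):

======================  =======================================================
column                  meaning
======================  =======================================================
subject_id              id of the genotyped offspring
parent_sex              "father" or "mother"
observed_age            parent age last observed (death age or age at interview)
event                   1 if the parent was dead at interview, 0 if alive
adopted                 offspring reported being adopted (parental genes unknown)
age_valid               generator/ingest flag; ages > 115 are treated as invalid
covariate_1..k          confounder covariates (centre, batch, deprivation, PCs)
======================  =======================================================

Genotypes are held in :class:`GenotypeMatrix`, oriented variants x subjects,
with dosages of the counted (effect) allele in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

PHENO_CORE_COLUMNS = ("subject_id", "parent_sex", "observed_age", "event")

VARIANT_COLUMNS = ("snp", "chrom", "pos", "effect_allele", "freq")


def covariate_columns(phenotypes: pd.DataFrame) -> list[str]:
    """Names of the covariate columns of a phenotype table, in order."""
    return [c for c in phenotypes.columns if c.startswith("covariate_")]


def validate_phenotypes(phenotypes: pd.DataFrame) -> None:
    """Raise :class:`FormatError` naming the first missing core column."""
    for col in PHENO_CORE_COLUMNS:
        if col not in phenotypes.columns:
            raise FormatError(f"phenotype table is missing required column {col!r}")


@dataclass
class GenotypeMatrix:
    """Offspring dosages of the counted allele, variants x subjects.

    Parameters
    ----------
    dosages
        Array of shape (n_variants, n_subjects); values in [0, 2], NaN for
        missing calls.
    subjects
        Subject ids, one per column.
    variants
        Per-variant metadata with columns ``snp, chrom, pos, effect_allele,
        freq`` (``freq`` is the counted-allele frequency used at simulation
        time and may be NaN for ingested data).
    """

    dosages: np.ndarray
    subjects: np.ndarray
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subjects = np.asarray(self.subjects)
        if self.dosages.ndim != 2:
            raise FormatError("dosages must be a 2-d (variants x subjects) array")
        if self.dosages.shape[1] != len(self.subjects):
            raise AlignmentError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.subjects)} subject ids"
            )
        if len(self.variants) != self.dosages.shape[0]:
            raise AlignmentError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.variants)} variant records"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise FormatError(f"variant table is missing columns {missing}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise FormatError("dosages must lie in [0, 2]")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.variants["snp"].to_numpy()

    def subset_subjects(self, subject_ids) -> "GenotypeMatrix":
        """Columns re-ordered/subset to ``subject_ids`` (error if any are absent)."""
        index = pd.Index(self.subjects)
        locs = index.get_indexer(pd.Index(subject_ids))
        if (locs < 0).any():
            n_missing = int((locs < 0).sum())
            raise AlignmentError(f"{n_missing} requested subject ids absent from genotype matrix")
        return GenotypeMatrix(self.dosages[:, locs], np.asarray(subject_ids), self.variants.copy())

    def subset_variants(self, snp_ids) -> "GenotypeMatrix":
        index = pd.Index(self.variants["snp"])
        locs = index.get_indexer(pd.Index(snp_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(snp_ids, locs) if l < 0]
            raise AlignmentError(f"variants absent from genotype matrix: {missing}")
        return GenotypeMatrix(
            self.dosages[locs], self.subjects, self.variants.iloc[locs].reset_index(drop=True)
        )

    def dosage_for(self, snp_id: str) -> np.ndarray:
        """Dosage row for a single variant id."""
        return self.subset_variants([snp_id]).dosages[0]
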