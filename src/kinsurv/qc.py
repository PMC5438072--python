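"""Phenotype exclusion rules with an auditable tally.

Subjects and parent records are excluded in a fixed precedence order, each
subject counted once under the first rule it triggers:

1. adopted offspring (parental genotype unrelated to offspring genotype);
2. no usable parental data (no parent records, or every parent dead before 40);
3. implausible parent age (> 115 years) — excludes the whole subject;
4. missing covariate — excludes the whole subject;
5. a single parent death before age 40 — excludes that parent *record* only
   (the phenotype is survival from 40, and early deaths are dominated by
   accidents and war).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import covariate_columns, validate_phenotypes

MAX_VALID_AGE = 115.0
MIN_DEATH_AGE = 40.0


@dataclass
class ExclusionTally:
    """Counts of excluded subjects/records; reconciles exactly with the input."""

    subjects_in: int
    adopted: int
    missing_parent_data: int
    invalid_age: int
    missing_covariate: int
    pre40_parent_records: int
    subjects_remaining: int
    records_remaining: int

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def subjects_excluded(self) -> int:
        return self.adopted + self.missing_parent_data + self.invalid_age + self.missing_covariate

    def check(self) -> None:
        assert self.subjects_in == self.subjects_remaining + self.subjects_excluded


def apply_exclusions(raw: pd.DataFrame):
    """Apply the exclusion rules to a parent-record phenotype table.

    Returns ``(clean, tally)``; ``clean`` preserves the input row order and
    dtypes and contains only records usable for survival-from-40 analysis.
    """
    validate_phenotypes(raw)
    cov_cols = covariate_columns(raw)
    if raw.empty:
        tally = ExclusionTally(0, 0, 0, 0, 0, 0, 0, 0)
        return raw.copy(), tally

    by_subject = raw.groupby("subject_id", sort=False)
    subjects_in = by_subject.ngroups

    pre40_record = (raw["observed_age"] < MIN_DEATH_AGE) | (
        (raw["observed_age"] == MIN_DEATH_AGE) & (raw["event"] == 0)
    )
    invalid_record = raw["observed_age"] > MAX_VALID_AGE
    if "age_valid" in raw.columns:
        invalid_record |= ~raw["age_valid"].astype(bool)
    missing_cov_record = (
        raw[cov_cols].isna().any(axis=1) if cov_cols else pd.Series(False, index=raw.index)
    )

    per_subject = pd.DataFrame(
        {
            "adopted": raw["adopted"].astype(bool) if "adopted" in raw.columns else False,
            "pre40": pre40_record,
            "invalid": invalid_record,
            "missing_cov": missing_cov_record,
        },
        index=raw.index,
    )
    per_subject["subject_id"] = raw["subject_id"].to_numpy()
    agg = per_subject.groupby("subject_id", sort=False).agg(
        adopted=("adopted", "any"),
        all_pre40=("pre40", "all"),
        any_invalid=("invalid", "any"),
        any_missing_cov=("missing_cov", "any"),
    )

    # precedence: adopted -> missing parental data -> invalid age -> missing covariate
    rule_adopted = agg["adopted"]
    rule_missing_data = agg["all_pre40"] & ~rule_adopted
    rule_invalid = agg["any_invalid"] & ~rule_adopted & ~rule_missing_data
    rule_missing_cov = (
        agg["any_missing_cov"] & ~rule_adopted & ~rule_missing_data & ~rule_invalid
    )
    subject_excluded = rule_adopted | rule_missing_data | rule_invalid | rule_missing_cov

    excluded_ids = agg.index[subject_excluded]
    keep_record = ~raw["subject_id"].isin(excluded_ids) & ~pre40_record
    pre40_count = int(
        (pre40_record & ~raw["subject_id"].isin(excluded_ids)).sum()
    )

    clean = raw.loc[keep_record].copy()
    tally = ExclusionTally(
        subjects_in=subjects_in,
        adopted=int(rule_adopted.sum()),
        missing_parent_data=int(rule_missing_data.sum()),
        invalid_age=int(rule_invalid.sum()),
        missing_covariate=int(rule_missing_cov.sum()),
        pre40_parent_records=pre40_count,
        subjects_remaining=int(clean["subject_id"].nunique()),
        records_remaining=len(clean),
    )
    tally.check()
    return clean, tally
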