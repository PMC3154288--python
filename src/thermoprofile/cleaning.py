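"""Data cleaning and min-max normalization.

Cleaning runs in a fixed order: duplicate records, then low-variation
("useless") attributes, then highly correlated attributes. The standard
deviation filter operates on raw (pre-normalization) values; the correlation
filter scans attribute pairs in schema order and drops the later member of
any pair with |Pearson r| above the threshold — an attribute that has been
dropped is never used to drop others, so the rule is a deterministic greedy
keep-earlier policy.

Min-max parameters are fitted once on a training table and can be re-applied
to new data; re-applied values falling outside the fitted range are clipped
to [0, 1] so published thresholds stay applicable to fresh sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable


@dataclass
class CleaningConfig:
    sd_threshold: float = 0.1
    corr_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.sd_threshold < 0 or self.corr_threshold < 0:
            raise ValueError("cleaning thresholds must be >= 0")


@dataclass
class CleaningReport:
    removed_duplicate_records: list[str] = field(default_factory=list)
    removed_useless: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_records_before: int = 0
    n_records_after: int = 0
    n_attributes_before: int = 0
    n_attributes_after: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_duplicate_records": list(self.removed_duplicate_records),
            "removed_useless": list(self.removed_useless),
            "removed_correlated": [
                {"dropped": d, "kept": k, "r": r} for d, k, r in self.removed_correlated
            ],
            "n_records_before": self.n_records_before,
            "n_records_after": self.n_records_after,
            "n_attributes_before": self.n_attributes_before,
            "n_attributes_after": self.n_attributes_after,
        }


def remove_duplicate_records(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Drop records identical in all numeric attributes (first kept)."""
    if table.n_records == 0:
        raise ValueError("empty table")
    dup_mask = table.values.duplicated(keep="first")
    removed = list(table.values.index[dup_mask])
    keep = np.flatnonzero(~dup_mask.to_numpy())
    return table.take(keep), removed


def remove_useless_attributes(
    table: FeatureTable, sd_threshold: float = 0.1
) -> tuple[FeatureTable, list[str]]:
    """Drop numeric attributes with sample SD <= threshold (raw values)."""
    if table.n_records < 2:
        raise ValueError("need at least 2 records to estimate SDs")
    sds = table.values.std(ddof=1)
    removed = list(sds.index[sds <= sd_threshold])
    kept = [a for a in table.attributes if a not in set(removed)]
    return table.select(kept), removed


def remove_correlated_attributes(
    table: FeatureTable, corr_threshold: float = 0.9
) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Greedy keep-earlier scan dropping the later of any |r|>threshold pair."""
    cols = table.attributes
    x = table.matrix()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dropped: set[int] = set()
    removals: list[tuple[str, str, float]] = []
    p = len(cols)
    for i in range(p):
        if i in dropped:
            continue
        for j in range(i + 1, p):
            if j in dropped:
                continue
            r = corr[i, j]
            if abs(r) > corr_threshold:
                dropped.add(j)
                removals.append((cols[j], cols[i], float(r)))
    kept = [cols[i] for i in range(p) if i not in dropped]
    return table.select(kept), removals


def clean(
    table: FeatureTable, config: CleaningConfig | None = None
) -> tuple[FeatureTable, CleaningReport]:
    """Duplicates -> useless -> correlated, with a consolidated report."""
    config = config or CleaningConfig()
    report = CleaningReport(
        n_records_before=table.n_records, n_attributes_before=table.n_attributes
    )
    table, report.removed_duplicate_records = remove_duplicate_records(table)
    table, report.removed_useless = remove_useless_attributes(
        table, config.sd_threshold
    )
    table, report.removed_correlated = remove_correlated_attributes(
        table, config.corr_threshold
    )
    report.n_records_after = table.n_records
    report.n_attributes_after = table.n_attributes
    return table, report


@dataclass
class MinMaxParams:
    minima: pd.Series
    maxima: pd.Series

    def __post_init__(self) -> None:
        if (self.maxima < self.minima).any():
            raise ValueError("max < min in normalization parameters")

    def to_dict(self) -> dict:
        return {
            "min": self.minima.to_dict(),
            "max": self.maxima.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxParams":
        return cls(pd.Series(d["min"]), pd.Series(d["max"]))


def fit_min_max(table: FeatureTable) -> MinMaxParams:
    if table.n_records < 2:
        raise ValueError("need at least 2 records to fit min-max parameters")
    return MinMaxParams(table.values.min(), table.values.max())


def apply_min_max(table: FeatureTable, params: MinMaxParams) -> FeatureTable:
    """Rescale to (x - min)/(max - min), clipping new data into [0, 1]."""
    mins = params.minima.reindex(table.attributes)
    maxs = params.maxima.reindex(table.attributes)
    if mins.isna().any():
        missing = list(mins.index[mins.isna()])
        raise KeyError(f"no normalization parameters for attribute(s) {missing}")
    span = maxs - mins
    if (span == 0).any():
        degenerate = list(span.index[span == 0])
        raise ValueError(
            f"max == min for attribute(s) {degenerate}; remove as useless first"
        )
    out = table.copy()
    out.values = ((table.values - mins) / span).clip(0.0, 1.0)
    return out


def normalize(table: FeatureTable) -> tuple[FeatureTable, MinMaxParams]:
    params = fit_min_max(table)
    return apply_min_max(table, params), params
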