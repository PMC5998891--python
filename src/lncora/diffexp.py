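"""Differential-expression filtering on replicate FPKM tables.

Three rules, applied in order: (1) replicate-variability filter (drop
features whose replicate coefficient of variation exceeds the threshold
in either condition), (2) fold-change filter (|signed fold change| must
exceed the threshold), (3) expression floor (up-regulated features need
mean case FPKM >= floor; down-regulated need mean control FPKM >= floor).

Signed fold change is the ratio of condition means reported as r when
r >= 1 and -1/r otherwise, so symmetric thresholds (+/-1.5) apply.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lncora.errors import ConfigError

logger = logging.getLogger(__name__)

ALL_FILTERS = frozenset({"variability", "fold_change", "low_fpkm"})

#: sentinel fold changes for zero-denominator features
INF_UP = math.inf
INF_DOWN = -math.inf


@dataclass
class ExpressionTable:
    """FPKM values per feature per sample, split into case/control."""

    values: pd.DataFrame  # features x samples
    conditions: dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        bad = set(self.conditions.values()) - {"case", "control"}
        if bad:
            raise ConfigError(f"unknown condition labels: {sorted(bad)}")
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ConfigError(f"samples without condition label: {sorted(missing)}")
        for cond in ("case", "control"):
            if not self.samples(cond):
                raise ConfigError(f"no samples labelled {cond!r}")
        if self.values.isna().any().any():
            raise ConfigError("expression table contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ConfigError("FPKM values must be non-negative")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def replicate_values(self, feature_id: str, condition: str) -> np.ndarray:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature: {feature_id}")
        return self.values.loc[feature_id, self.samples(condition)].to_numpy(float)

    @classmethod
    def from_files(cls, expression_tsv, conditions_tsv) -> "ExpressionTable":
        """Load from a TSV with a ``feature_id`` + sample columns and a
        two-column ``sample<TAB>condition`` map."""
        values = pd.read_csv(expression_tsv, sep="\t", index_col=0, comment="#")
        cond_df = pd.read_csv(
            conditions_tsv, sep="\t", header=None, names=["sample", "condition"],
            comment="#",
        )
        if list(cond_df.columns) and cond_df.iloc[0]["sample"] == "sample":
            cond_df = cond_df.iloc[1:]
        conditions = dict(zip(cond_df["sample"], cond_df["condition"]))
        return cls(values=values, conditions=conditions)


@dataclass
class DEConfig:
    """Filter thresholds. Defaults reproduce the FPKM filtering rules:
    CV <= 15%, |fold change| > 1.5, mean FPKM >= 1 in the up-regulated
    condition."""

    fold_change_threshold: float = 1.5
    min_fpkm: float = 1.0
    max_replicate_cv: float = 0.15
    active_filters: frozenset[str] = ALL_FILTERS
    # per-condition: either condition failing CV => filtered; pooled: all
    # replicates of both conditions together
    cv_scope: str = "per_condition"

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 1:
            raise ConfigError("fold_change_threshold must be > 1")
        if self.min_fpkm < 0:
            raise ConfigError("min_fpkm must be >= 0")
        if not (0 < self.max_replicate_cv <= 1):
            raise ConfigError("max_replicate_cv must be in (0, 1]")
        unknown = set(self.active_filters) - ALL_FILTERS
        if unknown:
            raise ConfigError(f"unknown filters: {sorted(unknown)}")
        if self.cv_scope not in {"per_condition", "pooled"}:
            raise ConfigError(f"unknown cv_scope: {self.cv_scope!r}")
        object.__setattr__(self, "active_filters", frozenset(self.active_filters))


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    mean_case: float
    mean_control: float
    signed_fc: float  # may be +/-inf (zero denominator) or nan (both zero)
    status: str  # de_up | de_down | filtered
    filter_reason: str  # variability | fold_change | low_fpkm | none


def condition_means(table: ExpressionTable, feature_id: str) -> tuple[float, float]:
    """Arithmetic mean of replicate FPKMs, (case, control)."""
    case = table.replicate_values(feature_id, "case")
    control = table.replicate_values(feature_id, "control")
    return float(case.mean()), float(control.mean())


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Ratio of means in signed convention: r if r >= 1, else -1/r.

    Zero denominators give +/-inf; both zero gives nan (the feature is
    caught by the expression floor under the default config).
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("means must be non-negative")
    if mean_case == 0 and mean_control == 0:
        return math.nan
    if mean_control == 0:
        return INF_UP
    if mean_case == 0:
        return INF_DOWN
    r = mean_case / mean_control
    return r if r >= 1 else -1.0 / r


def replicate_cv(values) -> float:
    """Sample standard deviation divided by the mean.

    Needs >= 2 values; a zero mean returns nan (the feature then fails
    the variability filter).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("replicate_cv needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return float(arr.std(ddof=1) / mean)


def _fails_variability(table: ExpressionTable, feature_id: str, config: DEConfig) -> bool:
    if config.cv_scope == "pooled":
        pooled = np.concatenate(
            [
                table.replicate_values(feature_id, "case"),
                table.replicate_values(feature_id, "control"),
            ]
        )
        cv = replicate_cv(pooled)
        return math.isnan(cv) or cv > config.max_replicate_cv
    for cond in ("case", "control"):
        cv = replicate_cv(table.replicate_values(feature_id, cond))
        if math.isnan(cv) or cv > config.max_replicate_cv:
            return True
    return False


def classify_feature(
    table: ExpressionTable, feature_id: str, config: DEConfig
) -> DEResult:
    """Apply the filter cascade to one feature."""
    mean_case, mean_control = condition_means(table, feature_id)
    fc = signed_fold_change(mean_case, mean_control)

    if "variability" in config.active_filters and _fails_variability(
        table, feature_id, config
    ):
        return DEResult(feature_id, mean_case, mean_control, fc, "filtered", "variability")

    fc_threshold = (
        config.fold_change_threshold if "fold_change" in config.active_filters else 1.0
    )
    if math.isnan(fc) or abs(fc) <= fc_threshold:
        return DEResult(feature_id, mean_case, mean_control, fc, "filtered", "fold_change")

    floor = config.min_fpkm if "low_fpkm" in config.active_filters else 0.0
    if fc > 0:
        if mean_case < floor:
            return DEResult(
                feature_id, mean_case, mean_control, fc, "filtered", "low_fpkm"
            )
        return DEResult(feature_id, mean_case, mean_control, fc, "de_up", "none")
    if mean_control < floor:
        return DEResult(feature_id, mean_case, mean_control, fc, "filtered", "low_fpkm")
    return DEResult(feature_id, mean_case, mean_control, fc, "de_down", "none")


def filter_de(table: ExpressionTable, config: DEConfig | None = None) -> list[DEResult]:
    """Classify every feature in the table; deterministic and independent
    of input row order (results come back in table order)."""
    if config is None:
        config = DEConfig()
    if "variability" in config.active_filters:
        for cond in ("case", "control"):
            n_reps = len(table.samples(cond))
            if config.cv_scope == "per_condition" and n_reps < 2:
                raise ConfigError(
                    f"variability filter needs >= 2 replicates in {cond!r}, "
                    f"got {n_reps}"
                )
    results = [classify_feature(table, fid, config) for fid in table.feature_ids]
    counts: dict[str, int] = {}
    for r in results:
        counts[r.status] = counts.get(r.status, 0) + 1
    logger.info("filter_de: %s", counts)
    return results


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    """DEResult list -> output table (feature_id, means, fc, status, reason)."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "signed_fc": r.signed_fc,
                "status": r.status,
                "filter_reason": r.filter_reason,
            }
            for r in results
        ],
        columns=[
            "feature_id", "mean_case", "mean_control",
            "signed_fc", "status", "filter_reason",
        ],
    )


def de_feature_ids(results: list[DEResult]) -> set[str]:
    """Identifiers with status de_up or de_down."""
    return {r.feature_id for r in results if r.status in ("de_up", "de_down")}
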