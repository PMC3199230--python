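"""Feature filtering, coefficient-of-variation selection, lobe-pair collapsing.

These are the steps applied to a log2 expression matrix before any
supervised or unsupervised analysis: drop unannotated / lowly expressed
features, optionally keep only the most variable genes for unsupervised
views, and reduce paired upper/lower-lobe samples to one sample per patient
so downstream models see independent observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, PhenotypeTable

__all__ = ["FilterReport", "filter_features", "select_top_cov",
           "collapse_lobe_pairs"]


@dataclass
class FilterReport:
    n_input: int
    n_dropped_unannotated: int
    n_dropped_low_expression: int
    n_retained: int

    def __post_init__(self) -> None:
        dropped = self.n_dropped_unannotated + self.n_dropped_low_expression
        if self.n_input != self.n_retained + dropped:
            raise ValueError("filter report counts inconsistent")


def filter_features(X: ExpressionMatrix, min_mean: float = 4.0
                    ) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep annotated features whose mean log2 expression is strictly > min_mean.

    Unannotated features are dropped first; among annotated features the
    mean across all samples must exceed the threshold (strict inequality,
    so boundary features are dropped).
    """
    means = X.values.mean(axis=1)
    keep, n_unann, n_low = [], 0, 0
    for i, f in enumerate(X.feature_ids):
        if not X.annotation.get(f):
            n_unann += 1
        elif not means[i] > min_mean:
            n_low += 1
        else:
            keep.append(f)
    if not keep:
        raise ValueError(
            f"no features pass the filter (min_mean={min_mean}); "
            "review the threshold or the annotation"
        )
    report = FilterReport(X.n_features, n_unann, n_low, len(keep))
    return X.subset_features(keep), report


def select_top_cov(X: ExpressionMatrix, fraction: float = 0.10
                   ) -> ExpressionMatrix:
    """Keep the ceil(fraction * n) features with largest coefficient of variation.

    CoV = sample sd / mean, computed on the log2 values; ties broken
    stably by input order.  Requires all feature means > 0 (guaranteed
    after `filter_features` with min_mean >= 0 on the log2 scale).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    means = X.values.mean(axis=1)
    if np.any(means <= 0):
        bad = X.feature_ids[int(np.argmax(means <= 0))]
        raise ValueError(f"non-positive mean for feature {bad!r}; CoV undefined")
    sds = X.values.std(axis=1, ddof=1)
    cov = sds / means
    n_keep = math.ceil(fraction * X.n_features)
    # stable: sort by (-cov, input order)
    order = np.lexsort((np.arange(X.n_features), -cov))[:n_keep]
    order = np.sort(order)  # preserve input order among the selected
    return X.subset_features([X.feature_ids[i] for i in order])


def collapse_lobe_pairs(X: ExpressionMatrix, pheno: PhenotypeTable,
                        prefer: str = "upper"
                        ) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Keep exactly one sample per patient, preferring the given lobe.

    Patients with a single sample pass through unchanged; for lobe pairs
    the preferred lobe is kept when present.  Two samples of the same
    patient and same lobe are ambiguous and rejected.
    """
    if prefer not in ("upper", "lower"):
        raise ValueError("prefer must be 'upper' or 'lower'")
    df = pheno.table
    missing = set(X.sample_ids) - set(df["sample_id"])
    if missing:
        raise ValueError(f"phenotype table lacks samples: {sorted(missing)[:5]}")
    df = df[df["sample_id"].isin(X.sample_ids)]
    keep: list[str] = []
    for _, sub in df.groupby("patient_id", sort=False):
        if len(sub) == 1:
            keep.append(sub["sample_id"].iloc[0])
            continue
        if sub["lobe"].duplicated().any():
            dup = sub["lobe"][sub["lobe"].duplicated()].iloc[0]
            raise ValueError(
                f"patient {sub['patient_id'].iloc[0]!r} has two "
                f"{dup!r}-lobe samples; ambiguous"
            )
        preferred = sub[sub["lobe"] == prefer]
        keep.append((preferred if len(preferred) else sub)["sample_id"].iloc[0])
    keep = [s for s in X.sample_ids if s in set(keep)]  # preserve matrix order
    return X.subset_samples(keep), pheno.subset(keep)
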