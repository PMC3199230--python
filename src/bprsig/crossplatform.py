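"""Cross-platform signature transfer.

A signature trained on one microarray platform is applied to a cohort
measured on another by (1) linking features across platforms through shared
gene identifiers (many-by-many), (2) averaging linked validation features
into the training feature space, (3) scale/shift normalizing each feature
to the training cohort's first two moments, and (4) projecting onto the
training-only SVD loadings, so validation predictions never touch training
labels or refit anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bpr import GeneSignatureResults
from .io import ExpressionMatrix
from .simulate import FeatureMapping

__all__ = ["MappingReport", "derive_mapping", "map_expression",
           "scale_shift_normalize", "project_validation", "transfer_predict"]


@dataclass
class MappingReport:
    n_signature_features: int
    n_mapped: int
    unmapped: list[str] = field(default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        if self.n_signature_features == 0:
            return 0.0
        return self.n_mapped / self.n_signature_features


def derive_mapping(annotation_train: dict[str, set[str]],
                   annotation_val: dict[str, set[str]]) -> FeatureMapping:
    """Link every train/validation feature pair sharing >= 1 gene identifier."""
    if not annotation_train or not annotation_val:
        raise ValueError("both annotations must be nonempty")
    by_gene: dict[str, list[str]] = {}
    for vid, genes in annotation_val.items():
        for g in genes:
            by_gene.setdefault(g, []).append(vid)
    links: set[tuple[str, str]] = set()
    for tid, genes in annotation_train.items():
        for g in genes:
            for vid in by_gene.get(g, ()):
                links.add((tid, vid))
    return FeatureMapping(links=links, provenance="gene-id")


def map_expression(X_val: ExpressionMatrix, mapping: FeatureMapping,
                   signature_features: list[str], aggregate: str = "mean"
                   ) -> tuple[ExpressionMatrix, MappingReport]:
    """Express validation samples in training-feature space.

    Each signature feature's value is the unweighted mean (or median) of
    all linked validation features; features with no link are excluded and
    reported.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    col = {f: i for i, f in enumerate(X_val.feature_ids)}
    by_train: dict[str, list[int]] = {}
    for t, v in mapping.links:
        if v in col:
            by_train.setdefault(t, []).append(col[v])
    rows, kept, unmapped = [], [], []
    agg = np.mean if aggregate == "mean" else np.median
    for f in signature_features:
        idx = by_train.get(f)
        if not idx:
            unmapped.append(f)
            continue
        rows.append(agg(X_val.values[sorted(idx)], axis=0))
        kept.append(f)
    if not kept:
        raise ValueError("no signature feature maps to the validation platform")
    report = MappingReport(len(signature_features), len(kept), unmapped)
    mapped = ExpressionMatrix(kept, list(X_val.sample_ids), np.vstack(rows),
                              {f: set() for f in kept})
    return mapped, report


def scale_shift_normalize(X_val_mapped: ExpressionMatrix,
                          training_stats: dict[str, tuple[float, float]]
                          ) -> tuple[ExpressionMatrix, list[str]]:
    """Match each feature's validation-cohort mean/sd to the training stats.

    Per feature: z-score with the validation cohort's own mean/sd, then
    rescale to the training feature's mean/sd.  Zero-variance validation
    features cannot be normalized and are dropped (returned for reporting).
    """
    keep, rows, dropped = [], [], []
    for i, f in enumerate(X_val_mapped.feature_ids):
        if f not in training_stats:
            raise KeyError(f"no training stats for feature {f!r}")
        vals = X_val_mapped.values[i]
        sd = vals.std(ddof=1)
        if sd <= 0:
            dropped.append(f)
            continue
        tr_mean, tr_sd = training_stats[f]
        rows.append((vals - vals.mean()) / sd * tr_sd + tr_mean)
        keep.append(f)
    if not keep:
        raise ValueError("every mapped feature has zero variance")
    out = ExpressionMatrix(keep, list(X_val_mapped.sample_ids),
                           np.vstack(rows), {f: set() for f in keep})
    return out, dropped


def project_validation(results: GeneSignatureResults,
                       X_val_norm: ExpressionMatrix,
                       method: str = "mean_prob"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Factor scores and probabilities through training-only loadings.

    Missing signature features are handled by least-squares projection on
    the available loading rows (pseudo-inverse), which coincides with the
    training-time score formula S^-1 U' x~ at full coverage.
    """
    basis = results.basis
    avail = [f for f in basis.feature_ids if f in set(X_val_norm.feature_ids)]
    if len(avail) < basis.n_factors:
        raise ValueError("fewer mapped features than factors")
    idx = {f: i for i, f in enumerate(basis.feature_ids)}
    rows = [idx[f] for f in avail]
    sub = X_val_norm.subset_features(avail)
    xt = (sub.values - basis.center[rows][:, None]) / basis.scale[rows][:, None]
    U_avail = basis.loadings[rows]
    w, *_ = np.linalg.lstsq(U_avail, xt, rcond=None)  # r x samples
    scores = (w / basis.singular_values[:, None]).T
    probs = results.predict_from_scores(scores, method)
    return scores, probs


def transfer_predict(results: GeneSignatureResults,
                     X_val: ExpressionMatrix,
                     mapping: FeatureMapping,
                     aggregate: str = "mean",
                     method: str = "mean_prob") -> dict:
    """Chain map -> normalize -> project -> predict for a validation cohort."""
    basis = results.basis
    mapped, report = map_expression(X_val, mapping, basis.feature_ids,
                                    aggregate)
    stats_by_feature = {
        f: (float(basis.center[i]), float(basis.scale[i]))
        for i, f in enumerate(basis.feature_ids)
    }
    norm, dropped = scale_shift_normalize(mapped, stats_by_feature)
    scores, probs = project_validation(results, norm, method)
    return {"scores": scores, "probabilities": probs,
            "mapping_report": report, "dropped_zero_variance": dropped,
            "sample_ids": list(X_val.sample_ids)}
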