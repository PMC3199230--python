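"""Differential expression.

Per-feature two-sample Student t-tests for gene ranking, empirical-Bayes
moderated t-statistics (unpaired two-group and paired one-sample designs)
with hierarchical variance shrinkage, Benjamini-Hochberg FDR adjustment,
and p-value histogram diagnostics.

The moderated test places a scaled inverse-chi-square prior on the
per-feature residual variance: the posterior variance is a weighted
combination s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), and the t-statistic
formed with s~_g has d0 + d_g degrees of freedom.  The hyperparameters
(d0, s0^2) are estimated by method of moments on log s_g^2 using
digamma/trigamma matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats, optimize

from .io import ExpressionMatrix

__all__ = ["DiffExprResult", "student_t_rank", "moderated_t", "bh_adjust",
           "pvalue_histogram"]


@dataclass
class DiffExprResult:
    """Per-feature differential-expression statistics.

    ``table`` columns: feature, effect (mean difference on the contrast),
    t, df, p, q.  ``d0``/``s0_sq`` are the prior df and prior variance of
    the variance-shrinkage model (None for plain Student tests).
    """

    table: pd.DataFrame
    d0: float | None = None
    s0_sq: float | None = None

    def top_features(self, k: int) -> list[str]:
        """The k features with largest |t| (stable ties by input order)."""
        df = self.table
        order = np.lexsort((np.arange(len(df)), -df["t"].abs().to_numpy()))
        return [df["feature"].iloc[i] for i in order[:k]]


def _two_sample_arrays(X: ExpressionMatrix, y: np.ndarray,
                       min_per_class: int = 1):
    y = np.asarray(y).astype(int)
    if y.shape[0] != X.n_samples:
        raise ValueError("labels length does not match sample count")
    g1, g0 = X.values[:, y == 1], X.values[:, y == 0]
    # pooled t needs >= 1 residual df; a singleton class is tolerated (it
    # contributes no variance) so that minimal leave-one-out folds still run
    if (g1.shape[1] < min_per_class or g0.shape[1] < min_per_class
            or g1.shape[1] + g0.shape[1] < 3):
        raise ValueError("too few samples per class for a pooled t-test")
    return g0, g1


def student_t_rank(X: ExpressionMatrix, y: np.ndarray) -> DiffExprResult:
    """Pooled-variance two-sample Student t per feature, ranked by |t|.

    Effect = mean(class 1) - mean(class 0); a positive t indicates
    up-regulation in class 1.
    """
    g0, g1 = _two_sample_arrays(X, y)
    n0, n1 = g0.shape[1], g1.shape[1]
    effect = g1.mean(axis=1) - g0.mean(axis=1)
    ss0 = np.sum((g0 - g0.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ss1 = np.sum((g1 - g1.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df = n0 + n1 - 2
    sp2 = (ss0 + ss1) / df
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame({
        "feature": X.feature_ids, "effect": effect, "t": t,
        "df": float(df), "p": p, "q": bh_adjust(p),
    })
    order = np.lexsort((np.arange(len(table)), -np.abs(t)))
    return DiffExprResult(table.iloc[order].reset_index(drop=True))


def _fit_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-feature variances.

    Works on z_g = log s_g^2: under the hierarchical model z_g has variance
    trigamma(d_g/2) + trigamma(d0/2).  Solve trigamma(d0/2) = var(z) -
    trigamma(d_g/2); when the right side is <= 0 the prior df is infinite
    (all spread explained by sampling noise) and s0^2 is the bias-corrected
    mean of log variances.
    """
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero; prior undefined")
    z = np.log(pos)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    ebar = float(np.mean(e))
    target = float(np.var(e, ddof=1)) * (len(e) - 1) / len(e) - \
        float(special.polygamma(1, dg / 2.0))
    if target <= 0 or len(e) < 2:
        # no excess spread beyond sampling noise: infinite prior df, and the
        # common variance is the plain average so constant-variance inputs
        # shrink to themselves (moderated t == ordinary t there)
        return np.inf, float(np.mean(pos))
    # invert trigamma(d0/2) = target
    sol = optimize.brentq(
        lambda x: special.polygamma(1, x) - target, 1e-6, 1e8)
    d0 = 2.0 * sol
    s0_sq = float(np.exp(ebar + special.digamma(sol) - np.log(sol)))
    return d0, s0_sq


def moderated_t(X: ExpressionMatrix, y: np.ndarray | None = None,
                design: str = "unpaired",
                pairs: list[str] | None = None) -> DiffExprResult:
    """Empirical-Bayes moderated t-test.

    unpaired: two-group comparison coded by ``y`` (effect = group1 - group0).
    paired: one-sample test on within-pair differences; ``pairs`` gives the
    pairing ID per sample and ``y`` codes the within-pair contrast arm
    (difference = arm1 - arm0 per pair).
    Zero residual variances are floored at the smallest positive variance
    and flagged in the output column ``var_floored``.
    """
    if design == "unpaired":
        g0, g1 = _two_sample_arrays(X, np.asarray(y), min_per_class=2)
        n0, n1 = g0.shape[1], g1.shape[1]
        effect = g1.mean(axis=1) - g0.mean(axis=1)
        dg = n0 + n1 - 2
        s2 = ((g0.var(axis=1, ddof=1) * (n0 - 1)
               + g1.var(axis=1, ddof=1) * (n1 - 1)) / dg)
        c = 1.0 / n0 + 1.0 / n1
    elif design == "paired":
        if pairs is None or y is None:
            raise ValueError("paired design requires pairs and arm labels")
        y = np.asarray(y).astype(int)
        pair_ids = sorted(set(pairs))
        diffs = []
        for pid in pair_ids:
            idx = [i for i, p in enumerate(pairs) if p == pid]
            if len(idx) != 2 or {y[idx[0]], y[idx[1]]} != {0, 1}:
                raise ValueError(f"pair {pid!r} is incomplete")
            i1 = idx[0] if y[idx[0]] == 1 else idx[1]
            i0 = idx[1] if i1 == idx[0] else idx[0]
            diffs.append(X.values[:, i1] - X.values[:, i0])
        Dm = np.column_stack(diffs)
        npairs = Dm.shape[1]
        if npairs < 2:
            raise ValueError("need at least two complete pairs")
        effect = Dm.mean(axis=1)
        dg = npairs - 1
        s2 = Dm.var(axis=1, ddof=1)
        c = 1.0 / npairs
    else:
        raise ValueError("design must be 'unpaired' or 'paired'")

    floored = s2 <= 0
    if floored.all():
        raise ValueError("all residual variances are zero; prior undefined")
    if floored.any():
        s2 = np.where(floored, np.min(s2[~floored]), s2)

    d0, s0_sq = _fit_variance_prior(s2, float(dg))
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    t = effect / np.sqrt(s2_tilde * c)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame({
        "feature": X.feature_ids, "effect": effect, "t": t,
        "df": df_total, "p": p, "q": bh_adjust(p),
        "var_floored": floored,
    })
    return DiffExprResult(table, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} (n / j) p_(j), capped at 1, returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def pvalue_histogram(p_values, bin_width: float = 0.05) -> dict:
    """Histogram of p-values plus the excess mass below 0.05 over uniform."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(p, bins=edges)
    n = len(p)
    below = int(np.sum(p < 0.05))
    excess = (below - n * 0.05) / n if n else 0.0
    return {"bin_edges": edges, "counts": counts, "n": n,
            "excess_below_0.05": float(excess)}
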