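"""SVD-factor Bayesian probit regression signatures.

The classifier at the core of the package: select the top-k genes by
two-sample Student t, standardize them with training means/sds, decompose
the standardized k x n matrix by SVD, and regress the binary phenotype on
the first r right-singular-vector scores ("metagene factors", r = 2 by
default) with a Bayesian probit model

    Pr(y_i = 1) = Phi(beta_0 + f_i' beta),   beta ~ Normal(0, V),

sampled by the classic latent-variable Gibbs scheme (truncated-normal
latents given beta; conjugate multivariate-normal beta given latents).
Model size k is tuned by leave-one-out cross-validation using the sum of
deviances, with the misclassification rate reported alongside.

Organised statsmodels-style: :class:`GeneSignatureModel` is constructed
from data and ``fit()`` returns a :class:`GeneSignatureResults` carrying
the frozen signature (features, centers/scales, loadings, posterior draws)
with ``predict_proba`` and ``summary``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import ndtr, ndtri

from .diffexpr import student_t_rank
from .io import ExpressionMatrix

__all__ = [
    "FactorBasis", "PosteriorFit", "ModelSelectionTrace",
    "GeneSignatureModel", "GeneSignatureResults",
    "build_factors", "fit_bpr", "predict_probability",
    "loo_evaluate", "tune_model_size", "train_signature",
    "DEFAULT_PRIOR", "DEFAULT_MCMC", "LOO_MCMC",
]

PROB_CLIP = 1e-6

DEFAULT_PRIOR = {"var_intercept": 100.0, "var_coef": 4.0}
DEFAULT_MCMC = {"iterations": 10_000, "burn_in": 2_000, "seed": 0}
#: lighter settings used inside leave-one-out loops
LOO_MCMC = {"iterations": 2_000, "burn_in": 500, "seed": 0}


@dataclass
class FactorBasis:
    """Frozen training-side factor construction.

    feature_ids: the k selected genes; center/scale: training mean and sd
    per gene; loadings U (k x r, orthonormal columns); singular_values S
    (length r, positive nonincreasing).  New-sample factor scores are
    S^-1 U' x~ with x~ the standardized expression vector.
    """

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray

    @property
    def n_factors(self) -> int:
        return int(self.loadings.shape[1])

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center[:, None]) / self.scale[:, None]

    def scores(self, values: np.ndarray) -> np.ndarray:
        """Factor scores (samples x r) for a k x m matrix of raw values."""
        xt = self.standardize(values)
        return (self.loadings.T @ xt).T / self.singular_values


@dataclass
class PosteriorFit:
    """Retained MCMC draws of (intercept, factor coefficients)."""

    draws: np.ndarray  # (n_draws, 1 + r)
    settings: dict

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


@dataclass
class ModelSelectionTrace:
    """Per-candidate-size leave-one-out performance."""

    sizes: list[int]
    sum_deviance: list[float]
    misclassification_rate: list[float]
    chosen_k: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.sizes,
            "sum_deviance": self.sum_deviance,
            "misclassification_rate": self.misclassification_rate,
        })


def build_factors(X: ExpressionMatrix, y: np.ndarray, k: int, r: int = 2
                  ) -> tuple[FactorBasis, np.ndarray]:
    """Select top-k genes by |Student t|, standardize, SVD; return basis + scores."""
    if k > X.n_features:
        raise ValueError(f"k={k} exceeds {X.n_features} available features")
    if r > min(k, X.n_samples):
        raise ValueError("too many factors for the data size")
    ranked = student_t_rank(X, y)
    feats = ranked.top_features(k)
    sub = X.subset_features(feats)
    center = sub.values.mean(axis=1)
    scale = sub.values.std(axis=1, ddof=1)
    if np.any(scale <= 0):
        bad = feats[int(np.argmax(scale <= 0))]
        raise ValueError(f"zero-variance selected feature {bad!r}")
    xt = (sub.values - center[:, None]) / scale[:, None]
    U, s, Vt = np.linalg.svd(xt, full_matrices=False)
    basis = FactorBasis(feats, center, scale, U[:, :r], s[:r])
    scores = Vt[:r].T  # == S^-1 U' x~ per sample
    return basis, scores


def _std_truncnorm_lower(rng: np.random.Generator, a: np.ndarray
                         ) -> np.ndarray:
    """Standard normal truncated to (a, inf), by inverse CDF.

    Two numerically stable branches: the CDF form when a <= 0 and the
    survival form (tail-accurate) when a > 0.
    """
    u = rng.random(a.shape)
    tail = a > 0
    out = np.empty_like(a)
    if np.any(~tail):
        lo_cdf = ndtr(a[~tail])
        out[~tail] = ndtri(lo_cdf + u[~tail] * (1.0 - lo_cdf))
    if np.any(tail):
        out[tail] = -ndtri(u[tail] * ndtr(-a[tail]))
    # guard the measure-zero overflow of the inverse CDF at the boundary
    return np.clip(out, a + 1e-10, 38.0)


def _sample_truncnorm(rng: np.random.Generator, mean: np.ndarray,
                      positive: np.ndarray) -> np.ndarray:
    """Latent z_i ~ Normal(mean_i, 1) truncated to (0, inf) or (-inf, 0)."""
    a = np.where(positive, -mean, mean)
    w = _std_truncnorm_lower(rng, a)
    return np.where(positive, mean + w, mean - w)


def fit_bpr(F: np.ndarray, y: np.ndarray, prior: dict | None = None,
            mcmc: dict | None = None) -> PosteriorFit:
    """Albert-Chib Gibbs sampler for the probit model on factor scores.

    F: (n x r) factor scores; y: binary labels (both classes required);
    prior: independent zero-mean normal variances for intercept and each
    factor coefficient; mcmc: iterations, burn_in, seed.
    """
    prior = {**DEFAULT_PRIOR, **(prior or {})}
    mcmc = {**DEFAULT_MCMC, **(mcmc or {})}
    F = np.asarray(F, dtype=float)
    y = np.asarray(y).astype(int)
    if F.ndim != 2 or F.shape[0] != y.shape[0]:
        raise ValueError("F must be (n_samples x r) aligned with y")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite factor scores")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    n, r = F.shape
    W = np.column_stack([np.ones(n), F])
    v = np.concatenate([[prior["var_intercept"]], np.full(r, prior["var_coef"])])
    A = W.T @ W + np.diag(1.0 / v)
    cho = linalg.cho_factor(A, lower=True)
    L = np.linalg.cholesky(np.linalg.inv(A))  # for correlated draws

    iters, burn = int(mcmc["iterations"]), int(mcmc["burn_in"])
    if burn >= iters:
        raise ValueError("burn_in must be smaller than iterations")
    rng = np.random.default_rng(int(mcmc["seed"]))
    beta = np.zeros(1 + r)
    pos = y == 1
    draws = np.empty((iters - burn, 1 + r))
    for it in range(iters):
        eta = W @ beta
        z = _sample_truncnorm(rng, eta, pos)
        mu = linalg.cho_solve(cho, W.T @ z)
        beta = mu + L @ rng.standard_normal(1 + r)
        if it >= burn:
            draws[it - burn] = beta
    return PosteriorFit(draws, {"prior": prior, "mcmc": mcmc})


class GeneSignatureModel:
    """Bayesian probit gene-signature model (statsmodels-style).

    Parameters
    ----------
    X : ExpressionMatrix
        Training expression (already filtered, one sample per patient).
    y : array of 0/1
        Phenotype per sample, aligned with ``X.sample_ids``.
    n_genes : int
        Signature size k (top-|t| genes).
    n_factors : int
        Number of SVD factors fed to the regression (default 2).
    prior : dict
        ``var_intercept`` and ``var_coef`` of the normal coefficient prior.
    """

    def __init__(self, X: ExpressionMatrix, y, n_genes: int,
                 n_factors: int = 2, prior: dict | None = None):
        self.X = X
        self.y = np.asarray(y).astype(int)
        self.n_genes = int(n_genes)
        self.n_factors = int(n_factors)
        self.prior = {**DEFAULT_PRIOR, **(prior or {})}

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, pheno: pd.DataFrame,
                       annotation: dict | None = None, **kwargs
                       ) -> "GeneSignatureModel":
        X = ExpressionMatrix(list(expr.index), list(expr.columns),
                             expr.to_numpy(float), annotation or {})
        y = pheno.set_index("sample_id").loc[X.sample_ids, "phenotype"]
        return cls(X, y.to_numpy(), **kwargs)

    def fit(self, iterations: int = 10_000, burn_in: int = 2_000,
            seed: int = 0) -> "GeneSignatureResults":
        basis, scores = build_factors(self.X, self.y, self.n_genes,
                                      self.n_factors)
        mcmc = {"iterations": iterations, "burn_in": burn_in, "seed": seed}
        posterior = fit_bpr(scores, self.y, self.prior, mcmc)
        return GeneSignatureResults(self, basis, posterior, scores)


@dataclass
class GeneSignatureResults:
    """A fitted signature: factor basis + posterior coefficient draws."""

    model: GeneSignatureModel | None
    basis: FactorBasis
    posterior: PosteriorFit
    train_scores: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        """Posterior-mean coefficients (intercept, factor terms)."""
        return self.posterior.posterior_mean

    def factor_scores(self, X_new: ExpressionMatrix) -> np.ndarray:
        missing = [f for f in self.basis.feature_ids
                   if f not in set(X_new.feature_ids)]
        if missing:
            raise KeyError(
                f"{len(missing)} signature features missing from input, "
                f"e.g. {missing[:5]}; provide a cross-platform mapping"
            )
        sub = X_new.subset_features(self.basis.feature_ids)
        return self.basis.scores(sub.values)

    def predict_proba(self, X_new: ExpressionMatrix,
                      method: str = "mean_prob") -> np.ndarray:
        """Predictive probability of phenotype 1 per sample.

        ``mean_prob``: posterior mean of Phi(linear predictor) (default).
        ``prob_at_mean``: Phi at the posterior-mean linear predictor.
        """
        return self.predict_from_scores(self.factor_scores(X_new), method)

    def predict_from_scores(self, scores: np.ndarray,
                            method: str = "mean_prob") -> np.ndarray:
        W = np.column_stack([np.ones(scores.shape[0]), scores])
        eta = W @ self.posterior.draws.T  # samples x draws
        if method == "mean_prob":
            return ndtr(eta).mean(axis=1)
        if method == "prob_at_mean":
            return ndtr(eta.mean(axis=1))
        raise ValueError("method must be 'mean_prob' or 'prob_at_mean'")

    def summary(self) -> str:
        mean = self.params
        sd = self.posterior.draws.std(axis=0, ddof=1)
        lo = np.percentile(self.posterior.draws, 2.5, axis=0)
        hi = np.percentile(self.posterior.draws, 97.5, axis=0)
        names = ["intercept"] + [f"factor_{i+1}"
                                 for i in range(self.basis.n_factors)]
        lines = [
            "Bayesian probit gene-signature results",
            f"  genes: {len(self.basis.feature_ids)}"
            f"   factors: {self.basis.n_factors}"
            f"   draws: {self.posterior.draws.shape[0]}",
            f"  {'term':<12}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for i, nm in enumerate(names):
            lines.append(f"  {nm:<12}{mean[i]:>10.4f}{sd[i]:>10.4f}"
                         f"{lo[i]:>10.4f}{hi[i]:>10.4f}")
        return "\n".join(lines)

    # --- serialization: JSON envelope + TSV blocks -----------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        env = {
            "n_genes": len(self.basis.feature_ids),
            "n_factors": self.basis.n_factors,
            "settings": self.posterior.settings,
            "meta": self.meta,
            "singular_values": self.basis.singular_values.tolist(),
        }
        (path / "model.json").write_text(json.dumps(env, indent=2))
        feat = pd.DataFrame({"feature": self.basis.feature_ids,
                             "center": self.basis.center,
                             "scale": self.basis.scale})
        for j in range(self.basis.n_factors):
            feat[f"loading_{j+1}"] = self.basis.loadings[:, j]
        feat.to_csv(path / "features.tsv", sep="\t", index=False,
                    float_format="%.17g")
        cols = ["intercept"] + [f"factor_{i+1}"
                                for i in range(self.basis.n_factors)]
        pd.DataFrame(self.posterior.draws, columns=cols).to_csv(
            path / "draws.tsv", sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(self.train_scores).to_csv(
            path / "train_scores.tsv", sep="\t", index=False,
            float_format="%.17g")

    @classmethod
    def load(cls, path) -> "GeneSignatureResults":
        path = Path(path)
        env = json.loads((path / "model.json").read_text())
        feat = pd.read_csv(path / "features.tsv", sep="\t",
                           dtype={"feature": str},
                           float_precision="round_trip")
        r = env["n_factors"]
        basis = FactorBasis(
            list(feat["feature"]),
            feat["center"].to_numpy(), feat["scale"].to_numpy(),
            feat[[f"loading_{j+1}" for j in range(r)]].to_numpy(),
            np.asarray(env["singular_values"]),
        )
        draws = pd.read_csv(path / "draws.tsv", sep="\t",
                            float_precision="round_trip").to_numpy()
        scores = pd.read_csv(path / "train_scores.tsv", sep="\t",
                             float_precision="round_trip").to_numpy()
        return cls(None, basis, PosteriorFit(draws, env["settings"]),
                   scores, env.get("meta", {}))


def predict_probability(results: GeneSignatureResults,
                        X_new: ExpressionMatrix,
                        method: str = "mean_prob") -> np.ndarray:
    return results.predict_proba(X_new, method)


def deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Sum of deviances -2 [y log p + (1-y) log(1-p)] with clipped p."""
    p = np.clip(np.asarray(p, float), PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y, float)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def loo_evaluate(X: ExpressionMatrix, y: np.ndarray, k: int,
                 settings: dict | None = None) -> dict:
    """Leave-one-out evaluation of a size-k signature.

    Each fold re-runs gene ranking, standardization, SVD and the Gibbs
    sampler on the remaining n-1 samples (nested selection), then predicts
    the held-out sample.  Fold f uses seed base_seed + f.  Set
    ``fixed_selection=True`` in settings to rank genes once on the full
    data (the cheaper, optimistically biased variant).
    """
    s = {"n_factors": 2, "prior": DEFAULT_PRIOR, "mcmc": dict(LOO_MCMC),
         "fixed_selection": False}
    if settings:
        s.update(settings)
    y = np.asarray(y).astype(int)
    n = X.n_samples
    if n < 4 or np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need n >= 4 with at least two samples per class")
    fixed_feats = (student_t_rank(X, y).top_features(k)
                   if s["fixed_selection"] else None)
    probs = np.empty(n)
    base_seed = int(s["mcmc"].get("seed", 0))
    for f in range(n):
        keep = [sid for i, sid in enumerate(X.sample_ids) if i != f]
        X_tr = X.subset_samples(keep)
        y_tr = np.delete(y, f)
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a fold lost one class entirely")
        if fixed_feats is not None:
            X_sel = X_tr.subset_features(fixed_feats)
            basis, scores = build_factors(X_sel, y_tr, k, s["n_factors"])
        else:
            basis, scores = build_factors(X_tr, y_tr, k, s["n_factors"])
        mcmc = {**s["mcmc"], "seed": base_seed + f}
        post = fit_bpr(scores, y_tr, s["prior"], mcmc)
        res = GeneSignatureResults(None, basis, post, scores)
        held = X.subset_samples([X.sample_ids[f]])
        probs[f] = res.predict_proba(held)[0]
    miscls = float(np.mean((probs >= 0.5).astype(int) != y))
    return {"sum_deviance": deviance(y, probs),
            "misclassification_rate": miscls,
            "probabilities": probs}


def tune_model_size(X: ExpressionMatrix, y: np.ndarray,
                    grid=tuple(range(50, 251, 10)),
                    settings: dict | None = None) -> ModelSelectionTrace:
    """LOO sum-of-deviances over a grid of signature sizes.

    The chosen size is the smallest k attaining the minimum sum of
    deviances; the misclassification rate is reported alongside for
    diagnostic plots.
    """
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty model-size grid")
    if max(grid) > X.n_features:
        raise ValueError("grid exceeds the number of available features")
    devs, miscls = [], []
    for k in grid:
        out = loo_evaluate(X, y, k, settings)
        devs.append(out["sum_deviance"])
        miscls.append(out["misclassification_rate"])
    chosen = grid[int(np.argmin(devs))]
    return ModelSelectionTrace(grid, devs, miscls, chosen)


def train_signature(X: ExpressionMatrix, y: np.ndarray, k: int,
                    settings: dict | None = None) -> GeneSignatureResults:
    """Full-data fit at signature size k, with reproduction metadata."""
    s = {"n_factors": 2, "prior": DEFAULT_PRIOR, "mcmc": dict(DEFAULT_MCMC)}
    if settings:
        s.update(settings)
    model = GeneSignatureModel(X, y, k, s["n_factors"], s["prior"])
    res = model.fit(**{kk: s["mcmc"][kk]
                       for kk in ("iterations", "burn_in", "seed")})
    res.meta = {
        "n_genes": int(k),
        "labels": np.asarray(y).astype(int).tolist(),
        "prevalence": float(np.mean(np.asarray(y).astype(int))),
        "settings": s,
    }
    return res
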