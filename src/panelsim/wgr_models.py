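"""Whole-genome regression: RR-BLUP (REML) and Bayes-B / Bayes-C samplers.

All models share the linear form

    y = 1 mu + Z u + e,

where Z is the column-centered dosage submatrix of the fitted marker panel
and u the vector of marker effects.  RR-BLUP places a single normal prior
u ~ N(0, I sigma_u^2) and estimates the two variance components by REML
through one spectral decomposition of the Z Z' kernel, which makes it
numerically identical to GBLUP with the corresponding genomic relationship
matrix.  Bayes-C adds a point mass at zero (mixture probability pi_zero)
with a common slab variance; Bayes-B gives each included marker its own
variance, i.e. a point-mass + scaled-t mixture.

Prior scales follow the usual genomic-prediction heuristic: the expected
marker-explained fraction of phenotypic variance (``prior_r2``) is divided
by the summed column variance of the panel, so prior strength adapts to
panel size; scale parameters are set so the prior mode matches that
partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh, helmert
from scipy.optimize import minimize_scalar

from ._samplers import bayes_mixture_gibbs

MODELS = ("rrblup", "bayesB", "bayesC")


@dataclass(frozen=True)
class MCMCSettings:
    """Gibbs-chain settings and variance-prior hyperparameters."""

    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 2:
            raise ValueError("prior_df must exceed 2")
        if not (0.0 < self.prior_r2 < 1.0):
            raise ValueError("prior_r2 must lie in (0, 1)")


@dataclass
class FittedWGR:
    """A fitted whole-genome regression model."""

    model: str
    intercept: float
    effects: np.ndarray
    marker_variance: float
    residual_variance: float
    column_centers: np.ndarray
    pi_zero: Optional[float] = None
    sampler_meta: dict = field(default_factory=dict)
    effect_posterior_sd: Optional[np.ndarray] = None
    inclusion_prob: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "intercept": self.intercept,
            "effects": self.effects.tolist(),
            "marker_variance": self.marker_variance,
            "residual_variance": self.residual_variance,
            "column_centers": self.column_centers.tolist(),
            "pi_zero": self.pi_zero,
            "sampler_meta": self.sampler_meta,
        }
        if self.effect_posterior_sd is not None:
            out["effect_posterior_sd"] = self.effect_posterior_sd.tolist()
        if self.inclusion_prob is not None:
            out["inclusion_prob"] = self.inclusion_prob.tolist()
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _prepare(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError(f"dimension mismatch: X {X.shape}, y {y.shape}")
    if y.size < 3:
        raise ValueError("need at least 3 training records")
    centers = X.mean(axis=0)
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic column in the training matrix")
    if not poly.all():
        warnings.warn(
            f"{(~poly).sum()} monomorphic training columns dropped (zero effect)",
            stacklevel=3,
        )
    return X, y, centers, poly


def _constant_fit(model, y, centers, meta) -> FittedWGR:
    warnings.warn("phenotype is constant; returning a zero-effect model", stacklevel=3)
    return FittedWGR(
        model=model,
        intercept=float(y[0]),
        effects=np.zeros(centers.size),
        marker_variance=0.0,
        residual_variance=0.0,
        column_centers=centers,
        sampler_meta=meta,
    )


def fit_rrblup(X, y, lambda_: float | None = None) -> FittedWGR:
    """Ridge-regression BLUP of marker effects with REML variance components.

    REML maximizes the restricted likelihood in the single variance ratio
    lambda = sigma_e^2 / sigma_u^2 after rotating intercept contrasts of
    y onto the eigenbasis of the centered kernel K = Z Z'.  Effects are
    recovered as u = Z'(K + lambda I)^-1 (y - mu).  Passing ``lambda_``
    bypasses REML and solves the ridge system at that fixed ratio.
    """
    X, y, centers, poly = _prepare(X, y)
    if y.std() == 0:
        return _constant_fit("rrblup", y, centers, {"lambda": None, "reml": False})
    Z = X[:, poly] - centers[poly]
    n = y.size
    K = Z @ Z.T

    if lambda_ is None:
        T = helmert(n)  # (n-1, n) orthonormal contrasts, rows _|_ 1
        d, U = eigh(T @ K @ T.T)
        d = np.maximum(d, 0.0)
        w = U.T @ (T @ y)
        scale = max(d.mean(), 1e-12)

        def neg_reml(t: float) -> float:
            lam = np.exp(t) * scale
            denom = d + lam
            s = np.mean(w**2 / denom)
            return (n - 1) * np.log(s) + np.sum(np.log(denom))

        res = minimize_scalar(neg_reml, bounds=(-18.0, 18.0), method="bounded")
        lam = float(np.exp(res.x) * scale)
        sigma_u2 = float(np.mean(w**2 / (d + lam)))
        sigma_e2 = lam * sigma_u2
        reml = True
    else:
        lam = float(lambda_)
        sigma_u2 = float("nan")
        sigma_e2 = float("nan")
        reml = False

    A = K + lam * np.eye(n)
    ones = np.ones(n)
    sol = np.linalg.solve(A, np.column_stack([y, ones]))
    mu = float(ones @ sol[:, 0] / (ones @ sol[:, 1]))
    alpha = np.linalg.solve(A, y - mu * ones)
    u = Z.T @ alpha

    effects = np.zeros(X.shape[1])
    effects[poly] = u
    return FittedWGR(
        model="rrblup",
        intercept=mu,
        effects=effects,
        marker_variance=sigma_u2,
        residual_variance=sigma_e2,
        column_centers=centers,
        sampler_meta={"lambda": lam, "reml": reml},
    )


def _fit_bayes(
    model: str,
    X,
    y,
    settings: MCMCSettings,
    pi_zero: float,
    update_pi: bool,
    fix_marker_variance: float | None,
    fix_residual_variance: float | None,
) -> FittedWGR:
    if not (0.0 <= pi_zero <= 1.0):
        raise ValueError("pi_zero must lie in [0, 1]")
    X, y, centers, poly = _prepare(X, y)
    meta = {
        "n_iter": settings.n_iter,
        "burn_in": settings.burn_in,
        "thin": settings.thin,
        "seed": settings.seed,
        "prior_df": settings.prior_df,
        "prior_r2": settings.prior_r2,
    }
    if y.std() == 0:
        fit = _constant_fit(model, y, centers, meta)
        fit.pi_zero = pi_zero
        return fit
    Z = X[:, poly] - centers[poly]
    var_y = float(y.var(ddof=1))
    msx = float((Z**2).mean(axis=0).sum())
    df = settings.prior_df
    r2p = settings.prior_r2
    incl_frac = max(1.0 - pi_zero, 1.0 / Z.shape[1])
    if fix_marker_variance is not None:
        scale_b, update_var_b = float(fix_marker_variance), False
    else:
        # prior mode of the slab variance = R2 * var(y) / (expected
        # included column variance mass)
        scale_b = r2p * var_y / (incl_frac * msx) * (df + 2.0) / df
        update_var_b = True
    if fix_residual_variance is not None:
        scale_e, update_var_e = float(fix_residual_variance), False
    else:
        scale_e = (1.0 - r2p) * var_y * (df + 2.0) / df
        update_var_e = True

    Xt = np.ascontiguousarray(Z.T)
    (
        mu,
        b_mean,
        b_sd,
        incl,
        var_b,
        var_e,
        pi_mean,
        n_samples,
    ) = bayes_mixture_gibbs(
        Xt,
        y,
        settings.n_iter,
        settings.burn_in,
        settings.thin,
        int(settings.seed) % 2**31,
        float(pi_zero),
        float(df),
        scale_b,
        float(df),
        scale_e,
        model == "bayesB",
        update_var_b,
        update_var_e,
        update_pi,
        model == "bayesB" and fix_marker_variance is None,
    )
    effects = np.zeros(X.shape[1])
    effects[poly] = b_mean
    post_sd = np.zeros(X.shape[1])
    post_sd[poly] = b_sd
    incl_full = np.zeros(X.shape[1])
    incl_full[poly] = incl
    meta["n_samples"] = int(n_samples)
    return FittedWGR(
        model=model,
        intercept=float(mu),
        effects=effects,
        marker_variance=float(var_b),
        residual_variance=float(var_e),
        column_centers=centers,
        pi_zero=float(pi_mean) if update_pi else float(pi_zero),
        sampler_meta=meta,
        effect_posterior_sd=post_sd,
        inclusion_prob=incl_full,
    )


def fit_bayesC(
    X,
    y,
    settings: MCMCSettings | None = None,
    pi_zero: float = 0.5,
    update_pi: bool = True,
    fix_marker_variance: float | None = None,
    fix_residual_variance: float | None = None,
) -> FittedWGR:
    """Bayes-C: point mass at zero + common-variance normal slab."""
    return _fit_bayes(
        "bayesC",
        X,
        y,
        settings or MCMCSettings(),
        pi_zero,
        update_pi,
        fix_marker_variance,
        fix_residual_variance,
    )


def fit_bayesB(
    X,
    y,
    settings: MCMCSettings | None = None,
    pi_zero: float = 0.5,
    update_pi: bool = True,
    fix_marker_variance: float | None = None,
    fix_residual_variance: float | None = None,
) -> FittedWGR:
    """Bayes-B: point mass at zero + locus-specific variances (scaled-t slab)."""
    return _fit_bayes(
        "bayesB",
        X,
        y,
        settings or MCMCSettings(),
        pi_zero,
        update_pi,
        fix_marker_variance,
        fix_residual_variance,
    )


def fit(model: str, X, y, **kwargs) -> FittedWGR:
    """Dispatch to one of the three model fitters by label."""
    if model == "rrblup":
        kwargs.pop("settings", None)
        kwargs.pop("pi_zero", None)
        return fit_rrblup(X, y, **kwargs)
    if model == "bayesB":
        return fit_bayesB(X, y, **kwargs)
    if model == "bayesC":
        return fit_bayesC(X, y, **kwargs)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def predict_genetic_values(model: FittedWGR, X_new) -> np.ndarray:
    """Predicted genetic values (X_new - training centers) . effects.

    The intercept is excluded: predictions are centered genetic values on
    the training scale, which is all a correlation-based accuracy needs.
    """
    X_new = np.asarray(X_new, dtype=np.float64)
    if X_new.ndim != 2 or X_new.shape[1] != model.effects.size:
        raise ValueError(
            f"X_new has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns, "
            f"model was fitted on {model.effects.size} loci"
        )
    return (X_new - model.column_centers) @ model.effects


def accuracy(predicted, truth) -> float:
    """Pearson correlation between predicted and true values."""
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if predicted.shape != truth.shape or predicted.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if predicted.std() == 0 or truth.std() == 0:
        raise ValueError("accuracy undefined for constant input")
    return float(np.corrcoef(predicted, truth)[0, 1])
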