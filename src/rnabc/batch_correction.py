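"""Parametric empirical-Bayes batch correction (the ComBat model).

The model for probe g in sample j of batch i is

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg,

with gamma_ig ~ Normal(gamma_bar_i, tau2_i) and delta2_ig ~ InverseGamma
(lambda_i, theta_i) as priors shared across probes within a batch. Per-probe
batch effects are first estimated by least squares (with a sample-size-
weighted zero-sum constraint on gamma for identifiability), the data are
standardized, the prior hyperparameters are moment-matched across probes, and
the posterior (EB-shrunk) location/scale effects gamma*_ig, delta2*_ig are
found by iterating the standard coupled conditional updates. All batches —
including the training cohort — are adjusted onto the pooled scale.

Covariates (e.g. receptor status) can be supplied so that known biological
structure is fit alongside the batch terms and therefore survives correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12
_DEGENERATE_LAMBDA = 1e6


@dataclass
class BatchDesign:
    """Per-sample batch labels plus an optional covariate table.

    Categorical covariates are dummy-expanded (first level dropped); the
    model's intercept lives in the batch terms, so the covariate design
    carries no intercept column of its own.
    """

    batch_labels: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.batch_labels = [str(b) for b in self.batch_labels]
        counts = pd.Series(self.batch_labels).value_counts()
        if len(counts) < 2:
            raise ValueError("batch correction requires at least two batches")
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(
                f"every batch needs >=2 samples; too small: {list(small.index)}"
            )
        if self.covariates is not None and len(self.covariates) != len(self.batch_labels):
            raise ValueError("covariate rows must match the number of samples")

    @property
    def batches(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.batch_labels:
            seen.setdefault(b)
        return list(seen)

    def covariate_design(self) -> np.ndarray | None:
        if self.covariates is None or self.covariates.shape[1] == 0:
            return None
        cols = []
        for name in self.covariates.columns:
            col = self.covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float)[:, None])
            else:
                dummies = pd.get_dummies(col.astype(str), drop_first=True)
                cols.append(dummies.to_numpy(dtype=float))
        x = np.hstack(cols) if cols else None
        return x if x is not None and x.shape[1] else None


@dataclass
class CombatParameters:
    """Fitted model pieces, kept for inspection and recovery checks."""

    batches: list[str]
    alpha_g: np.ndarray
    beta_g: np.ndarray | None
    sigma2_g: np.ndarray
    gamma_hat: dict[str, np.ndarray]
    delta2_hat: dict[str, np.ndarray]
    gamma_star: dict[str, np.ndarray]
    delta2_star: dict[str, np.ndarray]
    hyperparams: dict[str, tuple[float, float, float, float]]
    n_iterations: dict[str, int] = field(default_factory=dict)

    def mean_additive_effect(self, batch: str) -> float:
        """Mean over probes of the EB batch shift, in original data units."""
        return float(np.mean(self.gamma_star[batch] * np.sqrt(self.sigma2_g)))


def fit_eb_hyperparameters(
    gamma_hat: np.ndarray, delta2_hat: np.ndarray
) -> tuple[float, float, float, float]:
    """Moment-match the normal / inverse-gamma priors across probes.

    gamma_bar and tau2 are the sample mean and (unbiased) variance of the
    per-probe location effects. lambda and theta solve E[d2] = theta/(lambda-1)
    and Var[d2] = theta^2 / ((lambda-1)^2 (lambda-2)) for the scale effects.
    A zero variance of delta2_hat yields a degenerate prior (lambda set to
    1e6, total shrinkage), which is logged.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta2_hat = np.asarray(delta2_hat, dtype=float)
    if gamma_hat.size < 2 or delta2_hat.size < 2:
        raise ValueError("need at least two probes to fit EB hyperparameters")
    gamma_bar = float(gamma_hat.mean())
    tau2 = float(gamma_hat.var(ddof=1))
    m = float(delta2_hat.mean())
    s2 = float(delta2_hat.var(ddof=1))
    if s2 <= _VAR_FLOOR:
        logger.info("delta2_hat variance ~ 0; using degenerate inverse-gamma prior")
        lam = _DEGENERATE_LAMBDA
        theta = m * (lam - 1.0)
    else:
        lam = (2.0 * s2 + m * m) / s2
        theta = (m * s2 + m**3) / s2
    return gamma_bar, tau2, lam, theta


def _eb_iterate(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    hyper: tuple[float, float, float, float],
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Coupled gamma*/delta2* updates until relative change < tol."""
    gamma_bar, tau2, lam, theta = hyper
    n_i = z_batch.shape[0]
    g_star = gamma_hat.copy()
    d2_star = delta2_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n_i * tau2 * gamma_hat + d2_star * gamma_bar) / (
            n_i * tau2 + d2_star
        )
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (theta + 0.5 * sum2) / (n_i / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(g_new - g_star) / np.maximum(np.abs(g_star), 1e-8)),
            np.max(np.abs(d2_new - d2_star) / np.maximum(d2_star, 1e-8)),
        )
        g_star, d2_star = g_new, d2_new
        if change < tol:
            break
    return g_star, d2_star, it


def combat(
    matrix: ExpressionMatrix, design: BatchDesign
) -> tuple[ExpressionMatrix, CombatParameters]:
    """Adjust all batches onto the pooled scale with EB-shrunk batch effects."""
    if len(design.batch_labels) != matrix.shape[1]:
        raise ValueError("design labels do not match the number of samples")
    y = matrix.values.T  # samples x probes
    n_samples, n_probes = y.shape
    batches = design.batches
    labels = np.asarray(design.batch_labels)
    batch_masks = {b: labels == b for b in batches}
    n_per = {b: int(batch_masks[b].sum()) for b in batches}

    onehot = np.column_stack([batch_masks[b].astype(float) for b in batches])
    x_cov = design.covariate_design()
    design_mat = onehot if x_cov is None else np.hstack([onehot, x_cov])
    rank = np.linalg.matrix_rank(design_mat)
    if rank < design_mat.shape[1]:
        raise ValueError(
            "design matrix is rank deficient: a covariate is confounded with batch"
        )

    coef, *_ = np.linalg.lstsq(design_mat, y, rcond=None)
    gamma_ls = coef[: len(batches)]  # per-batch means, probes in columns
    beta = coef[len(batches):] if x_cov is not None else None

    weights = np.array([n_per[b] / n_samples for b in batches])
    alpha_g = weights @ gamma_ls
    fitted = design_mat @ coef
    # unbiased pooled residual variance (divide by residual df, not N): this
    # matches the ddof of the per-batch delta2_hat estimates, so a batch-free
    # equal-variance dataset standardizes to delta2_hat == 1 exactly and the
    # correction is idempotent in that case
    dof = max(n_samples - design_mat.shape[1], 1)
    sigma2_g = np.maximum(((y - fitted) ** 2).sum(axis=0) / dof, _VAR_FLOOR)
    sigma_g = np.sqrt(sigma2_g)

    stand_mean = alpha_g[None, :] + (x_cov @ beta if beta is not None else 0.0)
    z = (y - stand_mean) / sigma_g[None, :]

    gamma_hat: dict[str, np.ndarray] = {}
    delta2_hat: dict[str, np.ndarray] = {}
    gamma_star: dict[str, np.ndarray] = {}
    delta2_star: dict[str, np.ndarray] = {}
    hyperparams: dict[str, tuple[float, float, float, float]] = {}
    n_iterations: dict[str, int] = {}
    adjusted = np.empty_like(z)

    for b in batches:
        zb = z[batch_masks[b]]
        g_hat = zb.mean(axis=0)
        d2_hat = zb.var(axis=0, ddof=1)
        gamma_hat[b] = g_hat
        delta2_hat[b] = d2_hat

        ok = d2_hat > _VAR_FLOOR
        n_degenerate = int((~ok).sum())
        if n_degenerate:
            logger.info(
                "batch %s: %d zero-variance probe(s) get additive-only correction",
                b, n_degenerate,
            )
        if ok.sum() < 2:
            raise ValueError(
                f"batch {b!r} has fewer than two probes with positive variance"
            )
        hyper = fit_eb_hyperparameters(g_hat[ok], d2_hat[ok])
        hyperparams[b] = hyper
        g_star = g_hat.copy()
        d2_star = np.ones_like(d2_hat)
        g_sub, d2_sub, iters = _eb_iterate(zb[:, ok], g_hat[ok], d2_hat[ok], hyper)
        g_star[ok] = g_sub
        d2_star[ok] = d2_sub
        gamma_star[b] = g_star
        delta2_star[b] = d2_star
        n_iterations[b] = iters

        adjusted[batch_masks[b]] = (zb - g_star[None, :]) / np.sqrt(d2_star)[None, :]

    y_star = adjusted * sigma_g[None, :] + stand_mean
    out = matrix.with_values(y_star.T, "normalized")
    params = CombatParameters(
        batches=batches,
        alpha_g=alpha_g,
        beta_g=beta,
        sigma2_g=sigma2_g,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        hyperparams=hyperparams,
        n_iterations=n_iterations,
    )
    return out, params
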