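"""Empirical-Bayes site-effect harmonization (ComBat) for edge matrices.

Connectivity measured at different imaging sites carries additive and
multiplicative per-edge site effects.  The location/scale model per edge v,
subject j at site i is

    y_ijv = alpha_v + X_j . beta_v + gamma_iv + delta_iv * eps_ijv

where X holds the covariates whose biology must be preserved (diagnosis,
age, sex).  Estimation follows the parametric empirical-Bayes scheme:
feature-wise standardization with the site terms constrained to a
sample-size-weighted zero sum, normal priors on the additive site effects
and inverse-gamma priors on the squared multiplicative ones with
hyperparameters set by the method of moments across edges, and iterated
conditional posterior means for the shrunken estimates (gamma*, delta*^2).
The adjusted value is

    y*_ijv = sigma_v / delta*_iv * (z_ijv - gamma*_iv) + alpha_v + X_j . beta_v

so covariate effects are re-added unchanged.  Harmonization is applied to
each dataset separately, never jointly across datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import FCDataset
from .errors import DataValidationError

__all__ = ["HarmonizationModel", "harmonize", "apply_model", "site_effect_summary"]

DEFAULT_COVARIATES = ("diagnosis", "age", "sex")


@dataclass
class HarmonizationModel:
    """Fitted location/scale estimates plus empirical-Bayes site effects."""

    sites: list[str]
    n_per_site: np.ndarray  # (I,)
    covariates: tuple[str, ...]
    alpha: np.ndarray  # (m,) pooled intercept
    beta: np.ndarray  # (k, m) covariate slopes
    sigma2: np.ndarray  # (m,) pooled residual variance
    gamma_hat: np.ndarray  # (I, m) naive additive site effects (standardized scale)
    delta2_hat: np.ndarray  # (I, m) naive squared multiplicative site effects
    gamma_star: np.ndarray  # (I, m) EB-shrunk additive effects
    delta2_star: np.ndarray  # (I, m) EB-shrunk squared scale effects
    gamma_bar: np.ndarray  # (I,) normal prior means
    tau2: np.ndarray  # (I,) normal prior variances
    a_prior: np.ndarray  # (I,) inverse-gamma shapes
    b_prior: np.ndarray  # (I,) inverse-gamma scales
    n_iterations: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    identity: bool = False  # single-site bypass

    def to_json(self, path) -> None:
        payload = {
            "sites": self.sites,
            "covariates": list(self.covariates),
            "identity": self.identity,
        }
        for name in (
            "n_per_site",
            "alpha",
            "beta",
            "sigma2",
            "gamma_hat",
            "delta2_hat",
            "gamma_star",
            "delta2_star",
            "gamma_bar",
            "tau2",
            "a_prior",
            "b_prior",
            "n_iterations",
        ):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {
            "sites": payload["sites"],
            "covariates": tuple(payload["covariates"]),
            "identity": payload["identity"],
        }
        for name in (
            "n_per_site",
            "alpha",
            "beta",
            "sigma2",
            "gamma_hat",
            "delta2_hat",
            "gamma_star",
            "delta2_star",
            "gamma_bar",
            "tau2",
            "a_prior",
            "b_prior",
        ):
            kwargs[name] = np.asarray(payload[name])
        kwargs["n_iterations"] = np.asarray(payload["n_iterations"], dtype=int)
        return cls(**kwargs)


def _covariate_matrix(dataset: FCDataset, covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        s = dataset.participants[cov]
        if cov == "sex" and s.dtype == object:
            s = (s == "M").astype(float)
        cols.append(pd.to_numeric(s).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((dataset.n_subjects, 0))


def _eb_iterate(gamma_hat, delta2_hat, sdat, site_rows, gamma_bar, tau2, a, b, tol, max_iter):
    """Iterated conditional posterior means for one site (all edges at once)."""
    n = len(site_rows)
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    Z = sdat  # (n_i, m) standardized rows for this site
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((Z - g_new) ** 2).sum(axis=0)
        d_new = (b + 0.5 * sum2) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, it


def harmonize(
    dataset: FCDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[FCDataset, HarmonizationModel]:
    """Remove per-site location/scale effects while preserving covariates.

    Returns the adjusted dataset and the fitted model.  A single-site
    dataset is returned unchanged with a warning (there is nothing to
    harmonize across); a site containing only one diagnostic class is
    allowed — the diagnosis slope is then identified by the remaining
    sites — but is reported with a warning.
    """
    sites = list(pd.unique(dataset.participants["site"]))
    I = len(sites)
    m = dataset.n_edges
    n = dataset.n_subjects
    Y = dataset.fc
    if I < 2:
        warnings.warn(
            "single-site dataset: harmonization is an identity transform", stacklevel=2
        )
        model = HarmonizationModel(
            sites=sites,
            n_per_site=np.array([n]),
            covariates=tuple(covariates),
            alpha=Y.mean(axis=0),
            beta=np.zeros((len(covariates), m)),
            sigma2=Y.var(axis=0),
            gamma_hat=np.zeros((1, m)),
            delta2_hat=np.ones((1, m)),
            gamma_star=np.zeros((1, m)),
            delta2_star=np.ones((1, m)),
            gamma_bar=np.zeros(1),
            tau2=np.ones(1),
            a_prior=np.ones(1),
            b_prior=np.ones(1),
            identity=True,
        )
        return dataset, model

    site_idx = {s: np.flatnonzero(dataset.participants["site"].to_numpy() == s) for s in sites}
    n_i = np.array([len(site_idx[s]) for s in sites], dtype=float)
    if (n_i < 2).any():
        raise DataValidationError("every site needs at least 2 subjects")
    for s in sites:
        d = dataset.participants["diagnosis"].iloc[site_idx[s]]
        if d.nunique() == 1:
            warnings.warn(
                f"site {s!r} contains a single diagnostic class; its site effect is still "
                "estimated and the diagnosis slope is identified by the other sites",
                stacklevel=2,
            )

    batch = np.zeros((n, I))
    for k, s in enumerate(sites):
        batch[site_idx[s], k] = 1.0
    X_cov = _covariate_matrix(dataset, covariates)
    design = np.hstack([batch, X_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataValidationError("covariates are collinear with site")

    B, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (I + k, m)
    B_site = B[:I]
    B_cov = B[I:]
    # weighted zero-sum site constraint: the grand intercept is the
    # sample-size-weighted average of the per-site intercepts
    alpha = (n_i / n) @ B_site
    fitted = design @ B
    sigma2 = ((Y - fitted) ** 2).mean(axis=0)
    if (sigma2 <= 0).any():
        raise DataValidationError("degenerate (zero-variance) edges present")
    cov_part = X_cov @ B_cov if X_cov.shape[1] else 0.0
    Z = (Y - alpha - cov_part) / np.sqrt(sigma2)

    gamma_hat = np.vstack([Z[site_idx[s]].mean(axis=0) for s in sites])
    delta2_hat = np.vstack([Z[site_idx[s]].var(axis=0, ddof=1) for s in sites])
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    dbar = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + dbar**2) / s2
    b_prior = (dbar * s2 + dbar**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iters = np.zeros(I, dtype=int)
    for k, s in enumerate(sites):
        gamma_star[k], delta2_star[k], iters[k] = _eb_iterate(
            gamma_hat[k],
            delta2_hat[k],
            Z[site_idx[s]],
            site_idx[s],
            gamma_bar[k],
            tau2[k],
            a_prior[k],
            b_prior[k],
            tol,
            max_iter,
        )

    adjusted = Z.copy()
    for k, s in enumerate(sites):
        adjusted[site_idx[s]] = (Z[site_idx[s]] - gamma_star[k]) / np.sqrt(delta2_star[k])
    adjusted = adjusted * np.sqrt(sigma2) + alpha + cov_part

    model = HarmonizationModel(
        sites=sites,
        n_per_site=n_i,
        covariates=tuple(covariates),
        alpha=alpha,
        beta=B_cov,
        sigma2=sigma2,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iterations=iters,
    )
    out = FCDataset(
        dataset.participants.copy(), adjusted, dataset.atlas, name=dataset.name, truth=dataset.truth
    )
    return out, model


def apply_model(dataset: FCDataset, model: HarmonizationModel) -> FCDataset:
    """Adjust new subjects with an already-fitted harmonization model.

    Every site in ``dataset`` must have been seen when the model was fitted;
    the stored location/scale estimates and shrunken site effects are
    applied as-is.  Useful for checking, on held-out subjects, that the
    correction neither leaves site structure behind nor over-removes it.
    """
    if model.identity:
        return dataset
    unknown = set(pd.unique(dataset.participants["site"])) - set(model.sites)
    if unknown:
        raise DataValidationError(f"sites not seen during fitting: {sorted(unknown)}")
    X_cov = _covariate_matrix(dataset, model.covariates)
    cov_part = X_cov @ model.beta if X_cov.shape[1] else 0.0
    Z = (dataset.fc - model.alpha - cov_part) / np.sqrt(model.sigma2)
    adjusted = Z.copy()
    site_arr = dataset.participants["site"].to_numpy()
    for k, s in enumerate(model.sites):
        rows = np.flatnonzero(site_arr == s)
        if rows.size:
            adjusted[rows] = (Z[rows] - model.gamma_star[k]) / np.sqrt(model.delta2_star[k])
    adjusted = adjusted * np.sqrt(model.sigma2) + model.alpha + cov_part
    return FCDataset(
        dataset.participants.copy(),
        adjusted,
        dataset.atlas,
        name=dataset.name,
        truth=dataset.truth,
    )


def site_effect_summary(
    dataset: FCDataset, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Covariate-adjusted one-way site ANOVA per edge.

    Compares the regression with site dummies + covariates against the
    covariate-only model; returns per-edge F statistics and p-values.
    Edges whose full-model residual variance is (numerically) zero are
    flagged and get NaN statistics.
    """
    from scipy import stats

    sites = pd.unique(dataset.participants["site"])
    if len(sites) < 2:
        raise DataValidationError("site ANOVA needs at least 2 sites")
    n, m = dataset.fc.shape
    site_codes = pd.get_dummies(dataset.participants["site"]).to_numpy(dtype=float)
    X_cov = _covariate_matrix(dataset, covariates)
    X_full = np.hstack([site_codes, X_cov])
    X_red = np.hstack([np.ones((n, 1)), X_cov])
    Y = dataset.fc

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        return (resid**2).sum(axis=0), np.linalg.matrix_rank(X)

    rss_full, rank_full = rss(X_full)
    rss_red, rank_red = rss(X_red)
    df1 = rank_full - rank_red
    df2 = n - rank_full
    if df1 <= 0 or df2 <= 0:
        raise DataValidationError("site ANOVA is not identified for this design")
    flagged = rss_full <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    F[flagged] = np.nan
    p = stats.f.sf(F, df1, df2)
    return pd.DataFrame({"F": F, "p": p, "flagged": flagged})
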