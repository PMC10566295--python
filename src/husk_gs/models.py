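"""Whole-genome regression models for genomic selection.

Six models share a common fit/predict contract on centered dosage matrices:

* ``RRBLUP`` — ridge-regression BLUP.  Marker effects are i.i.d. normal with
  a common variance; the variance ratio ``lambda = sigma_e^2 / sigma_u^2``
  is estimated by restricted maximum likelihood via a spectral decomposition
  of the marker cross-product (single 1-D profile optimization), and the
  effects are the ridge solution at the REML optimum.  Equivalent to gBLUP
  on the corresponding genomic relationship matrix.
* ``BayesianAlphabetRegressor`` — single-site Gibbs samplers for BayesA,
  BayesB, BayesC, the Bayesian LASSO (BL) and Bayesian ridge regression
  (BRR), differing only in the prior on marker effects:

  ========  ======================================================
  BayesA    per-marker variance, scaled-inverse-chi^2 (scaled-t effects)
  BayesB    point mass at zero (prob. pi) + BayesA slab
  BayesC    point mass at zero (prob. pi) + common-variance normal slab
  BL        double-exponential via the exponential scale mixture
  BRR       common-variance normal (the Bayesian counterpart of ridge)
  ========  ======================================================

The only fixed effect is an intercept.  GEBVs are exact linear scores:
``intercept + (dosage - training_center) @ effects``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .genotype import GenotypeMatrix

__all__ = [
    "RRBLUP",
    "BayesianAlphabetRegressor",
    "GSFit",
    "GEBVResult",
    "fit_rrblup",
    "fit_bayes",
    "predict_gebv",
    "BAYES_MODELS",
]

BAYES_MODELS = ("BayesA", "BayesB", "BayesC", "BL", "BRR")
MODEL_NAMES = ("rrBLUP",) + BAYES_MODELS


# ------------------------------------------------------------------- rrBLUP
class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP with REML variance components.

    Parameters
    ----------
    lambda_ : float or None
        Fixed variance ratio sigma_e^2/sigma_u^2; None (default) estimates
        it by REML on ``log lambda`` in ``[-10, 10]``.

    Attributes
    ----------
    coef_ : per-marker effect estimates (the ridge solution at lambda_)
    intercept_ : GLS intercept
    centers_ : training column means used for prediction
    sigma2_u_, sigma2_e_ : REML variance components
    lambda_opt_ : the variance ratio used
    """

    def __init__(self, lambda_=None, log_lambda_bounds=(-10.0, 10.0), tol=1e-8):
        self.lambda_ = lambda_
        self.log_lambda_bounds = log_lambda_bounds
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing dosages: impute before fitting")
        n, m = X.shape
        # REML needs residual degrees of freedom; a fixed ratio does not
        if n < (3 if self.lambda_ is None else 2):
            raise ValueError("too few lines")
        self.centers_ = X.mean(axis=0)
        Z = X - self.centers_
        if y.std() == 0:
            self.coef_ = np.zeros(m)
            self.intercept_ = float(y[0])
            self.sigma2_u_ = 0.0
            self.sigma2_e_ = 0.0
            self.lambda_opt_ = np.inf
            self._spec = None
            return self

        K = Z @ Z.T
        one = np.ones(n)
        S = np.eye(n) - np.outer(one, one) / n
        A = S @ K @ S
        xi, U = np.linalg.eigh(A)
        # drop the eigenvector spanning the intercept direction (its
        # eigenvalue is exactly 0 and its transformed response is 0)
        drop = int(np.argmax(np.abs(U.T @ one)))
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        xi = np.maximum(xi[keep], 0.0)
        eta = U[:, keep].T @ (S @ y)
        self._spec = (xi, eta, n)

        if self.lambda_ is not None:
            lam = float(self.lambda_)
        else:
            lo, hi = self.log_lambda_bounds
            res = minimize_scalar(lambda t: -self._reml_ll(math.exp(t)),
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": self.tol})
            lam = math.exp(res.x)
        self.lambda_opt_ = lam
        self.sigma2_u_ = float((eta ** 2 / (xi + lam)).sum() / (n - 1))
        self.sigma2_e_ = lam * self.sigma2_u_

        H = K + lam * np.eye(n)
        Hinv_y = np.linalg.solve(H, y)
        Hinv_1 = np.linalg.solve(H, one)
        self.intercept_ = float(one @ Hinv_y / (one @ Hinv_1))
        self.coef_ = Z.T @ np.linalg.solve(H, y - self.intercept_)
        return self

    def _reml_ll(self, lam: float) -> float:
        xi, eta, n = self._spec
        q = n - 1
        ss = float((eta ** 2 / (xi + lam)).sum())
        return 0.5 * (q * math.log(q / (2 * math.pi)) - q
                      - q * math.log(ss) - float(np.log(xi + lam).sum()))

    def reml_loglik(self, lam: float) -> float:
        """Profiled restricted log-likelihood at a given variance ratio."""
        check_is_fitted(self, "coef_")
        if self._spec is None:
            raise ValueError("model was fitted on a constant response")
        return self._reml_ll(float(lam))

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + (X - self.centers_) @ self.coef_


# ------------------------------------------------------- Bayesian alphabet
class BayesianAlphabetRegressor(BaseEstimator, RegressorMixin):
    """Single-site Gibbs sampler for the Bayesian-alphabet marker models.

    Hyperpriors are weakly informative scaled-inverse-chi^2 with ``df0``
    degrees of freedom and data-scaled scale parameters derived from an
    a-priori proportion ``r2_prior`` of phenotypic variance attributed to
    markers.  For BayesB/BayesC the mixing proportion ``pi`` (probability
    a marker effect is exactly zero) gets a Beta(1, 1) prior and is sampled
    unless ``estimate_pi=False``.  Chains are deterministic given
    ``random_state``.
    """

    def __init__(self, model: str = "BRR", n_iter: int = 5000, burnin: int = 1000,
                 thin: int = 5, random_state: int | None = None,
                 df0: float = 5.0, r2_prior: float = 0.5,
                 pi: float = 0.5, estimate_pi: bool = True):
        self.model = model
        self.n_iter = n_iter
        self.burnin = burnin
        self.thin = thin
        self.random_state = random_state
        self.df0 = df0
        self.r2_prior = r2_prior
        self.pi = pi
        self.estimate_pi = estimate_pi

    def fit(self, X, y):
        if self.model not in BAYES_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_iter <= self.burnin:
            raise ValueError("n_iter must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing dosages: impute before fitting")
        n, m = X.shape
        if n < 3:
            raise ValueError("need at least 3 lines")
        rng = np.random.default_rng(self.random_state)

        self.centers_ = X.mean(axis=0)
        Z = np.asfortranarray(X - self.centers_)
        zsq = (Z ** 2).sum(axis=0)
        active = np.flatnonzero(zsq > 0)
        vary = float(np.var(y))
        if vary == 0:
            self.coef_ = np.zeros(m)
            self.intercept_ = float(y[0])
            self.sigma2_e_ = 0.0
            self.posterior_ = {}
            return self

        msx = float(zsq.sum()) / n
        df0, r2p = self.df0, self.r2_prior
        dfe = 5.0
        Se = vary * (1 - r2p) * (dfe + 2)           # mode-matched scale
        Sg = vary * r2p / msx * (df0 + 2)
        model = self.model

        mu = float(y.mean())
        g = np.zeros(m)
        resid = y - mu
        sigma_e2 = vary * (1 - r2p)
        sigma_g2 = vary * r2p / msx
        sk2 = np.full(m, sigma_g2)
        tau2 = np.full(m, sigma_g2 / sigma_e2)
        lam2_target = 2 * msx * (1 - r2p) / max(r2p, 1e-6)
        lam2 = lam2_target
        bl_shape0, bl_rate0 = 1.1, 1.1 / lam2_target
        pi = float(self.pi)
        incl = np.ones(m, dtype=bool)

        sum_g = np.zeros(m)
        sums = {"mu": 0.0, "sigma_e2": 0.0, "sigma_g2": 0.0, "pi": 0.0,
                "incl": np.zeros(m)}
        n_samples = 0

        for it in range(self.n_iter):
            # intercept
            resid += mu
            mu = rng.normal(resid.mean(), math.sqrt(sigma_e2 / n))
            resid -= mu

            # marker sweep
            for k in active:
                zk = Z[:, k]
                gk = g[k]
                rhs = float(zk @ resid) + zsq[k] * gk
                if model in ("BRR", "BayesC"):
                    vk = sigma_g2
                elif model in ("BayesA", "BayesB"):
                    vk = sk2[k]
                else:  # BL
                    vk = tau2[k] * sigma_e2
                if model in ("BayesB", "BayesC"):
                    if pi >= 1.0:
                        take = False
                    elif pi <= 0.0:
                        take = True
                    else:
                        a0 = sigma_e2 * zsq[k]
                        a1 = a0 + vk * zsq[k] ** 2
                        logodds = (math.log((1 - pi) / pi)
                                   + 0.5 * (math.log(a0 / a1)
                                            + rhs * rhs * (1 / a0 - 1 / a1)))
                        p_in = 1.0 / (1.0 + math.exp(-min(max(logodds, -700), 700)))
                        take = rng.random() < p_in
                    incl[k] = take
                else:
                    take = True
                if take:
                    C = zsq[k] + sigma_e2 / vk
                    gnew = rng.normal(rhs / C, math.sqrt(sigma_e2 / C))
                else:
                    gnew = 0.0
                if gnew != gk:
                    resid -= zk * (gnew - gk)
                    g[k] = gnew

            # variance / mixing updates
            if model == "BayesA":
                sk2 = (Sg + g ** 2) / rng.chisquare(df0 + 1.0, size=m)
            elif model == "BayesB":
                post = (Sg + g ** 2) / rng.chisquare(df0 + 1.0, size=m)
                prior = Sg / rng.chisquare(df0, size=m)
                sk2 = np.where(incl, post, prior)
            elif model == "BRR":
                sigma_g2 = (Sg + float(g @ g)) / rng.chisquare(df0 + m)
            elif model == "BayesC":
                nin = int(incl.sum())
                ssg = float(g[incl] @ g[incl]) if nin else 0.0
                sigma_g2 = (Sg + ssg) / rng.chisquare(df0 + nin)
            elif model == "BL":
                mu_ig = np.sqrt(lam2 * sigma_e2 / np.maximum(g ** 2, 1e-10))
                itau = rng.wald(np.minimum(mu_ig, 1e8), lam2)
                tau2 = 1.0 / np.maximum(itau, 1e-10)
                lam2 = rng.gamma(m + bl_shape0, 1.0 / (tau2.sum() / 2 + bl_rate0))
            if model in ("BayesB", "BayesC") and self.estimate_pi:
                nin = int(incl.sum())
                pi = rng.beta(1 + m - nin, 1 + nin)

            sse = float(resid @ resid)
            if model == "BL":
                sse += float((g ** 2 / tau2).sum())
                dfn = n + m + dfe
            else:
                dfn = n + dfe
            sigma_e2 = (Se + sse) / rng.chisquare(dfn)

            if it >= self.burnin and (it - self.burnin) % self.thin == 0:
                n_samples += 1
                sum_g += g
                sums["mu"] += mu
                sums["sigma_e2"] += sigma_e2
                sums["sigma_g2"] += sigma_g2
                sums["pi"] += pi
                sums["incl"] += incl

        self.coef_ = sum_g / n_samples
        self.intercept_ = sums["mu"] / n_samples
        self.sigma2_e_ = sums["sigma_e2"] / n_samples
        self.posterior_ = {
            "sigma_e2": sums["sigma_e2"] / n_samples,
            "sigma_g2": sums["sigma_g2"] / n_samples,
            "pi": sums["pi"] / n_samples,
            "inclusion_prob": sums["incl"] / n_samples,
            "n_samples": n_samples,
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + (X - self.centers_) @ self.coef_


# ----------------------------------------------------------------- wrappers
@dataclass
class GSFit:
    """Fitted whole-genome regression in marker-effect form."""

    model: str
    intercept: float
    marker_effects: np.ndarray
    marker_ids: np.ndarray
    centering: np.ndarray
    variance_components: dict = field(default_factory=dict)
    mcmc_meta: dict | None = None

    def __post_init__(self) -> None:
        if len(self.marker_effects) != len(self.marker_ids):
            raise ValueError("marker_effects / marker_ids length mismatch")

    def to_json(self, path: str) -> None:
        def _plain(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            return v

        payload = {
            "model": self.model,
            "intercept": self.intercept,
            "marker_effects": list(map(float, self.marker_effects)),
            "marker_ids": list(map(str, self.marker_ids)),
            "centering": list(map(float, self.centering)),
            "variance_components": _plain(self.variance_components),
            "mcmc_meta": self.mcmc_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "GSFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(model=d["model"], intercept=d["intercept"],
                   marker_effects=np.asarray(d["marker_effects"]),
                   marker_ids=np.asarray(d["marker_ids"], dtype=object),
                   centering=np.asarray(d["centering"]),
                   variance_components=d["variance_components"],
                   mcmc_meta=d["mcmc_meta"])


@dataclass
class GEBVResult:
    """Genomic estimated breeding values for a set of lines."""

    line_ids: np.ndarray
    gebv: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line_id": self.line_ids, "gebv": self.gebv})


def _align_y(g: GenotypeMatrix, y) -> np.ndarray:
    if isinstance(y, pd.Series):
        return y.loc[list(g.line_ids)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_lines:
        raise ValueError("phenotype length does not match panel")
    return y


def fit_rrblup(g: GenotypeMatrix, y, lambda_=None) -> GSFit:
    """REML ridge-regression BLUP on a panel; see :class:`RRBLUP`."""
    est = RRBLUP(lambda_=lambda_).fit(g.dosages, _align_y(g, y))
    return GSFit(model="rrBLUP", intercept=est.intercept_,
                 marker_effects=est.coef_, marker_ids=g.marker_ids,
                 centering=est.centers_,
                 variance_components={"sigma2_u": est.sigma2_u_,
                                      "sigma2_e": est.sigma2_e_,
                                      "lambda": est.lambda_opt_})


def fit_bayes(g: GenotypeMatrix, y, model: str = "BRR", iters: int = 5000,
              burnin: int = 1000, thin: int = 5, seed: int | None = None,
              **hyper) -> GSFit:
    """Gibbs-sampled Bayesian-alphabet fit; see
    :class:`BayesianAlphabetRegressor` for priors and hyperparameters."""
    est = BayesianAlphabetRegressor(model=model, n_iter=iters, burnin=burnin,
                                    thin=thin, random_state=seed, **hyper)
    est.fit(g.dosages, _align_y(g, y))
    return GSFit(model=model, intercept=est.intercept_,
                 marker_effects=est.coef_, marker_ids=g.marker_ids,
                 centering=est.centers_,
                 variance_components=dict(est.posterior_),
                 mcmc_meta={"iters": iters, "burnin": burnin,
                            "thin": thin, "seed": seed})


def predict_gebv(fit: GSFit, g_new: GenotypeMatrix) -> GEBVResult:
    """Score lines with a fitted model: exact linear GEBVs."""
    if len(g_new.marker_ids) != len(fit.marker_ids) or \
            not np.array_equal(g_new.marker_ids, fit.marker_ids):
        raise ValueError("marker sets of fit and new panel do not match")
    if g_new.missing_mask.any():
        raise ValueError("missing dosages: impute before prediction")
    gebv = fit.intercept + (g_new.dosages - fit.centering) @ fit.marker_effects
    return GEBVResult(line_ids=g_new.line_ids, gebv=gebv)
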