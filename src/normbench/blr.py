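"""Warped Bayesian linear regression.

The model is a Bayesian linear regression on a monotonically warped
response: with :math:`t = \\varphi(y)` the warped response,

.. math::

    t \\mid w \\sim \\mathcal N(Xw, \\beta^{-1}), \\qquad
    w \\sim \\mathcal N(0, \\alpha^{-1} I),

and the warp is a sinh-arcsinh transformation composed with an affine
standardization,

.. math::

    \\varphi(y) = \\sinh\\bigl(\\delta\\,\\mathrm{asinh}((y - \\mu)/\\sigma)
                  - \\epsilon\\bigr),

with skew parameter :math:`\\epsilon` and tail-weight parameter
:math:`\\delta > 0`; :math:`\\epsilon = 0, \\delta = 1` recovers the
identity up to the affine standardization. Hyperparameters
:math:`(\\alpha, \\beta, \\epsilon, \\delta)` are chosen by maximizing the
warped-Gaussian marginal likelihood (type-II maximum likelihood /
empirical Bayes), which includes the Jacobian of the warp. Given the
hyperparameters the weight posterior is Gaussian in closed form, and the
deviation (Z) score of an observation is its standardized residual under
the posterior predictive distribution in warped space:

.. math::

    Z = \\frac{\\varphi(y) - x^\\top m}
             {\\sqrt{\\beta^{-1} + x^\\top S x}}.

Usage follows the Model/Results convention::

    model = WarpedBLR(y, X)
    res = model.fit()
    z = res.deviation_scores(X_new, y_new)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

__all__ = ["WarpParams", "WarpedBLR", "WarpedBLRResults", "ModelMetrics", "evaluate_fit"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class WarpParams:
    """Sinh-arcsinh warp: skew ``epsilon``, tail weight ``delta`` (> 0),
    composed with affine standardization by ``shift`` and ``scale`` (> 0)."""

    epsilon: float = 0.0
    delta: float = 1.0
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def is_identity(self):
        return self.epsilon == 0.0 and self.delta == 1.0

    def transform(self, y):
        z0 = (np.asarray(y, dtype=float) - self.shift) / self.scale
        return np.sinh(self.delta * np.arcsinh(z0) - self.epsilon)

    def log_derivative(self, y):
        """log d(transform)/dy, elementwise; always finite for delta > 0."""
        z0 = (np.asarray(y, dtype=float) - self.shift) / self.scale
        arg = self.delta * np.arcsinh(z0) - self.epsilon
        logcosh = np.abs(arg) + np.log1p(np.exp(-2.0 * np.abs(arg))) - np.log(2.0)
        return np.log(self.delta) + logcosh - np.log(self.scale) - 0.5 * np.log1p(z0**2)

    def inverse(self, t):
        t = np.asarray(t, dtype=float)
        return self.shift + self.scale * np.sinh((np.arcsinh(t) + self.epsilon) / self.delta)


@dataclass
class ModelMetrics:
    """Fit metrics: explained variance, mean standardized log loss, and the
    skew and excess kurtosis of the deviation scores."""

    explained_variance: float
    msll: float
    z_skew: float
    z_kurtosis: float

    def to_dict(self):
        return asdict(self)


def evaluate_fit(z, y_warped, pred_mean, pred_var, baseline_mean, baseline_var):
    """Evaluation metrics for one fitted normative model.

    All quantities are in warped space. Explained variance is
    ``1 - var(y - mean)/var(y)``; MSLL is the mean negative predictive
    log-density minus the negative log-density under a Gaussian with the
    training set's mean and variance (more negative is better); skew and
    excess kurtosis are sample moments of the deviation scores.
    """
    z = np.asarray(z, dtype=float)
    y_warped = np.asarray(y_warped, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    pred_var = np.asarray(pred_var, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least 3 observations to evaluate a fit")
    vy = y_warped.var()
    if vy == 0:
        raise ValueError("zero-variance response; explained variance undefined")
    ev = 1.0 - (y_warped - pred_mean).var() / vy
    nll_pred = 0.5 * (_LOG2PI + np.log(pred_var)) + (y_warped - pred_mean) ** 2 / (2.0 * pred_var)
    nll_base = 0.5 * (_LOG2PI + np.log(baseline_var)) + (y_warped - baseline_mean) ** 2 / (
        2.0 * baseline_var
    )
    msll = float(np.mean(nll_pred - nll_base))
    return ModelMetrics(
        explained_variance=float(ev),
        msll=msll,
        z_skew=float(stats.skew(z)),
        z_kurtosis=float(stats.kurtosis(z)),  # excess
    )


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start yields a finite marginal likelihood."""


class WarpedBLR:
    """Warped Bayesian linear regression model of a single response column.

    Parameters
    ----------
    endog : (n,) array
        Response (one brain feature across subjects).
    exog : (n, d) array
        Design matrix (see :func:`normbench.design.build_design_matrix`).
    column_names : sequence of str, optional
        Design column names, carried through to the results summary.
    """

    def __init__(self, endog, exog, column_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        x = np.asarray(exog, dtype=float)
        if x.ndim != 2 or x.shape[0] != y.shape[0]:
            raise ValueError(f"incompatible shapes: endog {y.shape}, exog {x.shape}")
        if not np.all(np.isfinite(y)):
            bad = np.flatnonzero(~np.isfinite(y))
            raise ValueError(f"non-finite response at rows {bad.tolist()[:10]}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in design matrix")
        if y.std() == 0:
            raise ValueError("constant response cannot be modeled")
        self.endog = y
        self.exog = x
        self.column_names = list(column_names) if column_names is not None else [
            f"x{j}" for j in range(x.shape[1])
        ]
        self.nobs, self.k_exog = x.shape
        # cached quantities for evidence evaluation
        self._shift = float(y.mean())
        self._scale = float(y.std())
        self._z0 = (y - self._shift) / self._scale
        self._asinh_z0 = np.arcsinh(self._z0)
        self._jac_const = float(-self.nobs * np.log(self._scale) - 0.5 * np.log1p(self._z0**2).sum())
        xtx = x.T @ x
        self._eigvals, self._eigvecs = np.linalg.eigh(xtx)
        self._eigvals = np.clip(self._eigvals, 0.0, None)
        self._xtx = xtx

    # -- evidence ---------------------------------------------------------

    def _warped_target(self, eps, delta):
        return np.sinh(delta * self._asinh_z0 - eps)

    def _neg_log_evidence(self, log_alpha, log_beta, eps, log_delta):
        alpha, beta, delta = np.exp(log_alpha), np.exp(log_beta), np.exp(log_delta)
        t = self._warped_target(eps, delta)
        u = self.exog.T @ t
        d_eig = alpha + beta * self._eigvals
        if np.any(d_eig <= 0):
            return np.inf
        vu = self._eigvecs.T @ u
        m = self._eigvecs @ (beta * vu / d_eig)
        sse = float(t @ t - 2.0 * m @ u + m @ (self._xtx @ m))
        sse = max(sse, 0.0)
        arg = delta * self._asinh_z0 - eps
        logcosh = np.abs(arg) + np.log1p(np.exp(-2.0 * np.abs(arg))) - np.log(2.0)
        jac = self.nobs * np.log(delta) + logcosh.sum() + self._jac_const
        log_ev = (
            0.5 * self.k_exog * log_alpha
            + 0.5 * self.nobs * log_beta
            - 0.5 * beta * sse
            - 0.5 * alpha * float(m @ m)
            - 0.5 * np.log(d_eig).sum()
            - 0.5 * self.nobs * _LOG2PI
            + jac
        )
        if not np.isfinite(log_ev):
            return np.inf
        return -log_ev

    def fit(self, warp="sinh-arcsinh", n_starts=3, maxiter=300, fixed_alpha=None):
        """Fit by marginal-likelihood maximization.

        Parameters
        ----------
        warp : {"sinh-arcsinh", "identity"}
            "identity" pins epsilon = 0, delta = 1 and optimizes only the
            precisions (a plain Bayesian linear regression on the
            standardized response).
        n_starts : int
            Number of deterministic multi-starts over the warp parameters
            (reduces the risk of local optima in the skew direction).
        fixed_alpha : float, optional
            Pin the prior precision (e.g. a value near zero approximates a
            flat prior, whose posterior mean is the least-squares solution).
        """
        if warp not in ("sinh-arcsinh", "identity"):
            raise ValueError(f"unknown warp {warp!r}")
        identity = warp == "identity"
        la0 = 0.0 if fixed_alpha is None else float(np.log(fixed_alpha))

        starts = [(la0, 0.0, 0.0, 0.0), (la0, 0.0, 0.7, 0.0), (la0, 0.0, -0.7, 0.0)]
        starts = starts[: max(1, n_starts)]
        bounds_full = [(-12.0, 12.0), (-12.0, 12.0), (-2.0, 2.0), (-1.6, 1.6)]

        def pack(x):
            full = list(x)
            if fixed_alpha is not None:
                full = [la0] + full
            if identity:
                full = full + [0.0, 0.0]
            return full

        best = None
        diagnostics = []
        for s in starts if not identity else starts[:1]:
            x0 = list(s)
            bounds = list(bounds_full)
            if identity:
                x0, bounds = x0[:2], bounds[:2]
            if fixed_alpha is not None:
                x0, bounds = x0[1:], bounds[1:]
            res = optimize.minimize(
                lambda x: self._neg_log_evidence(*pack(x)),
                x0=np.asarray(x0),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
            diagnostics.append(res)
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError(
                "marginal-likelihood optimization failed for every start: "
                + "; ".join(str(d.message) for d in diagnostics)
            )
        la, lb, eps, ld = pack(best.x)
        return self._results_at(np.exp(la), np.exp(lb), eps, np.exp(ld), -best.fun, best)

    def _results_at(self, alpha, beta, eps, delta, log_evidence, optres=None):
        warp = WarpParams(epsilon=float(eps), delta=float(delta), shift=self._shift, scale=self._scale)
        t = warp.transform(self.endog)
        d_eig = alpha + beta * self._eigvals
        cov = (self._eigvecs / d_eig) @ self._eigvecs.T
        mean = beta * (cov @ (self.exog.T @ t))
        return WarpedBLRResults(
            model=self,
            alpha=float(alpha),
            beta=float(beta),
            warp=warp,
            coef_mean=mean,
            coef_cov=cov,
            log_evidence=float(log_evidence),
            train_warped_mean=float(t.mean()),
            train_warped_var=float(t.var()),
            optimizer_result=optres,
        )


class WarpedBLRResults:
    """Fitted warped BLR: posterior weights, warp, and prediction methods."""

    def __init__(
        self,
        model,
        alpha,
        beta,
        warp,
        coef_mean,
        coef_cov,
        log_evidence,
        train_warped_mean,
        train_warped_var,
        optimizer_result=None,
    ):
        self.model = model
        self.alpha = alpha
        self.beta = beta
        self.warp = warp
        self.coef_mean = np.asarray(coef_mean, dtype=float)
        self.coef_cov = np.asarray(coef_cov, dtype=float)
        self.log_evidence = log_evidence
        self.train_warped_mean = train_warped_mean
        self.train_warped_var = train_warped_var
        self.optimizer_result = optimizer_result

    @property
    def nobs(self):
        return self.model.nobs

    def _check_exog(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.coef_mean.shape[0]:
            raise ValueError(
                f"design has {x.shape[1]} columns, model expects {self.coef_mean.shape[0]}"
            )
        return x

    def predict(self, exog):
        """Posterior predictive mean and variance in warped space.

        Variance is the noise variance plus the design-projected posterior
        weight uncertainty, hence strictly positive.
        """
        x = self._check_exog(exog)
        mean = x @ self.coef_mean
        # quadratic form is >= 0 (posterior covariance PSD), so var >= 1/beta > 0
        var = 1.0 / self.beta + np.einsum("ij,jk,ik->i", x, self.coef_cov, x)
        return mean, var

    def predicted_median(self, exog):
        """Predicted median of the response in its original units."""
        mean, _ = self.predict(exog)
        return self.warp.inverse(mean)

    def predict_centiles(self, exog, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)):
        """Predictive centile curves in original response units."""
        mean, var = self.predict(exog)
        sd = np.sqrt(var)
        return {q: self.warp.inverse(mean + stats.norm.ppf(q) * sd) for q in quantiles}

    def deviation_scores(self, exog, endog):
        """Deviation (Z) scores: standardized warped residuals.

        Positive Z means the observed value is above the covariate-expected
        value (the warp is monotone increasing, so Z is strictly
        increasing in y at fixed covariates).
        """
        y = np.asarray(endog, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            bad = np.flatnonzero(~np.isfinite(y))
            raise ValueError(f"non-finite response at rows {bad.tolist()[:10]}")
        x = self._check_exog(exog)
        if x.shape[0] != y.shape[0]:
            raise ValueError("endog/exog row mismatch")
        mean, var = self.predict(x)
        return (self.warp.transform(y) - mean) / np.sqrt(var)

    def evaluate(self, exog, endog):
        """:func:`evaluate_fit` against this model's training baseline."""
        x = self._check_exog(exog)
        y = np.asarray(endog, dtype=float).ravel()
        mean, var = self.predict(x)
        t = self.warp.transform(y)
        z = (t - mean) / np.sqrt(var)
        return evaluate_fit(z, t, mean, var, self.train_warped_mean, self.train_warped_var)

    def to_dict(self):
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "warp": asdict(self.warp),
            "coef_mean": self.coef_mean.tolist(),
            "coef_cov": self.coef_cov.tolist(),
            "log_evidence": self.log_evidence,
            "train_warped_mean": self.train_warped_mean,
            "train_warped_var": self.train_warped_var,
            "column_names": self.model.column_names,
            "nobs": self.model.nobs,
        }

    @classmethod
    def from_dict(cls, d):
        model = _DeserializedModel(d["column_names"], d["nobs"])
        return cls(
            model=model,
            alpha=d["alpha"],
            beta=d["beta"],
            warp=WarpParams(**d["warp"]),
            coef_mean=np.asarray(d["coef_mean"], dtype=float),
            coef_cov=np.asarray(d["coef_cov"], dtype=float),
            log_evidence=d["log_evidence"],
            train_warped_mean=d["train_warped_mean"],
            train_warped_var=d["train_warped_var"],
        )

    def summary(self):
        lines = [
            "Warped Bayesian Linear Regression Results",
            "=" * 45,
            f"No. observations: {self.model.nobs:>8d}",
            f"Design columns:   {len(self.coef_mean):>8d}",
            f"log evidence:     {self.log_evidence:>12.3f}",
            f"alpha (prior precision): {self.alpha:12.5g}",
            f"beta (noise precision):  {self.beta:12.5g}",
            f"warp epsilon (skew):     {self.warp.epsilon:12.5g}",
            f"warp delta (tails):      {self.warp.delta:12.5g}",
            "-" * 45,
            f"{'column':<20s}{'post. mean':>12s}{'post. sd':>12s}",
        ]
        sds = np.sqrt(np.diag(self.coef_cov))
        for name, m, s in zip(self.model.column_names, self.coef_mean, sds):
            lines.append(f"{name:<20s}{m:>12.4f}{s:>12.4f}")
        return "\n".join(lines)


class _DeserializedModel:
    """Minimal stand-in carrying metadata for results loaded from disk."""

    def __init__(self, column_names, nobs):
        self.column_names = list(column_names)
        self.nobs = int(nobs)
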