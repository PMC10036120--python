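"""Per-feature normative model sets over covariate/feature tables.

A :class:`NormativeModelSet` fits one :class:`~normbench.blr.WarpedBLR`
per feature column against a shared design (age spline, sex, quality
metric, site indicators), produces deviation-score tables, evaluates fit
metrics, and supports transfer to unseen sites by affine recalibration of
the deviation scores from a small adaptation sample of controls — the
pre-trained weights are never refit.
"""

from __future__ import annotations

import copy
import json

import numpy as np
import pandas as pd

from .blr import WarpedBLR, WarpedBLRResults, evaluate_fit
from .design import DesignSpec, build_design_matrix

__all__ = ["NormativeModelSet", "transfer_recalibrate"]

MIN_ADAPTATION_SUBJECTS = 10


class NormativeModelSet:
    """A collection of fitted per-feature warped BLR normative models.

    Build with :meth:`fit`; query with :meth:`deviation_scores`,
    :meth:`metrics`, :meth:`transfer`, :meth:`summary`.
    """

    def __init__(self, spec, feature_names, results, site_calibration=None):
        self.spec = spec
        self.feature_names = list(feature_names)
        self.results = list(results)
        # site -> {"shift": (p,) array, "scale": (p,) array}
        self.site_calibration = site_calibration or {}

    # -- construction -----------------------------------------------------

    @classmethod
    def fit(cls, covariates, features, spec=None, warp="sinh-arcsinh", n_starts=3):
        """Fit one warped BLR per feature column.

        ``covariates`` and ``features`` are subject-indexed DataFrames with
        identical indices; ``spec`` defaults to a design learned from the
        training covariates (cubic spline, 5 interior knots at age
        quantiles).
        """
        if not features.index.equals(covariates.index):
            features = features.loc[covariates.index]
        if spec is None:
            spec = DesignSpec.from_training(covariates)
        x, names = build_design_matrix(covariates, spec)
        results = []
        for col in features.columns:
            model = WarpedBLR(features[col].to_numpy(dtype=float), x, column_names=names)
            results.append(model.fit(warp=warp, n_starts=n_starts))
        return cls(spec, list(features.columns), results)

    # -- prediction -------------------------------------------------------

    def _design(self, covariates, allow_unseen_sites=False):
        x, _ = build_design_matrix(covariates, self.spec, allow_unseen_sites=allow_unseen_sites)
        return x

    def _check_features(self, features):
        if list(features.columns) != self.feature_names:
            raise ValueError("feature columns do not match the fitted models")

    def _calibrated_predictive(self, covariates, features):
        """Warped targets and per-subject predictive mean/variance with any
        site calibration folded in.

        The transfer recalibration ``Z' = (Z - shift)/sqrt(scale)`` is
        equivalent to shifting the predictive mean by ``shift * sd`` and
        scaling the predictive variance by ``scale``, so deviation scores
        and fit metrics share one predictive distribution.
        """
        self._check_features(features)
        features = features.loc[covariates.index]
        sites = covariates[self.spec.site_col].astype(str)
        unknown = sorted(set(sites.unique()) - set(self.spec.sites) - set(self.site_calibration))
        if unknown:
            raise ValueError(
                f"site label(s) {unknown} are neither in the training design nor calibrated; "
                "run transfer() first"
            )
        x = self._design(covariates, allow_unseen_sites=bool(self.site_calibration))
        n, p = len(covariates), len(self.feature_names)
        t = np.empty((n, p))
        mean = np.empty((n, p))
        var = np.empty((n, p))
        for j, (col, res) in enumerate(zip(self.feature_names, self.results)):
            y = features[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(y)):
                bad = features.index[~np.isfinite(y)].tolist()[:10]
                raise ValueError(f"non-finite values in feature {col!r} for subjects {bad}")
            t[:, j] = res.warp.transform(y)
            mean[:, j], var[:, j] = res.predict(x)
        for site, cal in self.site_calibration.items():
            rows = (sites == site).to_numpy()
            if rows.any():
                mean[rows] += cal["shift"] * np.sqrt(var[rows])
                var[rows] *= cal["scale"]
        return t, mean, var

    def deviation_scores(self, covariates, features):
        """Deviation (Z) score table for the given subjects.

        Sites present in the calibration table get the transfer
        recalibration ``Z' = (Z - shift)/sqrt(scale)``; sites seen at fit
        time are scored directly; any other site raises.
        """
        t, mean, var = self._calibrated_predictive(covariates, features)
        z = (t - mean) / np.sqrt(var)
        return pd.DataFrame(z, index=covariates.index, columns=self.feature_names)

    def metrics(self, covariates, features):
        """Per-feature fit metrics (EV, MSLL, Z skew, Z excess kurtosis),
        computed under the calibrated predictive distribution."""
        t, mean, var = self._calibrated_predictive(covariates, features)
        z = (t - mean) / np.sqrt(var)
        rows = []
        for j, (col, res) in enumerate(zip(self.feature_names, self.results)):
            m = evaluate_fit(
                z[:, j], t[:, j], mean[:, j], var[:, j],
                res.train_warped_mean, res.train_warped_var,
            )
            rows.append(m.to_dict())
        return pd.DataFrame(rows, index=self.feature_names)

    # -- transfer ---------------------------------------------------------

    def transfer(self, covariates, features, new_site=None, min_adaptation=MIN_ADAPTATION_SUBJECTS):
        """Recalibrate to an unseen site from an adaptation sample.

        The adaptation subjects must all come from one site. Their
        uncalibrated deviation scores define a per-feature mean shift and
        variance scale; subsequent scoring of that site applies
        ``Z' = (Z - shift)/sqrt(scale)``. Returns a new model set; the
        original (and its scoring of known sites) is unchanged.
        """
        sites = covariates[self.spec.site_col].astype(str).unique()
        if len(sites) != 1:
            raise ValueError(f"adaptation sample spans multiple sites: {sorted(sites)}")
        site = sites[0]
        if new_site is not None and str(new_site) != site:
            raise ValueError(f"adaptation subjects are from {site!r}, not {new_site!r}")
        if len(covariates) < min_adaptation:
            raise ValueError(
                f"adaptation sample has {len(covariates)} subjects; need >= {min_adaptation}"
            )
        self._check_features(features)
        features = features.loc[covariates.index]
        x = self._design(covariates, allow_unseen_sites=True)
        z = np.column_stack(
            [
                res.deviation_scores(x, features[col].to_numpy(dtype=float))
                for col, res in zip(self.feature_names, self.results)
            ]
        )
        new = copy.copy(self)
        new.site_calibration = dict(self.site_calibration)
        new.site_calibration[site] = {"shift": z.mean(axis=0), "scale": z.var(axis=0, ddof=1)}
        return new

    # -- serialization ----------------------------------------------------

    def to_dict(self):
        return {
            "spec": self.spec.to_dict(),
            "feature_names": self.feature_names,
            "results": [r.to_dict() for r in self.results],
            "site_calibration": {
                s: {"shift": c["shift"].tolist(), "scale": c["scale"].tolist()}
                for s, c in self.site_calibration.items()
            },
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            spec=DesignSpec.from_dict(d["spec"]),
            feature_names=d["feature_names"],
            results=[WarpedBLRResults.from_dict(r) for r in d["results"]],
            site_calibration={
                s: {
                    "shift": np.asarray(c["shift"], dtype=float),
                    "scale": np.asarray(c["scale"], dtype=float),
                }
                for s, c in d["site_calibration"].items()
            },
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- reporting --------------------------------------------------------

    def summary(self):
        lines = [
            "Normative model set",
            "=" * 60,
            f"features: {len(self.feature_names)}   design columns: {len(self.results[0].coef_mean)}",
            f"training sites: {', '.join(self.spec.sites)}",
            f"calibrated transfer sites: {', '.join(sorted(self.site_calibration)) or '(none)'}",
            "-" * 60,
            f"{'feature':<14s}{'alpha':>10s}{'beta':>10s}{'epsilon':>10s}{'delta':>10s}",
        ]
        for name, r in zip(self.feature_names, self.results):
            lines.append(
                f"{name:<14s}{r.alpha:>10.3g}{r.beta:>10.3g}"
                f"{r.warp.epsilon:>10.3f}{r.warp.delta:>10.3f}"
            )
        return "\n".join(lines)

    def plot_centiles(self, covariates, features, feature, ax=None, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)):
        """Scatter one feature against age with predictive centile curves.

        Centiles are drawn for the reference site, the modal sex and the
        median quality metric of the supplied covariates.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = self.feature_names.index(feature)
        res = self.results[idx]
        age = covariates[self.spec.age_col].to_numpy(dtype=float)
        grid = pd.DataFrame(
            {
                self.spec.age_col: np.linspace(age.min(), age.max(), 200),
                self.spec.sex_col: covariates[self.spec.sex_col].mode().iloc[0],
                self.spec.site_col: self.spec.sites[0],
                self.spec.qc_col: covariates[self.spec.qc_col].median(),
            }
        )
        xg = self._design(grid, allow_unseen_sites=True)
        ax.scatter(age, features[feature], s=8, alpha=0.4, label="observed")
        for q, curve in res.predict_centiles(xg, quantiles).items():
            ax.plot(grid[self.spec.age_col], curve, lw=1.2, label=f"{int(q * 100)}th")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(feature)
        ax.legend(fontsize=7)
        return ax


def transfer_recalibrate(model_set, adaptation_covariates, adaptation_features, new_site=None, **kw):
    """Functional alias for :meth:`NormativeModelSet.transfer`."""
    return model_set.transfer(adaptation_covariates, adaptation_features, new_site=new_site, **kw)
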