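"""Design-matrix construction for normative models.

Age enters through a cubic B-spline basis with interior knots at training
age quantiles and linear extension beyond the training range; sex and the
scalar quality metric enter linearly; site enters as reference-coded
indicator columns (first site by sorted label dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["DesignSpec", "spline_basis", "build_design_matrix"]


@dataclass(frozen=True)
class DesignSpec:
    """Covariate-to-column mapping learned from a training covariate table."""

    knots: tuple
    age_bounds: tuple
    sites: tuple
    spline_degree: int = 3
    include_intercept: bool = True
    age_col: str = "age"
    sex_col: str = "sex"
    site_col: str = "site"
    qc_col: str = "qc"

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        lo, hi = self.age_bounds
        if knots.size and not np.all(np.diff(knots) > 0):
            raise ValueError("interior knots must be strictly increasing")
        if knots.size and (knots[0] <= lo or knots[-1] >= hi):
            raise ValueError("interior knots must lie strictly inside the training age range")
        if not lo < hi:
            raise ValueError("age_bounds must satisfy min < max")
        if self.spline_degree < 1:
            raise ValueError("spline_degree must be >= 1")

    @classmethod
    def from_training(cls, covariates, n_interior_knots=5, spline_degree=3, **kwargs):
        """Place interior knots at evenly spaced quantiles of training age."""
        age_col = kwargs.get("age_col", "age")
        site_col = kwargs.get("site_col", "site")
        for col in (age_col, kwargs.get("sex_col", "sex"), site_col, kwargs.get("qc_col", "qc")):
            if col not in covariates.columns:
                raise ValueError(f"covariate table missing required column {col!r}")
        age = covariates[age_col].to_numpy(dtype=float)
        qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
        knots = tuple(np.unique(np.quantile(age, qs)))
        sites = tuple(sorted(covariates[site_col].astype(str).unique()))
        return cls(
            knots=knots,
            age_bounds=(float(age.min()), float(age.max())),
            sites=sites,
            spline_degree=spline_degree,
            **kwargs,
        )

    @property
    def n_spline_columns(self):
        return len(self.knots) + self.spline_degree + 1

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["knots"] = tuple(d["knots"])
        d["age_bounds"] = tuple(d["age_bounds"])
        d["sites"] = tuple(d["sites"])
        return cls(**d)


def spline_basis(age, spec):
    """B-spline basis evaluated at ``age`` with linear extension outside
    the training range (first-order Taylor expansion at the boundary)."""
    age = np.asarray(age, dtype=float)
    lo, hi = spec.age_bounds
    k = spec.spline_degree
    t = np.concatenate([[lo] * (k + 1), np.asarray(spec.knots, dtype=float), [hi] * (k + 1)])
    clipped = np.clip(age, lo, hi)
    n_basis = len(t) - k - 1
    basis = np.empty((age.size, n_basis))
    outside = (age < lo) | (age > hi)
    delta = age - clipped
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        spl = BSpline(t, coef, k, extrapolate=False)
        vals = spl(clipped)
        vals = np.nan_to_num(vals, nan=0.0)
        if np.any(outside):
            dvals = spl.derivative()(clipped[outside])
            dvals = np.nan_to_num(dvals, nan=0.0)
            vals[outside] = vals[outside] + dvals * delta[outside]
        basis[:, j] = vals
    return basis


def build_design_matrix(covariates, spec, allow_unseen_sites=False):
    """Build the normative design matrix from a covariate table.

    Column order is deterministic: intercept, spline(age), sex, qc, site
    indicators (reference coding drops the first site by sorted label).
    Unseen site labels raise unless ``allow_unseen_sites`` (the transfer
    workflow), in which case their indicator columns are all zero and the
    per-site recalibration is expected to absorb the offset.

    Returns ``(X, column_names)``.
    """
    for col in (spec.age_col, spec.sex_col, spec.site_col, spec.qc_col):
        if col not in covariates.columns:
            raise ValueError(f"covariate table missing required column {col!r}")
    site = covariates[spec.site_col].astype(str)
    unseen = sorted(set(site.unique()) - set(spec.sites))
    if unseen and not allow_unseen_sites:
        raise ValueError(
            f"site label(s) {unseen} were not seen at fit time; "
            "use the transfer workflow for new sites"
        )
    cols, names = [], []
    n = len(covariates)
    if spec.include_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    sb = spline_basis(covariates[spec.age_col].to_numpy(dtype=float), spec)
    for j in range(sb.shape[1]):
        cols.append(sb[:, j])
        names.append(f"age_spline{j}")
    cols.append(covariates[spec.sex_col].to_numpy(dtype=float))
    names.append("sex")
    cols.append(covariates[spec.qc_col].to_numpy(dtype=float))
    names.append("qc")
    for s in spec.sites[1:]:
        cols.append((site == s).to_numpy(dtype=float))
        names.append(f"site[{s}]")
    return np.column_stack(cols), names
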