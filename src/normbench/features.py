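"""Feature-table utilities: connectome edge derivation, QC filtering, residualization.

Feature tables are pandas DataFrames (rows = subjects, columns = brain
features), indexed by subject id. Covariate tables are DataFrames indexed
by subject id with columns ``age`` (years), ``sex`` (0/1), ``site``
(string label), ``qc`` (scalar image-quality metric: rescaled Euler number
for structural features, mean framewise displacement in mm for functional
features) and optionally ``group`` and ``cognition``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "fisher_r_to_z",
    "fisher_z_to_r",
    "average_runs",
    "vectorize_upper_triangle",
    "matrix_from_upper_triangle",
    "qc_filter_subjects",
    "residualize_features",
    "connectome_feature_table",
    "read_table",
    "write_table",
]


def fisher_r_to_z(r):
    """Fisher r-to-z transform, ``arctanh(r)``.

    Defined only for correlations strictly inside (-1, 1); values at or
    beyond the boundary would map to +/-inf and are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_r_to_z requires |r| < 1 for every element")
    return np.arctanh(r)


def fisher_z_to_r(z):
    """Inverse Fisher transform, ``tanh(z)``."""
    return np.tanh(np.asarray(z, dtype=float))


def _check_square_symmetric(m, tol):
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > tol:
        raise ValueError(f"matrix is asymmetric beyond tolerance: max |M - M.T| = {asym:.3g}")
    return m


def average_runs(matrices, tol=1e-8):
    """Element-wise mean of per-run connectivity matrices for one subject."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("average_runs requires at least one matrix")
    checked = [_check_square_symmetric(m, tol) for m in matrices]
    shapes = {m.shape for m in checked}
    if len(shapes) > 1:
        raise ValueError(f"run matrices have mismatched shapes: {sorted(shapes)}")
    return np.mean(checked, axis=0)


def vectorize_upper_triangle(matrix, labels=None, tol=1e-8):
    """Vectorize the strict upper triangle of a symmetric matrix.

    Returns ``(values, names)`` where values follow row-major order of the
    strict upper triangle (length n(n-1)/2) and names pair the node labels
    as ``"a-b"``. The diagonal is excluded.
    """
    m = _check_square_symmetric(matrix, tol)
    n = m.shape[0]
    if labels is None:
        labels = [f"n{i + 1:02d}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    iu, ju = np.triu_indices(n, k=1)
    values = m[iu, ju]
    names = [f"{labels[i]}-{labels[j]}" for i, j in zip(iu, ju)]
    return values, names


def matrix_from_upper_triangle(values, n, diag=1.0):
    """Rebuild a symmetric matrix from its strict-upper-triangle vector."""
    values = np.asarray(values, dtype=float)
    if values.size != n * (n - 1) // 2:
        raise ValueError(f"expected {n * (n - 1) // 2} values for n={n}, got {values.size}")
    m = np.full((n, n), float(diag))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = values
    m[ju, iu] = values
    return m


def qc_filter_subjects(qc, euler_max=10.0, fd_max_mm=0.5):
    """Subjects passing both image-quality gates (strict inequalities).

    ``qc`` is a DataFrame with columns ``euler`` (rescaled Euler number)
    and ``mean_fd`` (mm), indexed by subject id or carrying a
    ``subject_id`` column. Keeps rows with euler < euler_max and
    mean_fd < fd_max_mm, preserving input order.
    """
    if euler_max <= 0 or fd_max_mm <= 0:
        raise ValueError("QC thresholds must be positive")
    qc = qc.set_index("subject_id") if "subject_id" in qc.columns else qc
    missing = {"euler", "mean_fd"} - set(qc.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    keep = (qc["euler"] < euler_max) & (qc["mean_fd"] < fd_max_mm)
    return list(qc.index[keep])


def _nuisance_design(covariates, include_motion):
    required = {"age", "sex", "site"} | ({"qc"} if include_motion else set())
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    age = covariates["age"].to_numpy(dtype=float)
    cols = [np.ones(len(covariates)), covariates["sex"].to_numpy(dtype=float), age, age**2]
    names = ["intercept", "sex", "age", "age2"]
    sites = sorted(covariates["site"].astype(str).unique())
    for site in sites[1:]:
        cols.append((covariates["site"].astype(str) == site).to_numpy(dtype=float))
        names.append(f"site[{site}]")
    if include_motion:
        motion = covariates["qc"].to_numpy(dtype=float)
        cols += [motion, motion**2]
        names += ["motion", "motion2"]
    return np.column_stack(cols), names


def residualize_features(features, covariates, include_motion=False):
    """OLS-residualize every feature column on nuisance covariates.

    The nuisance design is intercept, sex, site indicators, age, age^2 and
    (for functional features) motion and motion^2, fit by least squares on
    the pooled sample; residuals replace the feature values.
    """
    if not set(features.index).issubset(set(covariates.index)):
        missing = sorted(set(features.index) - set(covariates.index))[:5]
        raise ValueError(f"covariates missing for subjects: {missing} ...")
    cov = covariates.loc[features.index]
    x, _ = _nuisance_design(cov, include_motion)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank}/{x.shape[1]}); using pseudoinverse",
            RuntimeWarning,
        )
    y = features.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


def connectome_feature_table(runs, labels=None, order="fisher_then_average", tol=1e-8):
    """Turn per-subject run-level correlation matrices into an edge table.

    ``runs`` maps subject id -> list of symmetric full-correlation matrices.
    Each run is Fisher r-to-z transformed and runs are averaged
    (``order="fisher_then_average"``, the default) or averaged first and
    transformed once (``"average_then_fisher"``); the strict upper triangle
    of the resulting z-matrix becomes the subject's feature row.
    """
    if order not in ("fisher_then_average", "average_then_fisher"):
        raise ValueError(f"unknown order: {order!r}")
    rows, index, names = [], [], None
    for subject, mats in runs.items():
        if order == "fisher_then_average":
            zmats = []
            for m in mats:
                m = _check_square_symmetric(m, tol)
                off = m - np.diag(np.diag(m))
                z = fisher_r_to_z(off)
                zmats.append(z)
            zbar = average_runs(zmats, tol=tol)
        else:
            rbar = average_runs(mats, tol=tol)
            zbar = fisher_r_to_z(rbar - np.diag(np.diag(rbar)))
        values, names = vectorize_upper_triangle(zbar, labels=labels, tol=tol)
        rows.append(values)
        index.append(subject)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"), columns=names)
    return table


def read_table(path):
    """Read a subject-indexed CSV table (feature or covariate)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'subject_id' column")
    return df.set_index("subject_id")


def write_table(df, path):
    """Write a subject-indexed table as CSV with a subject_id column."""
    out = df.copy()
    out.index.name = "subject_id"
    out.to_csv(path)
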