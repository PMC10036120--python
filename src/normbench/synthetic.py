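"""Synthetic multi-site cohorts with known ground truth.

The generator emulates the statistical structure of multi-site
imaging-derived phenotype studies: several scanning sites with distinct
age windows, smooth nonlinear lifespan trends per feature (a logistic
developmental rise plus a linear late-life decline), a small additive sex
effect, a linear image-quality effect, additive per-site offsets and
multiplicative per-site noise scales, optionally skewed residual noise
(inverse sinh-arcsinh of a Gaussian), and a patient subgroup carrying
both a small shared group shift on a designated feature subset and
heterogeneous, spatially non-overlapping individual deviations. A latent
cognition score is driven by a linear projection of the features.

Default parameter values are the study conditions used throughout the
package's tests and reported runs; see docs/methods.md for the rationale
behind each choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "ConnectomeTruth",
    "generate_cohort",
    "generate_connectome_runs",
    "generate_cognition",
]


@dataclass
class CohortConfig:
    """Configuration of a synthetic multi-site cohort.

    Effect sizes are expressed in units of the (unit) residual noise SD.
    """

    n_sites: int = 4
    subjects_per_site: int = 150
    age_range_per_site: tuple = None
    site_offset_sd: float = 1.0
    site_scale_sd: float = 0.3
    n_features: int = 20
    patient_fraction: float = 0.25
    patient_site_shares: tuple = None
    shared_effect_size: float = 0.6
    group_effect_fraction: float = 0.3
    hetero_effect_size: float = 1.5
    hetero_feature_count: int = 5
    noise_skew: float = 0.5
    sex_effect_sd: float = 0.3
    qc_effect_sd: float = 0.05
    cognition_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.subjects_per_site < 2:
            raise ValueError("subjects_per_site must be >= 2 (later splits need both halves)")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0.0 <= self.patient_fraction <= 1.0:
            raise ValueError("patient_fraction must lie in [0, 1]")
        if self.site_offset_sd < 0 or self.site_scale_sd < 0:
            raise ValueError("site offset/scale spreads must be nonnegative")
        if self.hetero_feature_count < 0:
            raise ValueError("hetero_feature_count must be >= 0")
        if self.patient_fraction > 0 and self.hetero_feature_count > self.n_features:
            raise ValueError("hetero_feature_count cannot exceed n_features")
        if self.age_range_per_site is None:
            self.age_range_per_site = _default_age_ranges(self.n_sites)
        self.age_range_per_site = tuple(tuple(map(float, r)) for r in self.age_range_per_site)
        if len(self.age_range_per_site) != self.n_sites:
            raise ValueError("age_range_per_site must list one (min, max) pair per site")
        for lo, hi in self.age_range_per_site:
            if not lo < hi:
                raise ValueError(f"age range must have min < max, got ({lo}, {hi})")
        if self.patient_site_shares is None:
            self.patient_site_shares = _default_patient_shares(self.n_sites)
        self.patient_site_shares = tuple(float(s) for s in self.patient_site_shares)
        if len(self.patient_site_shares) != self.n_sites:
            raise ValueError("patient_site_shares must list one share per site")
        if any(s < 0 for s in self.patient_site_shares) or sum(self.patient_site_shares) <= 0:
            raise ValueError("patient_site_shares must be nonnegative and sum to > 0")

    @property
    def n_subjects(self):
        return self.n_sites * self.subjects_per_site

    @property
    def site_labels(self):
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if d.get("age_range_per_site") is not None:
            d["age_range_per_site"] = tuple(tuple(r) for r in d["age_range_per_site"])
        return cls(**d)


def _default_patient_shares(n_sites):
    """Clinical-recruitment profile for patient allocation across sites.

    Reference (early) sites contribute a token few cases, the
    second-to-last site is a mixed clinical site, and the last site is the
    case-heavy recruitment site — the site-diagnosis confounding regime
    that motivates normative modeling in multi-site case-control studies.
    """
    if n_sites == 1:
        return (1.0,)
    if n_sites == 2:
        return (0.2, 0.8)
    rest = 0.05 / (n_sites - 2)
    return tuple([rest] * (n_sites - 2) + [0.15, 0.8])


def _apportion_patients(n_patients, shares, site_capacity):
    """Largest-remainder apportionment of patients to sites, capped by
    site size (overflow spills to the next-largest-share site)."""
    shares = np.asarray(shares, dtype=float) / np.sum(shares)
    ideal = n_patients * shares
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for j in np.argsort(-remainder)[: n_patients - counts.sum()]:
        counts[j] += 1
    order = np.argsort(-shares)
    for j in range(len(counts)):
        over = counts[j] - site_capacity
        if over > 0:
            counts[j] = site_capacity
            for k in order:
                if k == j:
                    continue
                room = site_capacity - counts[k]
                take = min(room, over)
                counts[k] += take
                over -= take
                if over == 0:
                    break
    return counts


def _default_age_ranges(n_sites):
    # distinct nested windows: early sites are wide lifespan cohorts, later
    # sites are narrower adult cohorts contained in them (a reference cohort
    # should cover the age support of any site it is transferred to)
    return tuple((6.0 + 4.0 * i, 85.0 - 5.0 * i) for i in range(n_sites))


def _skew_noise_moments(skew):
    """Mean and SD of sinh(asinh(G) + skew) for G ~ N(0,1), by Gauss-Hermite."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(96)
    w = weights / np.sqrt(2.0 * np.pi)
    x = np.sinh(np.arcsinh(nodes) + skew)
    m = float(np.sum(w * x))
    v = float(np.sum(w * (x - m) ** 2))
    return m, np.sqrt(v)


def _draw_skew_noise(rng, size, skew):
    g = rng.standard_normal(size)
    if skew == 0.0:
        return g
    m, s = _skew_noise_moments(skew)
    return (np.sinh(np.arcsinh(g) + skew) - m) / s


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`generate_cohort`."""

    baseline: np.ndarray
    amplitude: np.ndarray
    center: np.ndarray
    steepness: np.ndarray
    decline_slope: np.ndarray
    decline_onset: np.ndarray
    sex_effects: np.ndarray
    qc_effects: np.ndarray
    site_offsets: dict
    site_scales: dict
    group_effect_features: list
    per_patient_perturbations: dict
    cognition_loadings: np.ndarray
    cognition_noise_sd: float
    noise_skew: float

    def mean_function(self, age, sex, qc):
        """True noiseless feature values (before site offset/scale)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))[:, None]
        sex = np.atleast_1d(np.asarray(sex, dtype=float))[:, None]
        qc = np.atleast_1d(np.asarray(qc, dtype=float))[:, None]
        rise = self.amplitude / (1.0 + np.exp(-(age - self.center) / self.steepness))
        decline = self.decline_slope * np.maximum(age - self.decline_onset, 0.0)
        return self.baseline + rise - decline + sex * self.sex_effects + qc * self.qc_effects

    def to_json(self, path):
        def convert(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        d = {k: convert(v) for k, v in asdict(self).items()}
        d["per_patient_perturbations"] = {
            k: {"features": list(map(int, f)), "shifts": list(map(float, s))}
            for k, (f, s) in self.per_patient_perturbations.items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        arrays = [
            "baseline",
            "amplitude",
            "center",
            "steepness",
            "decline_slope",
            "decline_onset",
            "sex_effects",
            "qc_effects",
            "cognition_loadings",
        ]
        for k in arrays:
            d[k] = np.asarray(d[k], dtype=float)
        d["per_patient_perturbations"] = {
            k: (v["features"], v["shifts"]) for k, v in d["per_patient_perturbations"].items()
        }
        return cls(**d)


def _make_covariates(config):
    """Covariate table; drawn from a stream keyed only by (seed, 0) so that
    structural and connectome generators share identical subjects."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n = config.n_subjects
    ages = np.empty(n)
    sites = np.empty(n, dtype=object)
    for i, (label, (lo, hi)) in enumerate(zip(config.site_labels, config.age_range_per_site)):
        sl = slice(i * config.subjects_per_site, (i + 1) * config.subjects_per_site)
        ages[sl] = rng.uniform(lo, hi, config.subjects_per_site)
        sites[sl] = label
    sex = rng.integers(0, 2, n)
    qc = rng.gamma(shape=3.0, scale=1.2, size=n)  # Euler-like positive quality metric
    n_pat = int(round(config.patient_fraction * n))
    group = np.full(n, "control", dtype=object)
    per_site = _apportion_patients(n_pat, config.patient_site_shares, config.subjects_per_site)
    patient_idx = []
    for i, count in enumerate(per_site):
        base = i * config.subjects_per_site
        if count:
            patient_idx.extend(base + rng.choice(config.subjects_per_site, size=count, replace=False))
    patient_idx = np.asarray(sorted(patient_idx), dtype=int)
    group[patient_idx] = "patient"
    index = pd.Index([f"sub-{i + 1:04d}" for i in range(n)], name="subject_id")
    cov = pd.DataFrame(
        {"age": ages, "sex": sex, "site": sites, "qc": qc, "group": group}, index=index
    )
    return cov, np.sort(patient_idx)


def generate_cohort(config):
    """Generate covariates, features and ground truth for one cohort.

    Returns ``(covariates, features, truth)``. Features are
    ``mean_function(age, sex, qc) + site_offset + site_scale * noise``,
    with the noise optionally skewed; patients additionally receive the
    shared group shift on the designated feature subset and
    ``hetero_feature_count`` per-patient negative shifts on features drawn
    independently per patient.
    """
    cov, patient_idx = _make_covariates(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n, p = config.n_subjects, config.n_features

    truth = SyntheticTruth(
        baseline=rng.normal(0.0, 1.0, p),
        amplitude=rng.uniform(2.0, 5.0, p),
        center=rng.uniform(10.0, 25.0, p),
        steepness=rng.uniform(3.0, 8.0, p),
        decline_slope=rng.uniform(0.01, 0.04, p),
        decline_onset=rng.uniform(30.0, 50.0, p),
        sex_effects=rng.normal(0.0, config.sex_effect_sd, p),
        qc_effects=rng.normal(0.0, config.qc_effect_sd, p),
        site_offsets={
            s: float(o)
            for s, o in zip(config.site_labels, rng.normal(0.0, config.site_offset_sd, config.n_sites))
        },
        site_scales={
            s: float(np.exp(v))
            for s, v in zip(config.site_labels, rng.normal(0.0, config.site_scale_sd, config.n_sites))
        },
        group_effect_features=[],
        per_patient_perturbations={},
        cognition_loadings=rng.normal(0.0, 1.0, p) / np.sqrt(p),
        cognition_noise_sd=config.cognition_noise_sd,
        noise_skew=config.noise_skew,
    )

    y = truth.mean_function(cov["age"], cov["sex"], cov["qc"])
    offsets = cov["site"].map(truth.site_offsets).to_numpy(dtype=float)
    scales = cov["site"].map(truth.site_scales).to_numpy(dtype=float)
    noise = _draw_skew_noise(rng, (n, p), config.noise_skew)
    y = y + offsets[:, None] + scales[:, None] * noise

    n_group_feat = max(1, int(round(config.group_effect_fraction * p)))
    group_feat = np.sort(rng.choice(p, size=n_group_feat, replace=False))
    truth.group_effect_features = [int(j) for j in group_feat]
    if patient_idx.size:
        y[np.ix_(patient_idx, group_feat)] -= config.shared_effect_size
        for i in patient_idx:
            feats = np.sort(rng.choice(p, size=config.hetero_feature_count, replace=False))
            shifts = np.full(config.hetero_feature_count, -config.hetero_effect_size)
            y[i, feats] += shifts
            truth.per_patient_perturbations[cov.index[i]] = (
                [int(j) for j in feats],
                [float(s) for s in shifts],
            )

    features = pd.DataFrame(
        y, index=cov.index, columns=[f"feat{j + 1:03d}" for j in range(p)]
    )
    return cov, features, truth


@dataclass
class ConnectomeTruth:
    """Ground truth for run-level connectome generation."""

    population_z: np.ndarray
    age_slopes_z: np.ndarray
    site_offsets_z: dict
    group_effect_edges: list
    per_patient_perturbations: dict
    true_matrices: dict = field(repr=False, default_factory=dict)
    subject_sd_z: float = 0.2
    run_noise_sd: float = 0.1
    cognition_loadings: np.ndarray = None
    cognition_noise_sd: float = 0.5


def _symmetrize_from_edges(vec, n):
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = vec
    m[ju, iu] = vec
    return m


def generate_connectome_runs(config, n_networks, n_runs=2, run_noise_sd=0.1):
    """Generate per-subject run-level between-network full-correlation matrices.

    Subject-level truth lives in Fisher z-space (population edge means,
    edge-wise age slopes, attenuated site offsets, patient shifts, subject
    idiosyncrasy); correlations are ``tanh`` of the z edges so off-diagonals
    stay strictly inside (-1, 1) with an exact unit diagonal. Runs are
    noisy z-space realizations of the subject's true matrix.

    Returns ``(covariates, runs, truth)`` where ``runs`` maps subject id to
    a list of ``n_runs`` symmetric matrices.
    """
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cov, patient_idx = _make_covariates(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    n_edges = n_networks * (n_networks - 1) // 2
    subject_sd = 0.2

    truth = ConnectomeTruth(
        population_z=rng.normal(0.25, 0.25, n_edges),
        age_slopes_z=rng.normal(0.0, 0.05, n_edges),
        site_offsets_z={
            s: float(o)
            for s, o in zip(
                config.site_labels, rng.normal(0.0, 0.15 * config.site_offset_sd, config.n_sites)
            )
        },
        group_effect_edges=[],
        per_patient_perturbations={},
        subject_sd_z=subject_sd,
        run_noise_sd=run_noise_sd,
        cognition_loadings=rng.normal(0.0, 1.0, n_edges) / np.sqrt(n_edges),
        cognition_noise_sd=config.cognition_noise_sd,
    )
    n_group = max(1, int(round(config.group_effect_fraction * n_edges)))
    group_edges = np.sort(rng.choice(n_edges, size=n_group, replace=False))
    truth.group_effect_edges = [int(j) for j in group_edges]

    ages = cov["age"].to_numpy(dtype=float)
    age_z = (ages - ages.mean()) / ages.std()
    patient_set = set(patient_idx.tolist())
    hetero_k = min(config.hetero_feature_count, n_edges)

    runs = {}
    for i, subject in enumerate(cov.index):
        edges = (
            truth.population_z
            + truth.age_slopes_z * age_z[i]
            + truth.site_offsets_z[cov["site"].iloc[i]]
            + subject_sd * rng.standard_normal(n_edges)
        )
        if i in patient_set:
            edges[group_edges] -= config.shared_effect_size * subject_sd
            feats = np.sort(rng.choice(n_edges, size=hetero_k, replace=False))
            edges[feats] -= config.hetero_effect_size * subject_sd
            truth.per_patient_perturbations[subject] = (
                [int(j) for j in feats],
                [-config.hetero_effect_size * subject_sd] * hetero_k,
            )
        true_m = np.tanh(_symmetrize_from_edges(edges, n_networks))
        np.fill_diagonal(true_m, 1.0)
        truth.true_matrices[subject] = true_m
        subject_runs = []
        for _ in range(n_runs):
            noisy = edges + run_noise_sd * rng.standard_normal(n_edges)
            m = np.tanh(_symmetrize_from_edges(noisy, n_networks))
            np.fill_diagonal(m, 1.0)
            subject_runs.append(m)
        runs[subject] = subject_runs
    return cov, runs, truth


def generate_cognition(features, truth, seed):
    """Latent cognition score: standardized feature projection plus noise.

    ``cognition = standardize(features @ loadings) + N(0, noise_sd)``,
    returned standardized to mean 0 and variance 1.
    """
    loadings = np.asarray(truth.cognition_loadings, dtype=float)
    if loadings.shape[0] != features.shape[1]:
        raise ValueError(
            f"cognition loadings length {loadings.shape[0]} does not match "
            f"{features.shape[1]} feature columns"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    proj = features.to_numpy(dtype=float) @ loadings
    sd = proj.std()
    proj = (proj - proj.mean()) / sd if sd > 0 else np.zeros_like(proj)
    cog = proj + rng.normal(0.0, truth.cognition_noise_sd, len(proj))
    cog = (cog - cog.mean()) / cog.std()
    return pd.Series(cog, index=features.index, name="cognition")
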