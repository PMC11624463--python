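"""Mixture-density mobility composite (MDS1).

Each participant's set of daily feature vectors is modeled as a k=3
Gaussian mixture over a standardized feature space.  Pairwise dissimilarity
between participants is the L2 distance between mixture densities,

    D^2(f, g) = Integral (f - g)^2 = <f,f> + <g,g> - 2<f,g>,

with the cross terms available in closed form from the Gaussian product
integral, <f,g> = sum_ab w_a v_b N(mu_a - nu_b; 0, S_a + L_b).  Classical
(Torgerson) multidimensional scaling of the resulting distance matrix yields
a one-dimensional embedding, MDS1: a relative mobility-pattern score where
nearby values mean similar overall mobility distributions.  MDS1 is defined
only up to a global sign, so downstream correlations are interpreted through
their magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .features import FEATURE_COLUMNS

#: daily features entering the mixture by default: all but the
#: missing-minutes accounting column (missingness is a sensor artifact, not
#: mobility); pass ``features=FEATURE_COLUMNS`` for the strict all-13 variant
DEFAULT_GMM_FEATURES = [c for c in FEATURE_COLUMNS if c != "minutes_missing"]

DEFAULT_K = 3
DEFAULT_RIDGE = 1e-6
#: covariance floor used by the cohort composite, in squared standardized
#: units: a participant whose daily value of some feature never varies would
#: otherwise contribute a near-delta density spike that dominates every L2
#: integral in 12 dimensions; 1e-2 corresponds to a floor of 0.1 cohort SD,
#: roughly the day-to-day measurement granularity of the features
COHORT_RIDGE = 1e-2
DEFAULT_RESTARTS = 10
DEFAULT_TOL = 1e-8
#: a mixture component is only supportable with at least this many days
MIN_DAYS_PER_COMPONENT = 3


@dataclass
class MixtureDensityModel:
    participant_id: str
    weights: np.ndarray     # (k,)
    means: np.ndarray       # (k, p)
    covariances: np.ndarray  # (k, p, p)
    feature_names: list
    k_requested: int

    @property
    def k(self):
        return len(self.weights)


@dataclass
class Mds1Scores:
    participant_ids: list
    mds1: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: float


def fit_daily_gmm(daily_matrix, k=DEFAULT_K, seed=0, ridge=DEFAULT_RIDGE,
                  n_init=DEFAULT_RESTARTS, participant_id="", feature_names=None):
    """Maximum-likelihood Gaussian mixture over one participant's days.

    ``daily_matrix`` is (n_days, p), already standardized with cohort-level
    mean/SD.  EM with ``n_init`` seeded restarts and a ridge on covariance
    diagonals; deterministic given ``seed``.  When fewer than 3k days are
    available, k is reduced to the largest component count with at least 3
    days each (recorded on the returned model).
    """
    X = np.asarray(daily_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if len(X) < 1:
        raise ValueError("no usable days to fit a mixture")
    k_eff = max(1, min(k, len(X) // MIN_DAYS_PER_COMPONENT))
    if k_eff < k:
        warnings.warn(
            f"participant {participant_id or '?'}: only {len(X)} usable days; "
            f"mixture components reduced from {k} to {k_eff}")
    gm = GaussianMixture(n_components=k_eff, covariance_type="full",
                         reg_covar=ridge, n_init=n_init, tol=DEFAULT_TOL,
                         max_iter=500, random_state=seed)
    gm.fit(X)
    return MixtureDensityModel(
        participant_id=participant_id,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])],
        k_requested=k)


def _gauss_at_zero_offset(diff, cov):
    """N(diff; 0, cov) for a single covariance and vector."""
    p = len(diff)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    sol = np.linalg.solve(cov, diff)
    return float(np.exp(-0.5 * (diff @ sol)
                        - 0.5 * (p * np.log(2 * np.pi) + logdet)))


def _cross_term(m1, m2):
    acc = 0.0
    for a in range(m1.k):
        for b in range(m2.k):
            acc += m1.weights[a] * m2.weights[b] * _gauss_at_zero_offset(
                m1.means[a] - m2.means[b],
                m1.covariances[a] + m2.covariances[b])
    return acc


def gmm_l2_distance(m1: MixtureDensityModel, m2: MixtureDensityModel):
    """Squared L2 distance between two mixture densities (closed form).

    Always nonnegative (clamped at 0 for floating-point roundoff).  Raises on
    feature-dimension mismatch.
    """
    if m1.means.shape[1] != m2.means.shape[1]:
        raise ValueError("mixture models live in different feature spaces")
    d2 = _cross_term(m1, m1) + _cross_term(m2, m2) - 2.0 * _cross_term(m1, m2)
    return max(d2, 0.0)


def build_distance_matrix(models):
    """Symmetric matrix of pairwise squared L2 density distances."""
    if len(models) < 2:
        raise ValueError("need at least 2 mixture models")
    n = len(models)
    self_terms = [_cross_term(m, m) for m in models]
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = max(self_terms[i] + self_terms[j]
                     - 2.0 * _cross_term(models[i], models[j]), 0.0)
            M[i, j] = M[j, i] = d2
    ids = [m.participant_id for m in models]
    return ids, M


def classical_mds(squared_distances, orient=None):
    """Torgerson classical MDS, first dimension only.

    ``squared_distances`` holds squared dissimilarities (double-centered
    directly: B = -1/2 J D2 J).  Scores are sqrt(lambda_1) * v_1; negative
    eigenvalues are ignored for the variance fraction.  A nonpositive top
    eigenvalue (all-identical configuration) raises.  If ``orient`` is given,
    the global sign is chosen so that the scores correlate nonnegatively
    with it.
    """
    D2 = np.asarray(squared_distances, dtype=float)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= max(1e-12, 1e-10 * max(np.trace(B), 0.0)):
        raise ValueError("degenerate configuration: top MDS eigenvalue <= 0")
    if (evals < -1e-8 * evals[0]).any():
        warnings.warn("distance matrix is not perfectly Euclidean; negative "
                      "MDS eigenvalues ignored")
    scores = np.sqrt(evals[0]) * evecs[:, 0]
    if orient is not None:
        o = np.asarray(orient, dtype=float)
        ok = ~np.isnan(o)
        if ok.sum() >= 2 and np.std(o[ok]) > 0 and np.std(scores[ok]) > 0:
            r = np.corrcoef(scores[ok], o[ok])[0, 1]
            if r < 0:
                scores = -scores
    pos = evals[evals > 0]
    return scores, evals, float(evals[0] / pos.sum())


def cohort_mds1(daily_df, features=None, k=DEFAULT_K, seed=0,
                min_days=MIN_DAYS_PER_COMPONENT, ridge=COHORT_RIDGE):
    """Fit per-participant mixtures and extract MDS1 for the cohort.

    Daily features are z-standardized with cohort-level mean/SD before
    fitting (meters-scale features would otherwise dominate the density
    integral).  The MDS1 sign is fixed by nonnegative correlation with mean
    daily distance traveled.  Returns ``(scores_df, models, distance_matrix)``.
    """
    features = list(features) if features is not None else list(DEFAULT_GMM_FEATURES)
    use = daily_df.loc[~daily_df.get("excluded", False).astype(bool)].copy()
    X = use[features].to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd[sd == 0] = 1.0
    use[features] = (X - mu) / sd

    models = []
    mean_dist = []
    for pid, g in use.groupby("participant_id", sort=True):
        Xi = g[features].to_numpy(dtype=float)
        Xi = Xi[~np.isnan(Xi).any(axis=1)]
        if len(Xi) < min_days:
            warnings.warn(f"participant {pid}: fewer than {min_days} usable "
                          "days; omitted from composite")
            continue
        models.append(fit_daily_gmm(Xi, k=k, seed=seed, ridge=ridge,
                                    participant_id=str(pid),
                                    feature_names=features))
        mean_dist.append(np.nanmean(g["distance_traveled"].to_numpy(dtype=float)))
    ids, M = build_distance_matrix(models)
    scores, evals, varfrac = classical_mds(M, orient=np.asarray(mean_dist))
    df = pd.DataFrame({"participant_id": ids, "mds1": scores,
                       "variance_fraction": varfrac})
    return df, models, pd.DataFrame(M, index=ids, columns=ids)
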