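"""Admixture-model population structure and choice of the cluster number K.

The model: each accession i draws the two allele copies at marker j from K
ancestral populations with membership fractions q_i (a point on the simplex)
and population allele frequencies p_kj, so the alternate-allele dosage is
Binomial(2, theta_ij) with theta_ij = sum_k q_ik p_kj. Parameters are fitted
by maximum-likelihood EM (seeded random initialisation, monotone
log-likelihood), a deterministic desk-scale stand-in for MCMC samplers of the
same likelihood.

Two selectors for K are provided side by side:

* hold-out cross-validation error — random folds of genotype cells are
  masked, the model is refitted, and the masked dosages are predicted by
  their expectation 2 * Q P; the K minimising the mean squared error wins;
* the Evanno second-difference statistic on the fitted log-likelihood over
  replicate runs, Delta K = mean |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)),
  maximised over interior K.

Band code 4 (second InDel allele) is collapsed to alternate dosage 2 for
this module's biallelic likelihood.
"""

from __future__ import annotations

import logging
from math import comb, log

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._util import dosage_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "AdmixtureEM",
    "fit_admixture_em",
    "cv_error",
    "evanno_delta_k",
    "selection_table",
    "select_k_by_cv",
    "select_k_by_delta_k",
]

_EPS = 1e-6
_LOG_COMB = {0.0: 0.0, 1.0: log(comb(2, 1)), 2.0: 0.0}


def _as_dosage(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return dosage_matrix(X)
    X = np.asarray(X, dtype=float)
    valid = np.isnan(X) | np.isin(X, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("dosages must be 0, 1, 2 or NaN (missing)")
    return X


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture model fitted by EM.

    Parameters
    ----------
    n_populations : int
        Number of ancestral populations K (>= 1).
    max_iter : int
        Maximum EM iterations.
    tol : float
        Stop when the log-likelihood improves by less than this.
    random_state : int or None
        Seed for the random initialisation.

    Attributes (after :meth:`fit`)
    ------------------------------
    Q_ : ndarray (n_accessions, K) — membership fractions, rows sum to 1.
    P_ : ndarray (K, n_markers) — population alternate-allele frequencies.
    loglik_ : float — fitted data log-likelihood.
    loglik_path_ : list[float] — per-iteration log-likelihood (non-decreasing).
    n_iter_ : int
    """

    def __init__(self, n_populations: int = 2, max_iter: int = 300,
                 tol: float = 1e-5, random_state: int | None = None):
        self.n_populations = n_populations
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _loglik(self, g, w, theta):
        const = np.zeros_like(g)
        const[g == 1.0] = _LOG_COMB[1.0]
        ll = const + g * np.log(theta) + (2.0 - g) * np.log1p(-theta)
        return float(np.sum(ll[w]))

    def fit(self, X, y=None):
        g = _as_dosage(X)
        n, m = g.shape
        K = self.n_populations
        if K < 1:
            raise ValueError("n_populations must be >= 1")
        if K > n:
            raise ValueError(f"n_populations={K} exceeds {n} accessions")
        w = ~np.isnan(g)
        if not w.any():
            raise ValueError("no observed genotypes")
        g0 = np.where(w, g, 0.0)

        obs_freq = np.zeros(m)
        counts = w.sum(axis=0)
        np.divide(g0.sum(axis=0), 2.0 * counts, out=obs_freq, where=counts > 0)
        obs_freq = np.clip(obs_freq, _EPS, 1 - _EPS)

        if K == 1:
            self.Q_ = np.ones((n, 1))
            self.P_ = obs_freq[None, :]
            theta = np.clip(self.Q_ @ self.P_, _EPS, 1 - _EPS)
            self.loglik_ = self._loglik(g0, w, theta)
            self.loglik_path_ = [self.loglik_]
            self.n_iter_ = 0
            return self

        rng = np.random.default_rng(self.random_state)
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(
            obs_freq[None, :] + rng.uniform(-0.1, 0.1, size=(K, m)), _EPS, 1 - _EPS
        )

        path: list[float] = []
        prev = -np.inf
        for it in range(1, self.max_iter + 1):
            theta = np.clip(Q @ P, _EPS, 1 - _EPS)
            ll = self._loglik(g0, w, theta)
            path.append(ll)
            if ll - prev < self.tol and it > 1:
                break
            prev = ll
            # responsibilities: alt copies -> (i,j,k) q_ik p_kj / theta_ij
            alt = Q[:, :, None] * P.T[None, :, :].transpose(0, 2, 1)  # n,K,m
            alt /= theta[:, None, :]
            ref = Q[:, :, None] * (1.0 - P).T[None, :, :].transpose(0, 2, 1)
            ref /= (1.0 - theta)[:, None, :]
            galt = (g0 * w)[:, None, :] * alt          # expected alt copies
            gref = ((2.0 - g0) * w)[:, None, :] * ref  # expected ref copies
            Q = (galt + gref).sum(axis=2)
            Q /= Q.sum(axis=1, keepdims=True)
            denom = (galt + gref).sum(axis=0)
            P = np.where(denom > 0, galt.sum(axis=0) / np.maximum(denom, _EPS),
                         obs_freq[None, :])
            P = np.clip(P, _EPS, 1 - _EPS)

        self.Q_, self.P_ = Q, P
        self.loglik_ = path[-1]
        self.loglik_path_ = path
        self.n_iter_ = len(path)
        return self

    def predict_dosage(self, X=None) -> np.ndarray:
        """Expected alternate dosage 2 * Q P for the fitted accessions."""
        return 2.0 * self.Q_ @ self.P_


def fit_admixture_em(matrix, K: int, seed: int | None = None,
                     max_iter: int = 300, tol: float = 1e-5) -> AdmixtureEM:
    """Fit the admixture model to a band-code matrix (or dosage array)."""
    return AdmixtureEM(
        n_populations=K, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(matrix)


def cv_error(matrix, K: int, n_folds: int = 5, seed: int | None = None,
             max_iter: int = 300, tol: float = 1e-5) -> float:
    """Mean held-out squared error of the K-population admixture model.

    Observed genotype cells are split into ``n_folds`` random folds; each
    fold in turn is masked, the model refitted on the rest, and the masked
    dosages compared with their predicted expectation 2 * Q P. Markers left
    with no training observations in a fold are skipped there (logged).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    g = _as_dosage(matrix)
    obs_i, obs_j = np.where(~np.isnan(g))
    if obs_i.size == 0:
        raise ValueError("no observed genotypes")
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, n_folds, size=obs_i.size)

    errors = []
    for fold in range(n_folds):
        mask = fold_of == fold
        if not mask.any():
            continue
        train = g.copy()
        train[obs_i[mask], obs_j[mask]] = np.nan
        empty = np.isnan(train).all(axis=0)
        if empty.any():
            logger.info("cv fold %d: %d markers with no training data skipped",
                        fold, int(empty.sum()))
        fit_seed = None if seed is None else int(
            np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31)
        )
        model = AdmixtureEM(n_populations=K, max_iter=max_iter, tol=tol,
                            random_state=fit_seed).fit(train)
        pred = model.predict_dosage()
        keep = mask & ~empty[obs_j]
        if not keep.any():
            continue
        ii, jj = obs_i[keep], obs_j[keep]
        errors.append(float(np.mean((pred[ii, jj] - g[ii, jj]) ** 2)))
    return float(np.mean(errors))


def evanno_delta_k(replicate_logliks: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno-style selection table from replicate log-likelihoods per K.

    Input maps each K (>= 3 consecutive values) to >= 2 replicate
    log-likelihoods. Returns a DataFrame with columns K, mean_lnP, sd_lnP and
    delta_k, where delta_k(K) = mean over replicates of
    |L(K+1) - 2 L(K) + L(K-1)| divided by sd of the L(K) replicates
    (replicates paired by run index when counts match, means otherwise).
    Delta K is NaN at the boundary Ks and +inf when the sd is zero.
    """
    ks = sorted(replicate_logliks)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    reps = {k: np.asarray(replicate_logliks[k], dtype=float) for k in ks}
    for k, v in reps.items():
        if v.size < 2:
            raise ValueError(f"need >= 2 replicates at K={k}")

    rows = []
    counts = {k: reps[k].size for k in ks}
    for k in ks:
        mean, sd = float(reps[k].mean()), float(reps[k].std(ddof=1))
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            if counts[k - 1] == counts[k] == counts[k + 1]:
                second = np.abs(reps[k + 1] - 2.0 * reps[k] + reps[k - 1])
                num = float(second.mean())
            else:
                num = abs(reps[k + 1].mean() - 2.0 * mean + reps[k - 1].mean())
            dk = num / sd if sd > 0 else float("inf")
            if not np.isfinite(dk):
                logger.warning("delta K undefined (zero sd) at K=%d", k)
        rows.append((k, mean, sd, dk))
    return pd.DataFrame(rows, columns=["K", "mean_lnP", "sd_lnP", "delta_k"])


def selection_table(matrix, k_values: range | list[int], n_replicates: int = 10,
                    n_folds: int = 5, seed: int | None = None,
                    max_iter: int = 300, tol: float = 1e-5) -> pd.DataFrame:
    """Replicate fits plus CV errors over a K range; one row per K with
    mean/sd log-likelihood, delta K and mean CV error."""
    ks = sorted(k_values)
    logliks: dict[int, list[float]] = {}
    cvs = {}
    for k in ks:
        runs = []
        for rep in range(n_replicates):
            fit_seed = None if seed is None else int(
                np.random.SeedSequence([seed, k, rep]).generate_state(1)[0] % (2**31)
            )
            runs.append(fit_admixture_em(matrix, k, seed=fit_seed,
                                         max_iter=max_iter, tol=tol).loglik_)
        logliks[k] = runs
        cv_seed = None if seed is None else int(
            np.random.SeedSequence([seed, 7919 + k]).generate_state(1)[0] % (2**31)
        )
        cvs[k] = cv_error(matrix, k, n_folds=n_folds, seed=cv_seed,
                          max_iter=max_iter, tol=tol)
    if len(ks) >= 3:
        table = evanno_delta_k(logliks)
    else:
        table = pd.DataFrame({
            "K": ks,
            "mean_lnP": [float(np.mean(logliks[k])) for k in ks],
            "sd_lnP": [float(np.std(logliks[k], ddof=1)) for k in ks],
            "delta_k": np.nan,
        })
    table["cv_error"] = [cvs[k] for k in table["K"]]
    return table


def select_k_by_cv(table: pd.DataFrame) -> int:
    """K with the minimum mean CV error (smallest K on ties)."""
    t = table.sort_values(["cv_error", "K"], kind="stable")
    return int(t.iloc[0]["K"])


def select_k_by_delta_k(table: pd.DataFrame) -> int:
    """Interior K with the maximum delta K (inf sorts above any finite value;
    smallest K on ties)."""
    t = table.dropna(subset=["delta_k"])
    if t.empty:
        raise ValueError("delta K undefined everywhere (need interior K)")
    t = t.sort_values(["delta_k", "K"], ascending=[False, True], kind="stable")
    return int(t.iloc[0]["K"])
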