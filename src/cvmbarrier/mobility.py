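"""Trapped/mobile classification of particles from log10 MSD.

Each sample's per-particle log10(MSD at tau = 1 s) histogram is
decomposed into two Gaussian components by expectation-maximization:
a low-MSD trapped fraction and a high-MSD mobile fraction.  When the
fitted mixture does not show two genuine peaks, a fixed cutoff of
log10(MSD) = -1.3 (MSD in um^2) separates trapped from mobile instead
— a threshold that cleanly separates the slow and fast populations for
a wide range of probe types in human mucus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["LogMSDMixture", "MixtureFit", "MobilityEstimate",
           "fit_mixture", "mobile_fraction", "sample_mobility_table",
           "LOG_MSD_CUTOFF"]

#: Fallback trapped/mobile cutoff, log10(MSD in um^2).
LOG_MSD_CUTOFF = -1.3


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture, components ordered by
    ascending mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    bimodal: bool
    insufficient: bool = False


@dataclass
class MobilityEstimate:
    sample_id: str
    probe: str
    mobile_fraction: float      # NaN when insufficient particles
    method: str                 # "mixture" | "cutoff" | "insufficient"
    cutoff: float
    n_particles: int
    mu_trapped: float = np.nan
    mu_mobile: float = np.nan
    w_mobile: float = np.nan


class LogMSDMixture(BaseEstimator):
    """Two-component Gaussian mixture on log10 MSD with a cutoff fallback.

    A scikit-learn style estimator.  ``fit(X)`` runs EM on a 1-D array
    of log10 MSD values with deterministic initialization (means at the
    25th/75th percentiles, equal weights, pooled SD), then decides
    whether the fit is genuinely bimodal; if not, the mobile fraction
    falls back to the proportion of values above ``cutoff``.

    Parameters
    ----------
    tol : EM stops when the log-likelihood improves by less than this.
    max_iter : EM iteration cap; non-convergence forces the cutoff path.
    var_floor : lower bound on component variance (log10 units squared),
        preventing singular collapse.
    cutoff : trapped/mobile threshold in log10(MSD um^2).
    sep_factor : components count as two peaks only when their means are
        at least ``sep_factor`` pooled SDs apart.
    min_weight : either component weight below this marks one peak.
    min_particles : fewer values than this marks the fit insufficient.
    fraction_mode : "weight" (mobile fraction = mixing weight of the
        higher-mean component) or "posterior" (fraction of particles
        whose posterior favours it).

    Attributes (after fit)
    ----------------------
    means_, sds_, weights_ : component parameters, mean-ascending.
    converged_, n_iter_, loglik_ : EM diagnostics.
    bimodal_ : whether the two-peak rule held.
    method_ : "mixture", "cutoff" or "insufficient".
    mobile_fraction_ : estimated mobile proportion.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 500,
                 var_floor: float = 1e-4, cutoff: float = LOG_MSD_CUTOFF,
                 sep_factor: float = 1.0, min_weight: float = 0.02,
                 min_particles: int = 10, fraction_mode: str = "weight"):
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.cutoff = cutoff
        self.sep_factor = sep_factor
        self.min_weight = min_weight
        self.min_particles = min_particles
        self.fraction_mode = fraction_mode

    # -- EM core -------------------------------------------------------
    def _em(self, x: np.ndarray):
        n = len(x)
        q25, q75 = np.percentile(x, [25, 75])
        mu = np.array([q25, q75], dtype=float)
        var = max(float(np.var(x)), self.var_floor) * np.ones(2)
        w = np.array([0.5, 0.5])
        loglik_prev = -np.inf
        converged = False
        loglik = -np.inf
        for it in range(1, self.max_iter + 1):
            # E step
            log_pdf = (-0.5 * np.log(2 * np.pi * var)[None, :]
                       - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :])
            log_w = np.log(np.clip(w, 1e-300, None))
            joint = log_pdf + log_w[None, :]
            m = joint.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
            loglik = float(lse.sum())
            resp = np.exp(joint - lse[:, None])
            # M step
            nk = resp.sum(axis=0)
            nk = np.clip(nk, 1e-12, None)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            var = np.clip(var, self.var_floor, None)
            if loglik - loglik_prev < self.tol and it > 1:
                converged = True
                break
            loglik_prev = loglik
        order = np.argsort(mu)
        return mu[order], np.sqrt(var[order]), w[order], converged, it, loglik

    def fit(self, X, y=None) -> "LogMSDMixture":
        x = np.asarray(X, dtype=float).ravel()
        if x.size and not np.all(np.isfinite(x)):
            raise ValueError("log MSD values must all be finite")
        self.n_samples_ = int(x.size)
        if x.size < self.min_particles:
            self.means_ = np.array([np.nan, np.nan])
            self.sds_ = np.array([np.nan, np.nan])
            self.weights_ = np.array([np.nan, np.nan])
            self.converged_, self.n_iter_, self.loglik_ = False, 0, np.nan
            self.bimodal_ = False
            self.method_ = "insufficient"
            self.mobile_fraction_ = np.nan
            return self

        mu, sd, w, converged, n_iter, loglik = self._em(x)
        self.means_, self.sds_, self.weights_ = mu, sd, w
        self.converged_, self.n_iter_, self.loglik_ = converged, n_iter, loglik
        pooled_sd = float(np.sqrt(w @ sd ** 2))
        self.bimodal_ = bool(
            converged
            and (mu[1] - mu[0]) >= self.sep_factor * pooled_sd
            and np.all(w >= self.min_weight))
        if self.bimodal_:
            self.method_ = "mixture"
            if self.fraction_mode == "posterior":
                self.mobile_fraction_ = float(
                    np.mean(self.predict(x) == 1))
            else:
                self.mobile_fraction_ = float(w[1])
        else:
            self.method_ = "cutoff"
            self.mobile_fraction_ = float(np.mean(x > self.cutoff))
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        mu, sd, w = self.means_, self.sds_, self.weights_
        log_pdf = (-0.5 * np.log(2 * np.pi * sd[None, :] ** 2)
                   - 0.5 * (x[:, None] - mu[None, :]) ** 2 / sd[None, :] ** 2)
        joint = log_pdf + np.log(np.clip(w, 1e-300, None))[None, :]
        m = joint.max(axis=1, keepdims=True)
        p = np.exp(joint - m)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """0 = trapped (lower mean), 1 = mobile (higher mean)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def to_fit(self) -> MixtureFit:
        return MixtureFit(means=self.means_, sds=self.sds_,
                          weights=self.weights_, converged=self.converged_,
                          n_iter=self.n_iter_, loglik=self.loglik_,
                          bimodal=self.bimodal_,
                          insufficient=self.method_ == "insufficient")


# -- thin functional wrappers ------------------------------------------

def fit_mixture(log_msds, seed: int | None = None, tol: float = 1e-8,
                max_iter: int = 500) -> MixtureFit:
    """EM fit of the two-component mixture (deterministic initialization;
    ``seed`` accepted for interface symmetry, unused by default)."""
    est = LogMSDMixture(tol=tol, max_iter=max_iter).fit(log_msds)
    return est.to_fit()


def mobile_fraction(log_msds, sample_id: str = "sample",
                    probe: str = "probe",
                    estimator: LogMSDMixture | None = None) -> MobilityEstimate:
    """Estimate the mobile particle fraction for one (sample, probe) group."""
    est = estimator if estimator is not None else LogMSDMixture()
    est = est.fit(log_msds)
    return MobilityEstimate(
        sample_id=sample_id, probe=probe,
        mobile_fraction=est.mobile_fraction_, method=est.method_,
        cutoff=est.cutoff, n_particles=est.n_samples_,
        mu_trapped=float(est.means_[0]), mu_mobile=float(est.means_[1]),
        w_mobile=float(est.weights_[1]))


def sample_mobility_table(msd_records: pd.DataFrame,
                          estimator: LogMSDMixture | None = None) -> pd.DataFrame:
    """Per-(sample, probe) mobility estimates from a per-particle table.

    ``msd_records`` uses the shared schema with columns ``sample_id``,
    ``probe`` and ``log10_msd`` (particles pooled across all videos of a
    sample).  Groups with too few particles are marked insufficient.
    """
    rows = []
    for (sid, probe), grp in msd_records.groupby(["sample_id", "probe"],
                                                 sort=True):
        e = mobile_fraction(grp["log10_msd"].to_numpy(), sid, probe,
                            estimator=estimator)
        rows.append(vars(e))
    cols = ["sample_id", "probe", "mobile_fraction", "method", "cutoff",
            "n_particles", "mu_trapped", "mu_mobile", "w_mobile"]
    return pd.DataFrame(rows, columns=cols)
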