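"""Vaginal community state type (CST) assignment and bookkeeping.

Samples are clustered on Bray-Curtis dissimilarities between taxon
relative-abundance vectors with partitioning around medoids (PAM,
k = 5), and clusters are named by their medoid's dominant taxon using
the conventional definitions: CST I = L. crispatus, II = L. gasseri,
III = L. iners, V = L. jensenii, IV = polymicrobial (no Lactobacillus
at >= 50% relative abundance).

Longitudinal rules: when a participant stops sampling before delivery,
the last sampled CST is carried forward to delivery; per-participant
particle-mobility summaries average over all of that participant's
samples within a CST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .simulate.microbiome import ARCHETYPE_TAXON, CST_LABELS

logger = logging.getLogger(__name__)

__all__ = ["CSTAssignment", "bray_curtis_matrix", "PAMKMedoids",
           "assign_cst_labels", "CSTClassifier", "carry_forward_cst",
           "participant_cst_mobility_average", "DOMINANCE_THRESHOLD"]

#: A cluster is a named Lactobacillus CST only if its medoid carries
#: that taxon at >= this relative abundance; otherwise it is CST IV.
DOMINANCE_THRESHOLD = 0.5

_TAXON_TO_CST = {taxon: cst for cst, taxon in ARCHETYPE_TAXON.items()}


@dataclass
class CSTAssignment:
    sample_id: str
    cst: str
    cluster_index: int
    medoid_sample_id: str
    dominant_taxon: str
    dominant_abundance: float


def _validate_table(table: pd.DataFrame) -> None:
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("relative abundances must be non-negative")
    sums = vals.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = table.index[np.argmax(np.abs(sums - 1.0))]
        raise ValueError(f"rows must sum to 1 (sample {bad!r} sums to "
                         f"{sums[np.argmax(np.abs(sums - 1.0))]:.6f})")


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between all samples.

    BC(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a + sum b); symmetric,
    zero diagonal, entries in [0, 1] for compositional rows.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 samples")
    _validate_table(table)
    dm = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dm, index=table.index, columns=table.index)


class PAMKMedoids(BaseEstimator, ClusterMixin):
    """Classic partitioning around medoids on a precomputed distance matrix.

    BUILD seeds medoids greedily (first the sample minimizing the total
    distance to all others, then whichever sample most reduces the
    objective), and SWAP exchanges (medoid, non-medoid) pairs while any
    swap lowers the total within-cluster distance to medoid.  BUILD is
    deterministic, so ``random_state`` is accepted for API symmetry but
    unused.

    Attributes after ``fit``: ``labels_`` (cluster index per sample),
    ``medoid_indices_`` (row indices of medoids), ``inertia_`` (total
    distance to assigned medoid).
    """

    def __init__(self, n_clusters: int = 5, max_swap_iter: int = 200,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.max_swap_iter = max_swap_iter
        self.random_state = random_state

    def fit(self, X, y=None) -> "PAMKMedoids":
        D = np.asarray(X, dtype=float)
        n = D.shape[0]
        if D.shape != (n, n):
            raise ValueError("X must be a square distance matrix")
        k = self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n_samples={n}")

        # BUILD
        medoids = [int(np.argmin(D.sum(axis=0)))]
        while len(medoids) < k:
            dmin = D[:, medoids].min(axis=1)
            # gain of adding candidate j: sum of reductions over points
            gains = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        medoids = sorted(medoids)
        self.build_inertia_ = float(D[:, medoids].min(axis=1).sum())

        # SWAP: apply best improving swap until local optimum
        for _ in range(self.max_swap_iter):
            dist_to_med = D[:, medoids]
            order = np.argsort(dist_to_med, axis=1)
            d1 = dist_to_med[np.arange(n), order[:, 0]]
            current = d1.sum()
            best_delta, best_swap = -1e-12, None
            med_set = set(medoids)
            for mi, m in enumerate(medoids):
                others = [j for j in range(len(medoids)) if j != mi]
                d_others = dist_to_med[:, others].min(axis=1) if others \
                    else np.full(n, np.inf)
                for h in range(n):
                    if h in med_set:
                        continue
                    new_d = np.minimum(d_others, D[:, h])
                    delta = new_d.sum() - current
                    if delta < best_delta:
                        best_delta, best_swap = delta, (mi, h)
            if best_swap is None:
                break
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)

        self.medoid_indices_ = np.asarray(medoids)
        self.labels_ = np.argmin(D[:, medoids], axis=1)
        # medoids always belong to their own cluster
        for ci, m in enumerate(medoids):
            self.labels_[m] = ci
        self.inertia_ = float(
            D[np.arange(n), self.medoid_indices_[self.labels_]].sum())
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def assign_cst_labels(labels: np.ndarray, medoid_indices: np.ndarray,
                      table: pd.DataFrame) -> list[CSTAssignment]:
    """Name PAM clusters by their medoid's dominant taxon.

    Clusters whose medoid has no single archetype Lactobacillus at
    >= 50% relative abundance are CST IV.  If two clusters map to the
    same Lactobacillus CST, the one with the higher medoid dominance
    keeps the name and the other falls through to IV with a warning.
    """
    n_clusters = len(medoid_indices)
    cluster_name: dict[int, str] = {}
    claims: dict[str, tuple[int, float]] = {}
    medoid_info = {}
    for ci in range(n_clusters):
        med = table.iloc[medoid_indices[ci]]
        dom_taxon = med.idxmax()
        dom_ab = float(med.max())
        medoid_info[ci] = (table.index[medoid_indices[ci]], dom_taxon, dom_ab)
        cst = _TAXON_TO_CST.get(dom_taxon)
        if cst is None or dom_ab < DOMINANCE_THRESHOLD:
            cluster_name[ci] = "IV"
            continue
        if cst in claims:
            prev_ci, prev_ab = claims[cst]
            if dom_ab > prev_ab:
                cluster_name[prev_ci] = "IV"
                claims[cst] = (ci, dom_ab)
                cluster_name[ci] = cst
            else:
                cluster_name[ci] = "IV"
            logger.warning(
                "two clusters map to CST %s; lower-dominance cluster "
                "reassigned to IV", cst)
        else:
            claims[cst] = (ci, dom_ab)
            cluster_name[ci] = cst

    out = []
    for i, sid in enumerate(table.index):
        ci = int(labels[i])
        med_sid, dom_taxon, dom_ab = medoid_info[ci]
        row = table.iloc[i]
        out.append(CSTAssignment(
            sample_id=str(sid), cst=cluster_name[ci], cluster_index=ci,
            medoid_sample_id=str(med_sid),
            dominant_taxon=str(row.idxmax()),
            dominant_abundance=float(row.max())))
    return out


class CSTClassifier(BaseEstimator):
    """Bray-Curtis + PAM community state typing as one estimator.

    ``fit(table)`` takes a samples-by-taxa relative-abundance DataFrame;
    ``assignments_`` holds one :class:`CSTAssignment` per sample and
    ``labels_`` the CST names in table order.
    """

    def __init__(self, n_clusters: int = 5, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "CSTClassifier":
        dm = bray_curtis_matrix(X)
        pam = PAMKMedoids(n_clusters=self.n_clusters,
                          random_state=self.random_state).fit(dm.to_numpy())
        self.pam_ = pam
        self.assignments_ = assign_cst_labels(
            pam.labels_, pam.medoid_indices_, X)
        self.labels_ = np.array([a.cst for a in self.assignments_])
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.assignments_]).rename(
            columns={"cluster_index": "cluster",
                     "medoid_sample_id": "medoid"})


def carry_forward_cst(timeline: pd.DataFrame,
                      delivery_week: float) -> pd.DataFrame:
    """Complete a participant's CST timeline through delivery.

    ``timeline`` holds one row per sampled visit with columns ``week``
    and ``cst`` (ordered or orderable by week).  Each visit's CST is
    assumed to persist until the next visit; after the last sampled
    visit (attrition included) the last observed CST persists to
    delivery.  Returns interval rows ``week_start``, ``week_end``,
    ``cst``, ``observed``.
    """
    if len(timeline) == 0:
        raise ValueError("participant has no CST assignments")
    tl = timeline.sort_values("week").reset_index(drop=True)
    rows = []
    for i in range(len(tl)):
        start = float(tl.loc[i, "week"])
        if i + 1 < len(tl):
            end, observed = float(tl.loc[i + 1, "week"]), True
        else:
            end = max(float(delivery_week), start)
            observed = end == start  # carried forward when it extends
        rows.append(dict(week_start=start, week_end=end,
                         cst=tl.loc[i, "cst"], observed=observed))
    return pd.DataFrame(rows)


def participant_cst_mobility_average(mobility: pd.DataFrame,
                                     assignments: pd.DataFrame,
                                     ) -> pd.DataFrame:
    """Average mobile fraction per participant per CST per probe.

    ``mobility`` has columns ``sample_id``, ``probe``,
    ``mobile_fraction``; ``assignments`` maps ``sample_id`` to ``cst``
    and ``participant_id``.  Samples without an assignment are logged
    and dropped; the mean is unweighted over samples.
    """
    merged = mobility.merge(
        assignments[["sample_id", "participant_id", "cst"]],
        on="sample_id", how="left")
    orphans = merged["cst"].isna()
    if orphans.any():
        logger.warning("dropping %d mobility rows without a CST assignment",
                       int(orphans.sum()))
        merged = merged[~orphans]
    if merged.empty:
        return pd.DataFrame(columns=["participant_id", "cst", "probe",
                                     "mobile_fraction", "n_samples"])
    out = (merged.groupby(["participant_id", "cst", "probe"], sort=True)
           .agg(mobile_fraction=("mobile_fraction", "mean"),
                n_samples=("mobile_fraction", "size"))
           .reset_index())
    return out
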