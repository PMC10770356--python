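"""Trend screening and clustering of expression profiles.

Features are screened by classical one-way ANOVA across the four
groups, partitioned by k-means for the overview heatmap, filtered on
the standard deviation of their log2 relative values, and soft-
clustered by fuzzy c-means on row-standardised profiles.  A cluster is
*treatment-reversed* when its centroid's group means move the same way
in CT/C and MT/M but the opposite way in M/C; features belonging to
such clusters are the pipeline's trend selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .matrix import GROUPS, ConfigurationError, IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-feature one-way ANOVA F statistic, p-value and pass flag."""

    table: pd.DataFrame  # columns: F, p, passed
    alpha: float

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]


@dataclass
class SoftClustering:
    """Fuzzy c-means result on standardised log2 profiles.

    ``membership`` rows sum to 1; ``hard`` is the argmax cluster per
    feature (ties broken toward the lower cluster index); ``centroids``
    live on the standardised scale (one column per sample).
    """

    centroids: pd.DataFrame  # clusters x samples
    membership: pd.DataFrame  # features x clusters
    fuzzifier: float
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)
    data: pd.DataFrame | None = None  # standardised profiles the fit saw

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def hard(self) -> pd.Series:
        arr = self.membership.to_numpy()
        return pd.Series(arr.argmax(axis=1), index=self.membership.index)


@dataclass
class TrendSelection:
    """Treatment-reversal call per cluster plus the selected features.

    ``cluster_table`` has one row per cluster: group-mean centroid over
    (C, CT, M, MT), the signs of CT-C, MT-M and M-C, the selected flag
    and a direction label (up-in-M-reversed / down-in-M-reversed).
    """

    cluster_table: pd.DataFrame
    selected_clusters: list[int]
    selected_features: list[str]
    membership_min: float
    epsilon: float


def anova_screen(rel: IntensityMatrix, alpha: float = 0.05) -> ScreenResult:
    """One-way ANOVA on log2 relative values across the four groups.

    Features with p < alpha pass the screen.  Degenerate rows (zero
    between- and within-group variance) get p = 1: constant data carry
    no evidence of group differences.
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    logv = rel.log2()
    group_arrays = [logv[rel.samples_in_group(g)].to_numpy() for g in GROUPS]
    if any(a.shape[1] < 2 for a in group_arrays):
        raise ConfigurationError("ANOVA needs >= 2 replicates per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*group_arrays, axis=1)
    degenerate = ~np.isfinite(F)
    if degenerate.any():
        logger.warning("%d features with degenerate ANOVA set to p=1", degenerate.sum())
        F = np.where(degenerate, 0.0, F)
        p = np.where(degenerate, 1.0, p)
    table = pd.DataFrame({"F": F, "p": p}, index=logv.index)
    # alpha == 1 is the everything-passes boundary; p can equal 1 exactly
    table["passed"] = (table["p"] < alpha) | (alpha >= 1)
    return ScreenResult(table=table, alpha=alpha)


def _standardize_rows(logv: pd.DataFrame) -> pd.DataFrame:
    """Row-standardise (mean 0, sd 1, n-1 denominator); drop zero-variance rows."""
    mean = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance rows before clustering", (~keep).sum())
    z = logv.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return z


def kmeans_clusters(
    rel: IntensityMatrix, k: int = 6, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """Hard k-means partition of row-standardised log2 profiles.

    k-means++ initialisation with ``n_init`` restarts keeps the best
    inertia; labels are relabelled by descending cluster size so the
    output is deterministic given the seed.
    """
    logv = rel.log2().dropna(axis=0, how="any")
    z = _standardize_rows(logv)
    if k < 1 or k > z.shape[0]:
        raise ConfigurationError(f"k={k} out of range for {z.shape[0]} features")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    # stable relabeling: cluster 0 = largest
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[l] for l in labels], index=z.index, name="cluster")


def log2_sd_filter(rel: IntensityMatrix, sd_min: float = 0.2) -> IntensityMatrix:
    """Keep features whose log2 relative values have sd > ``sd_min``.

    The standard deviation uses all samples with the n-1 denominator.
    Rows with nonpositive values are excluded (with a warning) since
    they have no log2 representation.
    """
    if sd_min < 0:
        raise ConfigurationError("sd_min must be nonnegative")
    logv = rel.log2()
    incomplete = logv.isna().any(axis=1) & rel.values.notna().all(axis=1)
    if incomplete.any():
        logger.warning(
            "%d features with nonpositive values excluded from SD filter",
            int(incomplete.sum()),
        )
    sd = logv.std(axis=1, ddof=1)
    keep = rel.values.index[(sd > sd_min).fillna(False)]
    return rel.subset(keep)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix from squared distances (features x clusters).

    u_ij is proportional to (1/d_ij^2)^(1/(m-1)); a feature coinciding
    with a centroid gets membership 1 there (limit rule).
    """
    exp = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore"):
        inv = (1.0 / d2) ** exp
    u = np.zeros_like(d2)
    coincident = np.isinf(inv).any(axis=1)
    if coincident.any():
        hits = np.isinf(inv[coincident])
        u[coincident] = hits / hits.sum(axis=1, keepdims=True)
    rest = ~coincident
    u[rest] = inv[rest] / inv[rest].sum(axis=1, keepdims=True)
    return u


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++ style) centroid seeding.

    Spreads initial centroids across separated blobs, avoiding the
    degenerate start where several centroids coincide on duplicate rows.
    """
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        total = d2.sum()
        if total == 0:  # all points coincide with chosen centroids
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centroids, dtype=float)


def fuzzy_cmeans(
    filtered: IntensityMatrix,
    c: int = 5,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    *,
    standardize: bool = True,
) -> SoftClustering:
    """Fuzzy c-means on row-standardised log2 relative profiles.

    Standard alternating optimisation: memberships
    ``u_ij ∝ (1/d_ij²)^(1/(m-1))`` and centroids as ``u^m``-weighted
    means, iterated until the largest centroid shift falls below
    ``tol`` or ``max_iter`` is reached.  The objective
    ``sum_ij u_ij^m d_ij²`` is non-increasing across iterations.
    Initial centroids are ``c`` distinct rows drawn with the seed.
    """
    if m <= 1:
        raise ConfigurationError("fuzzifier m must be > 1")
    logv = filtered.log2().dropna(axis=0, how="any")
    z = _standardize_rows(logv) if standardize else logv
    X = z.to_numpy(dtype=float)
    n = X.shape[0]
    if c < 1 or c > n:
        raise ConfigurationError(f"c={c} out of range for {n} features")

    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(X, c, rng)
    objective_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(d2, m)
        objective_path.append(float((u**m * d2).sum()))
        um = u**m
        denom = um.sum(axis=0)[:, None]
        # a cluster losing all membership keeps its previous centroid
        new_centroids = np.where(
            denom > 0, (um.T @ X) / np.where(denom > 0, denom, 1.0), centroids
        )
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _fcm_memberships(d2, m)
    return SoftClustering(
        centroids=pd.DataFrame(centroids, columns=z.columns),
        membership=pd.DataFrame(u, index=z.index, columns=range(c)),
        fuzzifier=m,
        converged=converged,
        n_iter=it,
        objective_path=objective_path,
        data=z,
    )


def select_trend_clusters(
    sc: SoftClustering,
    groups: pd.Series,
    *,
    epsilon: float = 0.05,
    membership_min: float = 0.5,
) -> TrendSelection:
    """Select clusters whose mean trend is reversed by treatment.

    For each centroid the per-group means over (C, CT, M, MT) are
    reduced to three differences: CT-C, MT-M and M-C.  A cluster is
    selected iff sign(CT-C) = sign(MT-M) = -sign(M-C) with every
    |difference| > ``epsilon`` (standardised centroid scale).  A
    feature is selected when its argmax cluster is selected and its
    total membership mass across selected clusters is at least
    ``membership_min`` (summing over selected clusters makes the call
    robust to near-duplicate centroids splitting one trend).
    """
    groups = pd.Series(groups)
    missing = [g for g in GROUPS if not (groups == g).any()]
    if missing:
        raise ConfigurationError(f"centroids do not cover groups: {missing}")
    rows = []
    selected = []
    for ci in range(sc.n_clusters):
        centroid = sc.centroids.iloc[ci]
        gm = {g: centroid[groups.index[groups == g]].mean() for g in GROUPS}
        d_ct = gm["CT"] - gm["C"]
        d_mt = gm["MT"] - gm["M"]
        d_m = gm["M"] - gm["C"]
        big = all(abs(d) > epsilon for d in (d_ct, d_mt, d_m))
        sel = big and np.sign(d_ct) == np.sign(d_mt) == -np.sign(d_m)
        label = ""
        if sel:
            label = "up-in-M-reversed" if d_m > 0 else "down-in-M-reversed"
            selected.append(ci)
        else:
            logger.debug(
                "cluster %d not selected (CT-C=%.3f, MT-M=%.3f, M-C=%.3f)",
                ci, d_ct, d_mt, d_m,
            )
        rows.append(
            {
                "cluster": ci,
                **{f"mean_{g}": gm[g] for g in GROUPS},
                "d_CT_C": d_ct,
                "d_MT_M": d_mt,
                "d_M_C": d_m,
                "selected": sel,
                "direction": label,
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")

    feats: list[str] = []
    if selected:
        hard = sc.hard
        mass = sc.membership[selected].sum(axis=1)
        keep = hard.isin(selected) & (mass >= membership_min)
        feats = list(sc.membership.index[keep])
    return TrendSelection(
        cluster_table=table,
        selected_clusters=selected,
        selected_features=feats,
        membership_min=membership_min,
        epsilon=epsilon,
    )
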