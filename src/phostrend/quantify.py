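"""Relative quantification, phosphosite correction and QC summaries.

Raw LFQ intensities I are row-centralised into relative quantitative
values R = I / mean(I) (mean over the feature's non-missing samples),
so every feature's row mean is 1 and samples become comparable without
absolute calibration.  Phosphosite relative values are divided by the
parent protein's relative value per sample to remove the protein
abundance component from the modification signal.  QC covers per-group
relative standard deviation (replicate repeatability) and a sample PCA
on log2 relative values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import GROUPS, ConfigurationError, IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Replicate-quality and sample-structure summaries.

    ``rsd``: per-feature per-group relative standard deviation
    (sd / mean of relative values, n-1 denominator).
    ``rsd_summary``: per-group median RSD and a pass flag
    (median < ``rsd_threshold``).
    ``pca_coords`` / ``explained_variance``: sample coordinates and
    explained-variance fractions when PCA was run.
    """

    rsd: pd.DataFrame | None = None
    rsd_summary: pd.DataFrame | None = None
    rsd_threshold: float = 0.2
    pca_coords: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def relative_quantify(raw: IntensityMatrix) -> IntensityMatrix:
    """Row-centralise intensities: R_ij = I_ij / mean_i(I_ij).

    Means are taken over non-missing entries, so every returned row has
    mean exactly 1.  Features whose mean is zero or undefined (all-zero
    or all-missing rows) are excluded with a logged warning.
    """
    vals = raw.values.astype(float)
    if (vals < 0).any().any():
        raise ConfigurationError("intensities must be nonnegative")
    row_mean = vals.mean(axis=1, skipna=True)
    bad = row_mean.isna() | (row_mean == 0)
    if bad.any():
        logger.warning(
            "excluding %d features with zero/undefined row mean: %s%s",
            int(bad.sum()),
            list(vals.index[bad][:5]),
            "..." if bad.sum() > 5 else "",
        )
    vals = vals.loc[~bad]
    rel = vals.div(row_mean.loc[~bad], axis=0)
    return raw.with_values(rel)


def completeness_filter(mat: IntensityMatrix, min_fraction: float = 0.5) -> IntensityMatrix:
    """Keep features quantified (non-missing) in >= ``min_fraction`` of samples.

    This is the 'comparable feature' criterion applied before any
    statistics; with complete data it is a no-op.
    """
    frac = mat.values.notna().mean(axis=1)
    return mat.subset(mat.values.index[frac >= min_fraction])


def correct_phospho_by_protein(
    site_rel: IntensityMatrix, prot_rel: IntensityMatrix
) -> IntensityMatrix:
    """Divide site relative values by the parent protein's relative values.

    Removes the protein-abundance component from site-level signal.
    Sites whose parent protein is not quantified pass through
    uncorrected and are flagged in ``sites['corrected']``; cells where
    the protein relative value is 0 become missing.
    """
    if site_rel.sites is None:
        raise ConfigurationError("site matrix carries no site table")
    if list(site_rel.values.columns) != list(prot_rel.values.columns):
        raise ConfigurationError("site and protein matrices must share samples")
    out = site_rel.values.copy()
    corrected = pd.Series(False, index=out.index)
    prot_index = set(prot_rel.values.index)
    parents = site_rel.sites["protein_id"]
    have_parent = parents.isin(prot_index)
    if (~have_parent).any():
        logger.warning(
            "%d sites have no quantified parent protein; left uncorrected",
            int((~have_parent).sum()),
        )
    idx = out.index[have_parent.loc[out.index]]
    denom = prot_rel.values.loc[parents.loc[idx]].to_numpy(dtype=float)
    zero = denom == 0
    if zero.any():
        logger.warning("protein relative value 0 in %d cells; set missing", zero.sum())
        denom = np.where(zero, np.nan, denom)
    out.loc[idx] = out.loc[idx].to_numpy(dtype=float) / denom
    corrected.loc[idx] = True
    res = site_rel.with_values(out)
    res.sites = res.sites.assign(corrected=corrected)
    return res


def compute_rsd(rel: IntensityMatrix, threshold: float = 0.2) -> QCReport:
    """Per-group relative standard deviation of each feature.

    RSD = sd / mean within a group (sample sd, n-1 denominator).  The
    report summarises each group by its median RSD with a pass flag
    (median < ``threshold``).  Cells with group mean 0 are excluded.
    """
    rows = {}
    for g in GROUPS:
        gv = rel.group_values(g)
        if gv.shape[1] < 2:
            raise ConfigurationError(f"group {g} has <2 replicates")
        mean = gv.mean(axis=1)
        sd = gv.std(axis=1, ddof=1)
        rsd = sd / mean.where(mean != 0)
        rows[g] = rsd
    rsd = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "median_rsd": rsd.median(),
            "pass": rsd.median() < threshold,
        }
    )
    return QCReport(rsd=rsd, rsd_summary=summary, rsd_threshold=threshold)


def pca_samples(rel: IntensityMatrix, n_components: int = 2) -> QCReport:
    """Sample PCA on log2 relative values with feature centering.

    Features are centred (no scaling) and samples decomposed by SVD;
    the sign convention makes each component's largest-magnitude
    loading positive, so results are deterministic.  Features with any
    missing or nonpositive value are dropped from the decomposition.
    """
    if rel.n_samples < 2:
        raise ConfigurationError("PCA needs >= 2 samples")
    logv = rel.log2().dropna(axis=0, how="any")
    max_comp = min(rel.n_samples, logv.shape[0])
    if n_components > max_comp:
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(samples, features)={max_comp}"
        )
    X = logv.T.to_numpy()  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coords = pd.DataFrame(
        coords,
        index=logv.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return QCReport(
        pca_coords=coords,
        explained_variance=pca.explained_variance_ratio_,
    )


def residue_class_stats(sites: pd.DataFrame) -> pd.DataFrame:
    """Count phosphosites per residue class (S/T/Y) with percentages.

    Returns a frame indexed S, T, Y with columns ``count`` and
    ``percent`` (percent of all sites, rounded to one decimal).
    """
    counts = sites["residue"].value_counts().reindex(["S", "T", "Y"], fill_value=0)
    total = int(counts.sum())
    pct = (100.0 * counts / total).round(1) if total else counts.astype(float)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})
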