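"""Per-contrast differential calls, interaction subnetworks and hub concordance.

A contrast compares two groups by fold change of relative-value means
(FC = mean_A / mean_B on the untransformed relative scale) and a
two-sample t-test on log2 relative values; features with FC > 1.5 and
p < 0.05 are called up, FC < 1/1.5 and p < 0.05 down.  Differential
features are intersected with a confidence-filtered interaction
network (STRING-style combined scores, threshold 0.7); nodes whose
degree strictly exceeds the subnetwork's average degree are hubs.
Proteins that are hubs in all three contrasts form the concordance
table, where a *reversal candidate* is a row whose model-contrast
(M/C) direction is opposed by the treatment contrast (MT/M) and
matched by the control-treatment contrast (CT/C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ConfigurationError, IntensityMatrix

logger = logging.getLogger(__name__)

CONTRAST_LABELS = ("CT/C", "M/C", "MT/M")


@dataclass
class ContrastResult:
    """Fold change, t-test p-value and call for one group pair.

    ``table`` columns: FC (mean_A / mean_B of relative values), p
    (two-sided t on log2 values) and call in {up, down, unchanged}.
    """

    label: str
    table: pd.DataFrame
    fc_up: float
    alpha: float

    def call_of(self, feature: str) -> str | None:
        if feature not in self.table.index:
            return None
        return str(self.table.at[feature, "call"])

    @property
    def deps(self) -> set[str]:
        """Features called up or down."""
        return set(self.table.index[self.table["call"] != "unchanged"])


def contrast(
    rel: IntensityMatrix,
    group_a: str,
    group_b: str,
    fc_up: float = 1.5,
    alpha: float = 0.05,
    *,
    equal_var: bool = True,
) -> ContrastResult:
    """Differential test of group_a vs group_b (A over B).

    FC is the ratio of group means of untransformed relative values;
    the p-value comes from a two-sided two-sample t-test (pooled
    variance by default, Welch with ``equal_var=False``) on log2
    values.  Features with zero variance in both groups and equal
    means get p = 1; features with a zero denominator mean have no
    fold change and are excluded with a warning.
    """
    if fc_up <= 1:
        raise ConfigurationError("fc_up must be > 1")
    A = rel.group_values(group_a)
    B = rel.group_values(group_b)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ConfigurationError("both groups need >= 2 replicates")

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    bad = (mean_b == 0) | mean_b.isna() | mean_a.isna()
    if bad.any():
        logger.warning(
            "%d features with undefined fold change excluded from %s/%s",
            int(bad.sum()), group_a, group_b,
        )
    fc = (mean_a / mean_b)[~bad]

    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log2(A.where(A > 0)).loc[fc.index].to_numpy()
        lb = np.log2(B.where(B > 0)).loc[fc.index].to_numpy()
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
    # zero variance in both groups: nan from scipy; equal means carry no evidence
    p = np.where(np.isfinite(p), p, 1.0)

    call = np.where(
        (fc > fc_up) & (p < alpha),
        "up",
        np.where((fc < 1 / fc_up) & (p < alpha), "down", "unchanged"),
    )
    table = pd.DataFrame({"FC": fc, "p": p, "call": call}, index=fc.index)
    return ContrastResult(
        label=f"{group_a}/{group_b}", table=table, fc_up=fc_up, alpha=alpha
    )


def build_subnetwork(
    edges: pd.DataFrame,
    nodes: set[str],
    score_min: float = 0.7,
) -> nx.Graph:
    """Induced interaction subgraph on a differential node set.

    ``edges`` needs columns node_a, node_b, score.  Scores given as
    0-999 integers (STRING export dialect) are rescaled by /1000 with a
    log message; edges are kept iff score > ``score_min`` after
    rescaling.  Isolated differential nodes are retained with degree 0;
    self-loops are dropped.
    """
    required = {"node_a", "node_b", "score"}
    if not required.issubset(edges.columns):
        raise ConfigurationError(f"edge table needs columns {sorted(required)}")
    scores = pd.to_numeric(edges["score"], errors="raise").astype(float)
    if (scores < 0).any() or (scores > 999).any():
        raise ConfigurationError("scores must be in [0, 1] or 0-999 integers")
    if (scores > 1).any():
        logger.info("integer 0-999 score column detected; rescaling by /1000")
        scores = scores / 1000.0

    G = nx.Graph()
    G.add_nodes_from(sorted(nodes))
    keep = scores > score_min
    for (u, v), s in zip(
        edges.loc[keep, ["node_a", "node_b"]].itertuples(index=False),
        scores[keep],
    ):
        if u == v:
            continue
        if u in nodes and v in nodes:
            G.add_edge(u, v, score=float(s))
    return G


def hub_nodes(
    net: nx.Graph, *, include_isolates: bool = True
) -> tuple[float, set[str]]:
    """Average degree and the above-average-degree hub set.

    Average degree is the mean over all nodes (isolates included by
    default); hubs are nodes whose degree strictly exceeds it.
    """
    nodes = list(net.nodes)
    if not include_isolates:
        nodes = [v for v in nodes if net.degree(v) > 0]
    if not nodes:
        raise ConfigurationError("network has no (eligible) nodes")
    degrees = {v: net.degree(v) for v in nodes}
    avg = float(np.mean(list(degrees.values())))
    hubs = {v for v, d in degrees.items() if d > avg}
    return avg, hubs


def is_reversal_pattern(ct_c: str, m_c: str, mt_m: str) -> bool:
    """Treatment-reversal rule on a direction triple.

    The model change (M/C) must be called and opposed by the treatment
    contrast (MT/M), with the control-treatment contrast (CT/C)
    matching MT/M.
    """
    return (
        m_c in ("up", "down")
        and mt_m in ("up", "down")
        and m_c != mt_m
        and mt_m == ct_c
    )


def concordance_table(
    protein_contrasts: dict[str, ContrastResult],
    hubs_per_contrast: dict[str, set[str]],
    site_contrasts: dict[str, ContrastResult] | None = None,
    site_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Three-contrast concordance of overlapping hub proteins.

    Rows cover proteins that are hubs in *all three* contrast
    subnetworks; a protein with differential sites contributes one row
    per site (sites inherit the protein's hub status through
    ``site_map``), a protein without sites one protein-only row.
    Columns give per-contrast site-level and protein-level directions
    and the reversal-candidate flag, judged on site directions where
    available, protein directions otherwise.
    """
    missing = [l for l in CONTRAST_LABELS if l not in protein_contrasts]
    if missing:
        raise ConfigurationError(f"missing contrasts: {missing}")
    missing = [l for l in CONTRAST_LABELS if l not in hubs_per_contrast]
    if missing:
        raise ConfigurationError(f"missing hub sets for contrasts: {missing}")

    overlapping = sorted(
        set.intersection(*(hubs_per_contrast[l] for l in CONTRAST_LABELS))
    )
    sites_by_protein: dict[str, list[str]] = {}
    if site_map is not None:
        for site, prot in site_map.items():
            sites_by_protein.setdefault(prot, []).append(site)

    rows = []
    for prot in overlapping:
        prot_dirs = {
            l: protein_contrasts[l].call_of(prot) or "unknown"
            for l in CONTRAST_LABELS
        }
        site_ids = sites_by_protein.get(prot, []) if site_contrasts else []
        # only sites actually measured in the site-level contrasts
        site_ids = [
            s
            for s in site_ids
            if any(site_contrasts[l].call_of(s) is not None for l in CONTRAST_LABELS)
        ]
        if site_ids:
            for s in sorted(site_ids):
                site_dirs = {
                    l: site_contrasts[l].call_of(s) or "unknown"
                    for l in CONTRAST_LABELS
                }
                rows.append(_concordance_row(prot, s, site_dirs, prot_dirs))
        else:
            rows.append(_concordance_row(prot, "", None, prot_dirs))
    cols = (
        ["protein", "site"]
        + [f"site_{l}" for l in CONTRAST_LABELS]
        + [f"protein_{l}" for l in CONTRAST_LABELS]
        + ["reversal_candidate"]
    )
    return pd.DataFrame(rows, columns=cols)


def _concordance_row(prot, site, site_dirs, prot_dirs) -> dict:
    judged = site_dirs if site_dirs is not None else prot_dirs
    return {
        "protein": prot,
        "site": site,
        **{f"site_{l}": (site_dirs or {}).get(l, "") for l in CONTRAST_LABELS},
        **{f"protein_{l}": prot_dirs[l] for l in CONTRAST_LABELS},
        "reversal_candidate": is_reversal_pattern(
            judged["CT/C"], judged["M/C"], judged["MT/M"]
        ),
    }
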