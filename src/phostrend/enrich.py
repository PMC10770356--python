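"""Annotation-term over-representation analysis.

Terms (GO-style categories, pathways) are tested one-sidedly for
over-representation in a selected feature set against a universe of
quantified features, using the hypergeometric upper tail — equivalent
to a one-sided Fisher exact test on the 2x2 overlap table.  Raw
p < alpha is the primary criterion; Benjamini-Hochberg adjusted values
are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class TermSet:
    """A named annotation term with its member feature ids."""

    term_id: str
    name: str
    members: set[str]
    category: str = ""


@dataclass
class EnrichmentResult:
    """Per-term enrichment table, sorted by ascending p.

    Columns: term, name, category, k (overlap), n (cluster size),
    K (term size in universe), N (universe size), fold
    ((k/n)/(K/N)), p (hypergeometric upper tail), p_adj
    (Benjamini-Hochberg), significant (p < alpha).
    """

    table: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes K, draws n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich(
    cluster: set[str],
    terms: list[TermSet],
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Test each term for over-representation in ``cluster``.

    Terms are restricted to the universe before testing; the p-value is
    the hypergeometric upper tail P(X >= k) with X ~
    Hypergeom(N=|universe|, K=|term|, n=|cluster|).
    """
    cluster = set(cluster)
    universe = set(universe)
    if not cluster or not universe:
        raise ConfigurationError("cluster and universe must be nonempty")
    extra = cluster - universe
    if extra:
        raise ConfigurationError(
            f"{len(extra)} cluster features outside the universe (e.g. {next(iter(extra))!r})"
        )
    N, n = len(universe), len(cluster)
    rows = []
    for t in terms:
        members = t.members & universe
        K = len(members)
        k = len(members & cluster)
        fold = (k / n) / (K / N) if K else np.nan
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append(
            {
                "term": t.term_id,
                "name": t.name,
                "category": t.category,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = _benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["p"] < alpha
        table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        table["p_adj"] = []
        table["significant"] = []
    return EnrichmentResult(table=table, alpha=alpha)


def read_gmt(path: str | Path) -> list[TermSet]:
    """Parse a GMT file: term, description, members (tab-separated).

    Duplicate members within a line are deduplicated with a warning;
    a line with fewer than three fields is a parse error naming the
    line number.  Empty files yield an empty list.
    """
    out: list[TermSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, desc, *members = fields
            uniq = set(members)
            if len(uniq) < len(members):
                logger.warning(
                    "%s: line %d: %d duplicate members in %s deduplicated",
                    path, lineno, len(members) - len(uniq), term_id,
                )
            out.append(TermSet(term_id=term_id, name=desc, members=uniq))
    return out


def write_gmt(terms: list[TermSet], path: str | Path) -> None:
    """Write term sets in GMT form (members sorted for determinism)."""
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")
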