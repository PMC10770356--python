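"""Core data container: a feature-by-sample intensity matrix with group labels.

The matrix holds either raw LFQ intensities or relative quantitative
values at protein or phosphosite level.  Samples belong to exactly one
of the four design groups C, CT, M, MT.  Phosphosite-level matrices
additionally carry a site table linking each row to its parent protein,
phosphorylated residue (S/T/Y) and sequence position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical group order: control, treated control, model, treated model.
GROUPS: tuple[str, ...] = ("C", "CT", "M", "MT")

#: The three contrasts reported by the pipeline, as (numerator, denominator).
CONTRASTS: tuple[tuple[str, str], ...] = (("CT", "C"), ("M", "C"), ("MT", "M"))

VALID_RESIDUES = frozenset({"S", "T", "Y"})


class PhosTrendError(Exception):
    """Base class for package errors."""


class ConfigurationError(PhosTrendError, ValueError):
    """Invalid configuration or arguments."""


class ConsistencyError(PhosTrendError, ValueError):
    """Internal linkage violated (e.g. a site referencing an absent protein)."""


@dataclass
class IntensityMatrix:
    """Feature x sample matrix with sample group labels.

    Parameters
    ----------
    values
        DataFrame of nonnegative intensities (or positive relative
        values), indexed by feature id, one column per sample.  NaN
        marks a missing measurement.
    groups
        Series mapping each sample (column) to its group label, one of
        ``GROUPS``.
    level
        ``"protein"`` or ``"phosphosite"``.
    sites
        For phosphosite level, a DataFrame indexed by site id with
        columns ``protein_id``, ``residue`` (S/T/Y) and ``position``.
    """

    values: pd.DataFrame
    groups: pd.Series
    level: str = "protein"
    sites: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.level not in ("protein", "phosphosite"):
            raise ConfigurationError(f"unknown level {self.level!r}")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ConfigurationError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        if self.level == "phosphosite" and self.sites is not None:
            site_ids = set(self.sites.index)
            orphan = [f for f in self.values.index if f not in site_ids]
            if orphan:
                raise ConsistencyError(
                    f"{len(orphan)} phosphosite rows have no site record "
                    f"(first: {orphan[0]!r})"
                )
            bad_res = set(self.sites["residue"]) - VALID_RESIDUES
            if bad_res:
                raise ConsistencyError(f"invalid residues: {sorted(bad_res)}")
            if (self.sites["position"] < 1).any():
                raise ConsistencyError("site positions must be >= 1")

    # -- convenience accessors -------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in column order."""
        if group not in GROUPS:
            raise ConfigurationError(f"unknown group {group!r}")
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix restricted to the samples of one group."""
        return self.values[self.samples_in_group(group)]

    def group_means(self) -> pd.DataFrame:
        """Per-feature mean over non-missing values, one column per group."""
        return pd.DataFrame(
            {g: self.group_values(g).mean(axis=1) for g in GROUPS}
        )

    def subset(self, features) -> "IntensityMatrix":
        """Restrict to the given feature ids (order preserved)."""
        features = list(features)
        sites = None
        if self.sites is not None:
            sites = self.sites.loc[[f for f in features if f in self.sites.index]]
        return replace(self, values=self.values.loc[features], sites=sites)

    def with_values(self, values: pd.DataFrame) -> "IntensityMatrix":
        """Same metadata, new value matrix (columns must be unchanged)."""
        if list(values.columns) != list(self.values.columns):
            raise ConfigurationError("sample columns must match")
        sites = None
        if self.sites is not None:
            sites = self.sites.loc[[f for f in values.index if f in self.sites.index]]
        return replace(self, values=values, sites=sites)

    def log2(self) -> pd.DataFrame:
        """log2 of the values; nonpositive entries become NaN."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(self.values.where(self.values > 0))
        return out
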