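"""Synthetic LFQ data with planted ground truth.

The generator emulates a four-group (C, CT, M, MT) label-free
proteomics experiment.  Each protein draws a log2 baseline abundance;
a configurable fraction of proteins additionally carries one of a set
of *trend templates* — a 4-vector of per-group log2 offsets.  The two
default templates describe the treatment-reversal shapes of interest:

* ``(0, -0.8, +1, 0)`` — up in the disease model, pulled back down by
  treatment, with a smaller same-direction shift in treated controls;
* ``(0, +0.8, -1, 0)`` — the mirrored down-in-model shape.

Phosphosites are generated on top of the proteome: each site row is its
parent protein's intensity times ``2**(site effect + noise)``, so that
dividing site by protein relative values recovers the site-level effect
exactly in the noise-free limit.  Annotation terms (one enriched per
template) and a STRING-like scored edge list with a densely wired hub
module complete the inputs needed by the downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CONTRASTS, GROUPS, ConfigurationError, ConsistencyError, IntensityMatrix

DEFAULT_TEMPLATES: tuple[tuple[float, float, float, float], ...] = (
    (0.0, -0.8, 1.0, 0.0),
    (0.0, 0.8, -1.0, 0.0),
)

TERM_CATEGORIES = ("biological process", "molecular function", "pathway")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic four-group experiment.

    Defaults describe the reference study conditions: 200 proteins,
    400 phosphosites, 4 replicates per group, log2 noise 0.2, a quarter
    of features per reversal template, S/T/Y residue mix 86/12.5/1.5%.
    """

    n_proteins: int = 200
    n_sites: int = 400
    replicates_per_group: int = 4
    trend_templates: tuple[tuple[float, ...], ...] = DEFAULT_TEMPLATES
    fraction_per_template: tuple[float, ...] = (0.25, 0.25)
    noise_sd: float = 0.2
    baseline_log_mean: float = 20.0
    baseline_log_sd: float = 2.0
    missing_rate: float = 0.0
    residue_probs: tuple[float, float, float] = (0.86, 0.125, 0.015)
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 40)
    enriched_term_per_template: bool = True
    enriched_term_purity: float = 0.8
    edge_density: float = 0.05
    hub_module_size: int = 10
    hub_edge_prob: float = 0.9
    hub_wiring: str = "clique"  # or "star"
    score_beta_params: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        if self.n_sites < 0:
            raise ConfigurationError("n_sites must be nonnegative")
        if self.replicates_per_group < 1:
            raise ConfigurationError("replicates_per_group must be positive")
        fr = self.fraction_per_template
        if len(fr) != len(self.trend_templates):
            raise ConfigurationError(
                "fraction_per_template must match trend_templates in length"
            )
        if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ConfigurationError(
                "template fractions must be nonnegative and sum to <= 1"
            )
        for t in self.trend_templates:
            if len(t) != len(GROUPS):
                raise ConfigurationError("each trend template must have 4 entries")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if abs(sum(self.residue_probs) - 1) > 1e-9:
            raise ConfigurationError("residue_probs must sum to 1")
        if not 0 <= self.edge_density <= 1:
            raise ConfigurationError("edge_density must be in [0, 1]")
        if self.hub_wiring not in ("clique", "star"):
            raise ConfigurationError("hub_wiring must be 'clique' or 'star'")
        if any(p <= 0 for p in self.score_beta_params):
            raise ConfigurationError("score_beta_params must be positive")


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the synthetic matrices."""

    templates: tuple[tuple[float, ...], ...]
    protein_template: pd.Series  # protein id -> template index, -1 for null
    site_protein: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    site_template: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    term_members: dict[str, set[str]] = field(default_factory=dict)
    enriched_terms: dict[int, str] = field(default_factory=dict)
    hub_proteins: list[str] = field(default_factory=list)

    def template_effect(self, idx: int) -> np.ndarray:
        if idx < 0:
            return np.zeros(len(GROUPS))
        return np.asarray(self.templates[idx], dtype=float)

    def true_directions(
        self, level: str = "protein", fc_up: float = 1.5
    ) -> pd.DataFrame:
        """Per-feature true direction (up/down/unchanged) for each contrast.

        Directions follow from the planted log2 effects: a contrast is
        'up' when the effect difference exceeds log2(fc_up), 'down' when
        it falls below -log2(fc_up).
        """
        assign = self.protein_template if level == "protein" else self.site_template
        thr = math.log2(fc_up)
        out = {}
        for num, den in CONTRASTS:
            gi, gj = GROUPS.index(num), GROUPS.index(den)
            dirs = []
            for t in assign:
                d = self.template_effect(t)[gi] - self.template_effect(t)[gj]
                dirs.append("up" if d > thr else "down" if d < -thr else "unchanged")
            out[f"{num}/{den}"] = dirs
        return pd.DataFrame(out, index=assign.index)

    def reversal_features(self, level: str = "protein", fc_up: float = 1.5):
        """Features whose planted pattern is treatment-reversed.

        The model-contrast (M/C) direction is opposed by the treatment
        contrast (MT/M), and the control-treatment contrast (CT/C)
        matches MT/M; all three called (no 'unchanged').
        """
        d = self.true_directions(level=level, fc_up=fc_up)
        mask = (
            (d["M/C"] != "unchanged")
            & (d["MT/M"] != "unchanged")
            & (d["CT/C"] != "unchanged")
            & (d["M/C"] != d["MT/M"])
            & (d["MT/M"] == d["CT/C"])
        )
        return set(d.index[mask])


def _sample_table(cfg: SimulationConfig) -> pd.Series:
    samples = {}
    for g in GROUPS:
        for r in range(1, cfg.replicates_per_group + 1):
            samples[f"{g}{r}"] = g
    return pd.Series(samples, name="group")


def _assign_templates(n: int, fractions, rng: np.random.Generator) -> np.ndarray:
    """Template index per feature (-1 = null), fractions taken from the top."""
    counts = [int(round(f * n)) for f in fractions]
    if sum(counts) > n:  # rounding overflow on tiny n
        counts[-1] -= sum(counts) - n
    assign = np.full(n, -1, dtype=int)
    order = rng.permutation(n)
    pos = 0
    for t, c in enumerate(counts):
        assign[order[pos : pos + c]] = t
        pos += c
    return assign


def simulate_proteome(cfg: SimulationConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate a protein-level LFQ intensity matrix with planted trends.

    Intensity of protein *j* in a sample of group *g* is
    ``2**(baseline_j + template_j[g] + N(0, noise_sd))``; missing values
    (if ``missing_rate`` > 0) are masked completely at random afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_table(cfg)
    n, n_samp = cfg.n_proteins, len(samples)
    proteins = [f"P{i:04d}" for i in range(1, n + 1)]

    assign = _assign_templates(n, cfg.fraction_per_template, rng)
    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    effects = np.zeros((n, n_samp))
    group_idx = np.array([GROUPS.index(g) for g in samples.values])
    for i, t in enumerate(assign):
        if t >= 0:
            effects[i] = np.asarray(cfg.trend_templates[t])[group_idx]
    log2_vals = baseline[:, None] + effects + rng.normal(0, cfg.noise_sd, (n, n_samp))
    values = pd.DataFrame(
        np.exp2(log2_vals), index=proteins, columns=samples.index
    )
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)

    truth = GroundTruth(
        templates=tuple(tuple(t) for t in cfg.trend_templates),
        protein_template=pd.Series(assign, index=proteins),
    )
    return IntensityMatrix(values, samples, level="protein"), truth


def simulate_phosphoproteome(
    cfg: SimulationConfig, proteome: IntensityMatrix, truth: GroundTruth
) -> tuple[IntensityMatrix, GroundTruth]:
    """Generate phosphosite intensities layered on a simulated proteome.

    Each site row equals its parent protein's intensity times
    ``2**(site template effect + N(0, noise_sd))``, so protein-level
    trends propagate into uncorrected site values and cancel exactly
    after phospho-by-protein correction (up to noise).  Residues are
    drawn S/T/Y with ``residue_probs``; positions are unique integers.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    samples = proteome.groups
    n = cfg.n_sites
    proteins = list(proteome.values.index)
    if n == 0:
        empty = pd.DataFrame(columns=proteome.values.columns)
        sites = pd.DataFrame(columns=["protein_id", "residue", "position"])
        truth.site_protein = pd.Series(dtype=object)
        truth.site_template = pd.Series(dtype=int)
        return IntensityMatrix(empty, samples, level="phosphosite", sites=sites), truth

    parents = rng.choice(proteins, size=n, replace=True)
    missing_parents = set(parents) - set(proteins)
    if missing_parents:
        raise ConsistencyError(f"sites reference absent proteins: {missing_parents}")
    residues = rng.choice(["S", "T", "Y"], size=n, p=list(cfg.residue_probs))
    positions = rng.choice(
        np.arange(1, max(2001, 5 * n)), size=n, replace=False
    )
    site_ids = [
        f"{p}_{r}{q}" for p, r, q in zip(parents, residues, positions)
    ]
    assign = _assign_templates(n, cfg.fraction_per_template, rng)

    group_idx = np.array([GROUPS.index(g) for g in samples.values])
    effects = np.zeros((n, len(samples)))
    for i, t in enumerate(assign):
        if t >= 0:
            effects[i] = np.asarray(cfg.trend_templates[t])[group_idx]
    parent_vals = proteome.values.loc[parents].to_numpy(dtype=float)
    site_vals = parent_vals * np.exp2(
        effects + rng.normal(0, cfg.noise_sd, (n, len(samples)))
    )
    values = pd.DataFrame(site_vals, index=site_ids, columns=samples.index)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)

    sites = pd.DataFrame(
        {"protein_id": parents, "residue": residues, "position": positions},
        index=pd.Index(site_ids, name="site_id"),
    )
    truth.site_protein = pd.Series(parents, index=site_ids)
    truth.site_template = pd.Series(assign, index=site_ids)
    mat = IntensityMatrix(values, samples, level="phosphosite", sites=sites)
    return mat, truth


def simulate_annotations_and_network(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, dict], pd.DataFrame]:
    """Generate GMT-style term sets and a scored interaction edge list.

    One term per trend template is *planted*: at least
    ``enriched_term_purity`` of its members come from that template's
    proteins (when ``enriched_term_per_template`` is on).  Edges are
    Erdos-Renyi background with Beta-distributed confidence scores plus
    a densely wired, high-confidence module among planted hub proteins
    drawn from the template features.  ``edge_density == 0`` disables
    the network entirely (an empty edge list, including the module).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    proteins = list(truth.protein_template.index)
    n = len(proteins)
    assign = truth.protein_template

    # ---- annotation terms -------------------------------------------------
    terms: dict[str, dict] = {}
    lo, hi = cfg.term_size_range
    t_idx = 0
    if cfg.enriched_term_per_template:
        for t in range(len(truth.templates)):
            t_idx += 1
            tid = f"TERM{t_idx:04d}"
            pool = [p for p in proteins if assign[p] == t]
            size = int(rng.integers(lo, hi + 1))
            size = min(size, n)
            n_in = min(len(pool), max(1, math.ceil(cfg.enriched_term_purity * size)))
            members = list(rng.choice(pool, size=n_in, replace=False))
            others = [p for p in proteins if p not in set(members)]
            n_out = min(size - n_in, len(others))
            if n_out > 0:
                members += list(rng.choice(others, size=n_out, replace=False))
            terms[tid] = {
                "name": f"planted template {t} term",
                "category": TERM_CATEGORIES[t % len(TERM_CATEGORIES)],
                "members": set(members),
            }
            truth.enriched_terms[t] = tid
    while t_idx < cfg.n_terms:
        t_idx += 1
        tid = f"TERM{t_idx:04d}"
        size = min(int(rng.integers(lo, hi + 1)), n)
        members = set(rng.choice(proteins, size=size, replace=False))
        terms[tid] = {
            "name": f"background term {t_idx}",
            "category": TERM_CATEGORIES[t_idx % len(TERM_CATEGORIES)],
            "members": members,
        }
    truth.term_members = {tid: t["members"] for tid, t in terms.items()}

    # ---- interaction network ---------------------------------------------
    if cfg.edge_density == 0:
        edges = pd.DataFrame(columns=["node_a", "node_b", "score"])
        truth.hub_proteins = []
        return terms, edges

    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < cfg.edge_density
    a, b = iu[keep], ju[keep]
    scores = rng.beta(*cfg.score_beta_params, size=len(a))
    edge_scores: dict[tuple[str, str], float] = {
        (proteins[i], proteins[j]): s for i, j, s in zip(a, b, scores)
    }

    template_feats = [p for p in proteins if assign[p] >= 0]
    k = min(cfg.hub_module_size, len(template_feats))
    hubs = list(rng.choice(template_feats, size=k, replace=False)) if k else []
    if cfg.hub_wiring == "star" and len(hubs) >= 2:
        pairs = [(hubs[0], h) for h in hubs[1:]]
        truth.hub_proteins = hubs[:1]
    else:
        pairs = [
            (hubs[i], hubs[j])
            for i in range(len(hubs))
            for j in range(i + 1, len(hubs))
            if rng.random() < cfg.hub_edge_prob
        ]
        truth.hub_proteins = hubs
    for u, v in pairs:
        key = (u, v) if u <= v else (v, u)
        edge_scores[key] = float(rng.uniform(0.75, 0.95))

    edges = pd.DataFrame(
        [(u, v, s) for (u, v), s in sorted(edge_scores.items())],
        columns=["node_a", "node_b", "score"],
    )
    return terms, edges


@dataclass
class SyntheticDataset:
    """Bundle of all simulated inputs plus the planted truth."""

    proteome: IntensityMatrix
    phospho: IntensityMatrix
    terms: dict[str, dict]
    edges: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run the three generators in sequence and bundle the results."""
    proteome, truth = simulate_proteome(cfg)
    phospho, truth = simulate_phosphoproteome(cfg, proteome, truth)
    terms, edges = simulate_annotations_and_network(cfg, truth)
    return SyntheticDataset(proteome, phospho, terms, edges, truth, cfg)
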