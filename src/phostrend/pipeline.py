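"""End-to-end orchestration of the trend-analysis pipeline.

Stages, in order: relative quantification and QC; phospho-by-protein
correction; protein path ANOVA screen -> k-means overview -> SD filter
-> fuzzy c-means -> treatment-reversal cluster selection; phospho path
SD filter -> fuzzy c-means -> selection (the ANOVA/k-means pre-screen
is skipped at site level, where the trend filter is applied to all
sites directly); term enrichment of the selections; three contrasts
(CT/C, M/C, MT/M) at both levels; confidence-filtered interaction
subnetworks, average-degree hubs and the three-contrast concordance
table.  The run report records feature counts at every stage together
with all parameters and the seed, so a run is reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cluster import (
    SoftClustering,
    TrendSelection,
    anova_screen,
    fuzzy_cmeans,
    kmeans_clusters,
    log2_sd_filter,
    select_trend_clusters,
)
from .enrich import EnrichmentResult, TermSet, enrich
from .matrix import ConfigurationError, IntensityMatrix
from .network import (
    CONTRAST_LABELS,
    ContrastResult,
    build_subnetwork,
    concordance_table,
    contrast,
    hub_nodes,
)
from .quantify import (
    completeness_filter,
    compute_rsd,
    correct_phospho_by_protein,
    pca_samples,
    relative_quantify,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    sd_min: log2-SD filters (0.2 protein, 0.5 phosphosite);
    kmeans_k / fuzzy_c: cluster counts (6 / 5 protein, 7 phosphosite);
    fc_up 1.5 and test_alpha 0.05 for differential calls; score_min
    0.7 for high-confidence interactions; anova_alpha / enrich_alpha
    0.05; membership_min 0.5 and trend_epsilon 0.05 for selection.
    """

    sd_min_protein: float = 0.2
    sd_min_phospho: float = 0.5
    kmeans_k: int = 6
    fuzzy_c_protein: int = 5
    fuzzy_c_phospho: int = 7
    fuzzifier: float = 2.0
    anova_alpha: float = 0.05
    fc_up: float = 1.5
    test_alpha: float = 0.05
    score_min: float = 0.7
    enrich_alpha: float = 0.05
    membership_min: float = 0.5
    trend_epsilon: float = 0.05
    completeness_min: float = 0.5
    rsd_threshold: float = 0.2
    correct_phospho: bool = True
    equal_var: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("anova_alpha", "test_alpha", "enrich_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        for name in ("sd_min_protein", "sd_min_phospho", "score_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.fc_up <= 1:
            raise ConfigurationError("fc_up must be > 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LevelResult:
    """Per-level (protein or phosphosite) intermediate results."""

    relative: IntensityMatrix
    screen: object | None
    kmeans: pd.Series | None
    filtered: IntensityMatrix
    clustering: SoftClustering | None
    selection: TrendSelection
    enrichment: EnrichmentResult | None


@dataclass
class PipelineResult:
    """Everything a run produced, plus the machine-readable report."""

    protein: LevelResult
    phospho: LevelResult | None
    contrasts_protein: dict[str, ContrastResult]
    contrasts_phospho: dict[str, ContrastResult]
    networks: dict[str, object]
    hubs: dict[str, set[str]]
    average_degree: dict[str, float]
    concordance: pd.DataFrame
    report: dict


def _trend_stage(
    rel: IntensityMatrix,
    level: str,
    cfg: PipelineConfig,
    counts: dict,
) -> tuple[LevelResult, set[str]]:
    """Screen/cluster/select for one level; returns result + selected ids."""
    if level == "protein":
        screen = anova_screen(rel, alpha=cfg.anova_alpha)
        counts["anova_pass"] = int(len(screen.passed))
        screened = rel.subset(screen.passed)
        km = (
            kmeans_clusters(screened, k=cfg.kmeans_k, seed=cfg.seed)
            if len(screen.passed) >= cfg.kmeans_k
            else None
        )
        sd_min, c = cfg.sd_min_protein, cfg.fuzzy_c_protein
    else:
        # site level skips the ANOVA/k-means pre-screen: the SD filter is
        # applied to all sites directly
        screen, km, screened = None, None, rel
        sd_min, c = cfg.sd_min_phospho, cfg.fuzzy_c_phospho

    filtered = log2_sd_filter(screened, sd_min=sd_min)
    counts["sd_pass"] = int(filtered.n_features)
    if filtered.n_features < c:
        # nothing (or too little) varies at this level: empty selection
        logger.warning(
            "%s: %d features after SD filter (< c=%d); skipping clustering",
            level, filtered.n_features, c,
        )
        sc = None
        sel = TrendSelection(
            cluster_table=pd.DataFrame(),
            selected_clusters=[],
            selected_features=[],
            membership_min=cfg.membership_min,
            epsilon=cfg.trend_epsilon,
        )
        counts["per_cluster"] = {}
    else:
        sc = fuzzy_cmeans(filtered, c=c, m=cfg.fuzzifier, seed=cfg.seed)
        sel = select_trend_clusters(
            sc,
            rel.groups,
            epsilon=cfg.trend_epsilon,
            membership_min=cfg.membership_min,
        )
        counts["per_cluster"] = {
            int(k): int(v) for k, v in sc.hard.value_counts().sort_index().items()
        }
    counts["selected_clusters"] = sel.selected_clusters
    counts["selected"] = len(sel.selected_features)
    result = LevelResult(
        relative=rel,
        screen=screen,
        kmeans=km,
        filtered=filtered,
        clustering=sc,
        selection=sel,
        enrichment=None,
    )
    return result, set(sel.selected_features)


def run_all(
    proteome_raw: IntensityMatrix,
    phospho_raw: IntensityMatrix | None,
    terms: list[TermSet],
    edges: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full pipeline on raw intensity matrices.

    Phospho correction by protein abundance is applied when both
    levels are supplied (and ``cfg.correct_phospho`` is on); corrected
    site values are re-centralised before trend analysis.
    """
    cfg = cfg or PipelineConfig()
    report: dict = {"config": cfg.to_dict(), "counts": {}, "qc": {}}

    # ---- quantification + QC ---------------------------------------------
    prot_counts: dict = {"features_in": int(proteome_raw.n_features)}
    prot_comparable = completeness_filter(proteome_raw, cfg.completeness_min)
    prot_counts["comparable"] = int(prot_comparable.n_features)
    rel_prot = relative_quantify(prot_comparable)
    qc = compute_rsd(rel_prot, threshold=cfg.rsd_threshold)
    report["qc"]["protein_rsd"] = {
        "median": qc.rsd_summary["median_rsd"].round(4).to_dict(),
        "pass": bool(qc.rsd_summary["pass"].all()),
    }
    try:
        pca = pca_samples(rel_prot, n_components=2)
        report["qc"]["protein_pca_explained"] = [
            round(float(v), 4) for v in pca.explained_variance
        ]
    except ConfigurationError:
        logger.warning("protein PCA skipped (too few complete features)")

    protein_level, prot_selected = _trend_stage(rel_prot, "protein", cfg, prot_counts)
    universe = set(rel_prot.values.index)
    if prot_selected and terms:
        protein_level.enrichment = enrich(
            prot_selected, terms, universe, alpha=cfg.enrich_alpha
        )
        prot_counts["enriched_terms"] = int(
            protein_level.enrichment.table["significant"].sum()
        )
    report["counts"]["protein"] = prot_counts

    # ---- phospho path -----------------------------------------------------
    phospho_level = None
    site_map = None
    contrasts_phospho: dict[str, ContrastResult] = {}
    if phospho_raw is not None and phospho_raw.n_features > 0:
        site_counts: dict = {"features_in": int(phospho_raw.n_features)}
        site_comparable = completeness_filter(phospho_raw, cfg.completeness_min)
        site_counts["comparable"] = int(site_comparable.n_features)
        rel_site = relative_quantify(site_comparable)
        if cfg.correct_phospho:
            corrected = correct_phospho_by_protein(rel_site, rel_prot)
            rel_site = relative_quantify(corrected)
            site_counts["corrected"] = int(rel_site.sites["corrected"].sum())
        phospho_level, site_selected = _trend_stage(rel_site, "phospho", cfg, site_counts)
        site_map = rel_site.sites["protein_id"]
        if site_selected and terms:
            parent_universe = set(site_map)
            parent_sel = {site_map[s] for s in site_selected} & parent_universe
            if parent_sel:
                phospho_level.enrichment = enrich(
                    parent_sel, terms, parent_universe, alpha=cfg.enrich_alpha
                )
                site_counts["enriched_terms"] = int(
                    phospho_level.enrichment.table["significant"].sum()
                )
        report["counts"]["phospho"] = site_counts
        contrasts_phospho = {
            f"{a}/{b}": contrast(
                rel_site, a, b, cfg.fc_up, cfg.test_alpha, equal_var=cfg.equal_var
            )
            for a, b in (("CT", "C"), ("M", "C"), ("MT", "M"))
        }

    # ---- contrasts, networks, hubs, concordance ---------------------------
    contrasts_protein = {
        f"{a}/{b}": contrast(
            rel_prot, a, b, cfg.fc_up, cfg.test_alpha, equal_var=cfg.equal_var
        )
        for a, b in (("CT", "C"), ("M", "C"), ("MT", "M"))
    }
    networks, hubs, avg_deg = {}, {}, {}
    dep_counts = {}
    for label in CONTRAST_LABELS:
        prot_deps = contrasts_protein[label].deps
        site_deps = (
            contrasts_phospho[label].deps if label in contrasts_phospho else set()
        )
        nodes = prot_deps | (
            {site_map[s] for s in site_deps} if site_map is not None else set()
        )
        dep_counts[label] = {
            "protein_deps": len(prot_deps),
            "site_deps": len(site_deps),
            "network_nodes": len(nodes),
        }
        if nodes:
            G = build_subnetwork(edges, nodes, score_min=cfg.score_min)
            avg, hub = hub_nodes(G)
        else:
            G, avg, hub = None, 0.0, set()
        networks[label], avg_deg[label], hubs[label] = G, avg, hub
        dep_counts[label]["edges"] = G.number_of_edges() if G is not None else 0
        dep_counts[label]["average_degree"] = round(avg, 4)
        dep_counts[label]["hubs"] = len(hub)
    report["counts"]["contrasts"] = dep_counts

    dep_sites = set()
    for cr in contrasts_phospho.values():
        dep_sites |= cr.deps
    conc = concordance_table(
        contrasts_protein,
        hubs,
        site_contrasts=contrasts_phospho or None,
        site_map=site_map.loc[sorted(dep_sites & set(site_map.index))]
        if site_map is not None
        else None,
    )
    report["counts"]["overlapping_rows"] = int(len(conc))
    report["counts"]["reversal_candidates"] = int(conc["reversal_candidate"].sum())

    return PipelineResult(
        protein=protein_level,
        phospho=phospho_level,
        contrasts_protein=contrasts_protein,
        contrasts_phospho=contrasts_phospho,
        networks=networks,
        hubs=hubs,
        average_degree=avg_deg,
        concordance=conc,
        report=report,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the run report and key tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(result.report, indent=1, default=str))
    for level, lr in (("protein", result.protein), ("phospho", result.phospho)):
        if lr is None:
            continue
        if lr.clustering is not None:
            lr.clustering.membership.rename_axis("feature_id").to_csv(
                outdir / f"{level}_membership.tsv", sep="\t"
            )
            lr.clustering.centroids.rename_axis("cluster").to_csv(
                outdir / f"{level}_centroids.tsv", sep="\t"
            )
        (outdir / f"{level}_selected.txt").write_text(
            "\n".join(lr.selection.selected_features) + "\n"
            if lr.selection.selected_features
            else ""
        )
        if lr.enrichment is not None:
            lr.enrichment.table.to_csv(
                outdir / f"{level}_enrichment.tsv", sep="\t", index=False
            )
    for label, cr in {**result.contrasts_protein}.items():
        safe = label.replace("/", "_")
        cr.table.rename_axis("feature_id").to_csv(
            outdir / f"contrast_protein_{safe}.tsv", sep="\t"
        )
    for label, cr in result.contrasts_phospho.items():
        safe = label.replace("/", "_")
        cr.table.rename_axis("feature_id").to_csv(
            outdir / f"contrast_phospho_{safe}.tsv", sep="\t"
        )
    result.concordance.to_csv(outdir / "concordance.tsv", sep="\t", index=False)
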