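"""Plain-text input/output for matrices, annotations and networks.

All formats are tab-separated text: intensity TSV (feature id + one
column per sample), sample table (sample_id, group, replicate), site
table (site_id, protein_id, residue, position), GMT annotation files,
scored edge lists (node_a, node_b, score) and a ground-truth JSON for
synthetic datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .enrich import TermSet, write_gmt
from .matrix import ConfigurationError, IntensityMatrix
from .simulate import SyntheticDataset


def read_samples(path: str | Path) -> pd.Series:
    """Sample table TSV -> Series mapping sample_id to group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns sample_id, group")
    return df.set_index("sample_id")["group"]


def read_intensities(
    path: str | Path,
    samples: pd.Series,
    level: str = "protein",
    sites_path: str | Path | None = None,
) -> IntensityMatrix:
    """Read an intensity TSV (first column = feature id) into a matrix."""
    vals = pd.read_csv(path, sep="\t", index_col=0)
    sites = None
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", index_col=0)
    return IntensityMatrix(vals, samples, level=level, sites=sites)


def write_matrix(mat: IntensityMatrix, path: str | Path, id_name: str = "feature_id") -> None:
    mat.values.rename_axis(id_name).to_csv(path, sep="\t")


def write_samples(groups: pd.Series, path: str | Path) -> None:
    rep = groups.groupby(groups).cumcount() + 1
    df = pd.DataFrame(
        {"sample_id": groups.index, "group": groups.values, "replicate": rep.values}
    )
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"node_a", "node_b", "score"}.issubset(df.columns):
        raise ConfigurationError(f"{path}: needs columns node_a, node_b, score")
    return df


def terms_to_termsets(terms: dict[str, dict]) -> list[TermSet]:
    """Convert the simulator's term dict to TermSet objects."""
    return [
        TermSet(term_id=tid, name=t["name"], members=set(t["members"]),
                category=t.get("category", ""))
        for tid, t in terms.items()
    ]


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.tsv",
        "phospho": outdir / "phospho.tsv",
        "samples": outdir / "samples.tsv",
        "sites": outdir / "sites.tsv",
        "terms": outdir / "terms.gmt",
        "edges": outdir / "edges.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_matrix(ds.proteome, paths["proteome"], "protein_id")
    write_matrix(ds.phospho, paths["phospho"], "site_id")
    write_samples(ds.proteome.groups, paths["samples"])
    ds.phospho.sites.rename_axis("site_id").to_csv(paths["sites"], sep="\t")
    write_gmt(terms_to_termsets(ds.terms), paths["terms"])
    ds.edges.to_csv(paths["edges"], sep="\t", index=False)

    truth = ds.truth
    payload = {
        "templates": [list(t) for t in truth.templates],
        "protein_template": truth.protein_template.to_dict(),
        "site_protein": truth.site_protein.to_dict(),
        "site_template": {k: int(v) for k, v in truth.site_template.items()},
        "term_members": {k: sorted(v) for k, v in truth.term_members.items()},
        "enriched_terms": {str(k): v for k, v in truth.enriched_terms.items()},
        "hub_proteins": list(truth.hub_proteins),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def load_dataset(indir: str | Path) -> tuple[IntensityMatrix, IntensityMatrix, list[TermSet], pd.DataFrame]:
    """Read back the files written by :func:`write_dataset` (no truth)."""
    from .enrich import read_gmt

    indir = Path(indir)
    samples = read_samples(indir / "samples.tsv")
    proteome = read_intensities(indir / "proteome.tsv", samples, "protein")
    phospho = read_intensities(
        indir / "phospho.tsv", samples, "phosphosite", indir / "sites.tsv"
    )
    terms = read_gmt(indir / "terms.gmt")
    edges = read_edges(indir / "edges.tsv")
    return proteome, phospho, terms, edges
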