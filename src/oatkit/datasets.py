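"""Bundled statistics of the published hexaploid oat SNP assay and map.

Small reference tables shipped with the package: the per-method summary of
the 3,072-assay GoldenGate SNP panel, and the per-chromosome statistics of
the 1,838.8 cM, 21-group physically-anchored consensus map.  The
per-genome marker totals are stored separately as printed because the
published per-chromosome marker column does not sum exactly to them
(417 printed vs 423 summed for the C genome); derived shares use the
printed totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("oatkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def assay_panel_summary() -> pd.DataFrame:
    """Per-discovery-method counts of tested, converted, mapped and
    diversity-polymorphic SNP assays."""
    return _load("assay_panel_summary.csv")


def consensus_map_chromosomes() -> pd.DataFrame:
    """Per-chromosome consensus-map statistics (length, marker classes)."""
    return _load("consensus_map_chromosomes.csv")


def consensus_map_genome_totals() -> pd.DataFrame:
    """Printed per-genome and grand totals of map length and marker count."""
    return _load("consensus_map_genome_totals.csv")


def diversity_polymorphic_share(summary: pd.DataFrame | None = None) -> float:
    """Percent of converted assays polymorphic in the diversity panel."""
    df = assay_panel_summary() if summary is None else summary
    return 100.0 * df["n_diversity_polymorphic"].sum() / df["n_converted"].sum()


def mapped_share(summary: pd.DataFrame | None = None) -> float:
    """Percent of converted assays segregating in at least one population."""
    df = assay_panel_summary() if summary is None else summary
    return 100.0 * df["n_mapped"].sum() / df["n_converted"].sum()


def total_map_length(chromosomes: pd.DataFrame | None = None) -> float:
    """Consensus map length (cM) as the sum of per-chromosome lengths."""
    df = consensus_map_chromosomes() if chromosomes is None else chromosomes
    return float(df["length_cm"].sum())


def genome_marker_share(genome: str,
                        totals: pd.DataFrame | None = None) -> float:
    """Percent of mapped markers on one subgenome, from per-genome totals."""
    df = consensus_map_genome_totals() if totals is None else totals
    per_genome = df[df["genome"] != "all"]
    n = per_genome.loc[per_genome["genome"] == genome, "n_markers"]
    if n.empty:
        raise KeyError(genome)
    return 100.0 * float(n.iloc[0]) / per_genome["n_markers"].sum()


def mean_marker_spacing(totals: pd.DataFrame | None = None) -> float:
    """Average marker distance: total length over the grand locus total."""
    df = consensus_map_genome_totals() if totals is None else totals
    grand = df[df["genome"] == "all"].iloc[0]
    return float(grand["length_cm"]) / float(grand["n_markers"])
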