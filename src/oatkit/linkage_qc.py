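"""Marker quality filters and recombination-fraction grouping.

Implements the marker-removal rules used ahead of consensus-map
construction (segregation distortion and missingness) and linkage-group
formation as connected components of the pairwise recombinant-fraction
graph, including the incremental threshold ladder (0.15 -> 0.25) used to
merge preliminary groups end-to-end.  Marker ordering is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats import GenotypeMatrix


@dataclass
class MarkerStats:
    marker: str
    a_fraction: float  # allele-A share of non-missing calls (H counts half)
    missing_fraction: float
    n_informative: int


def marker_stats(genotypes: GenotypeMatrix) -> list[MarkerStats]:
    calls = genotypes.calls
    out = []
    for m in calls.columns:
        col = calls[m]
        n = len(col)
        missing = (col == "U").sum()
        informative = n - missing
        n_a = (col == "A").sum() + 0.5 * (col == "H").sum()
        frac = n_a / informative if informative else float("nan")
        out.append(MarkerStats(m, float(frac), missing / n, int(informative)))
    return out


def filter_markers(genotypes: GenotypeMatrix, distortion_low: float = 0.25,
                   distortion_high: float = 0.75, max_missing: float = 0.10):
    """Remove distorted (<=0.25 or >=0.75 allele-A share) or gappy markers.

    The two rules act independently; the report names every rule a removed
    marker triggered, so either reading of the joint criterion is
    recoverable from it.

    Returns ``(kept_marker_list, report_dataframe)``.
    """
    rows = []
    kept = []
    for s in marker_stats(genotypes):
        reasons = []
        if not np.isnan(s.a_fraction) and (
                s.a_fraction <= distortion_low or s.a_fraction >= distortion_high):
            reasons.append("distortion")
        if s.missing_fraction >= max_missing:
            reasons.append("missingness")
        if not reasons:
            kept.append(s.marker)
        rows.append({
            "marker": s.marker,
            "a_fraction": s.a_fraction,
            "missing_fraction": s.missing_fraction,
            "removed": bool(reasons),
            "reasons": ",".join(reasons),
        })
    return kept, pd.DataFrame(rows)


def estimate_rf(genotypes: GenotypeMatrix, marker_i: str, marker_j: str):
    """Observed recombinant fraction R and the selfed-RIL meiotic estimate r.

    R = mismatched calls / non-missing homozygous pairs; r = R/(2-2R)
    capped at 0.5 (the selfed-RIL correction inverse of R = 2r/(1+2r)).
    Returns ``(R, r, n_pairs)``; pairs involving H or U are excluded.
    ``(None, None, 0)`` when no informative pair exists.
    """
    a = genotypes.calls[marker_i]
    b = genotypes.calls[marker_j]
    ok = a.isin(["A", "B"]) & b.isin(["A", "B"])
    n = int(ok.sum())
    if n == 0:
        return None, None, 0
    big_r = float((a[ok] != b[ok]).mean())
    if big_r >= 0.5:
        r = 0.5
    else:
        r = min(0.5, big_r / (2.0 - 2.0 * big_r))
    return big_r, r, n


def rf_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs observed recombinant fractions (NaN when uninformative)."""
    calls = genotypes.calls.to_numpy()
    x = np.where(calls == "B", 1.0, 0.0)
    valid = np.isin(calls, ["A", "B"]).astype(float)
    x = x * valid
    # mismatches_ij = sum over samples of xi(1-xj) + (1-xi)xj within valid pairs
    mism = x.T @ (valid - x) + (valid - x).T @ x
    n = valid.T @ valid
    with np.errstate(invalid="ignore", divide="ignore"):
        big_r = np.where(n > 0, mism / n, np.nan)
    np.fill_diagonal(big_r, 0.0)
    loci = genotypes.loci
    return pd.DataFrame(big_r, index=loci, columns=loci)


def group_markers(rf: pd.DataFrame, threshold: float) -> list[list[str]]:
    """Partition markers into linkage groups at an observed-R threshold.

    Groups are the connected components of the graph with an edge wherever
    R <= threshold; returned sorted (each group internally sorted, groups
    by first marker) for determinism.
    """
    g = nx.Graph()
    loci = list(rf.index)
    g.add_nodes_from(loci)
    arr = rf.to_numpy()
    ii, jj = np.where(np.triu(arr <= threshold, k=1))
    g.add_edges_from((loci[i], loci[j]) for i, j in zip(ii, jj))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def group_trajectory(rf: pd.DataFrame, start: float = 0.15, stop: float = 0.25,
                     step: float = 0.05):
    """Component partition at each rung of an increasing rf ladder."""
    thresholds = []
    t = start
    while t <= stop + 1e-9:
        thresholds.append(round(t, 10))
        t += step
    return [(t, group_markers(rf, t)) for t in thresholds]
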