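"""Model-genome match filtering and collinear block inference.

Match lists from sequence searches of SNP design sequences against rice or
Brachypodium pseudomolecules are reduced in a fixed order — significance
filter, per-Mb best-hit dedupe, promiscuous-query removal — and the
survivors, ordered along each oat linkage group in cM, are scanned for
runs of markers pointing at one target chromosome (macro-collinearity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .formats import LinkageMap, SyntenyMatch


def filter_matches(matches, min_score: float = 100.0,
                   max_e: float = 5e-20) -> list[SyntenyMatch]:
    """Keep significant matches: bit score > min_score OR E-value < max_e."""
    return [m for m in matches
            if m.bit_score > min_score or m.evalue < max_e]


def _mb_bin(midpoint: float, rounding: str) -> int:
    mb = midpoint / 1e6
    if rounding == "half-up":
        return math.floor(mb + 0.5)
    if rounding == "floor":
        return math.floor(mb)
    raise ValueError(f"unknown rounding {rounding!r}")


def dedupe_by_midpoint(matches, rounding: str = "half-up") -> list[SyntenyMatch]:
    """Best match per (query, genome, chromosome, integer-Mb midpoint bin).

    Ties break by lower E-value, then input order.  Output preserves input
    order of the winners.
    """
    best: dict[tuple, tuple] = {}
    for i, m in enumerate(matches):
        key = (m.query_id, m.genome, m.chromosome,
               _mb_bin(m.midpoint, rounding))
        rank = (-m.bit_score, m.evalue, i)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, i, m)
    winners = sorted(best.values(), key=lambda t: t[1])
    return [m for _, _, m in winners]


def drop_promiscuous(matches, max_chroms: int = 3,
                     genomes=None) -> list[SyntenyMatch]:
    """Drop every match of a query hitting too many chromosomes of a genome.

    Applied per (query, genome); ``genomes`` restricts the rule to the
    named genomes (default: all).  Highly repetitive sequences fall out
    here without a separate exclusion list.
    """
    chroms: dict[tuple, set] = {}
    for m in matches:
        chroms.setdefault((m.query_id, m.genome), set()).add(m.chromosome)
    dropped = {key for key, cs in chroms.items()
               if len(cs) > max_chroms
               and (genomes is None or key[1] in genomes)}
    return [m for m in matches if (m.query_id, m.genome) not in dropped]


def filter_pipeline(matches, min_score: float = 100.0, max_e: float = 5e-20,
                    max_chroms: int = 3, rounding: str = "half-up",
                    genomes=None) -> list[SyntenyMatch]:
    """Canonical order: significance filter -> Mb dedupe -> promiscuity drop."""
    out = filter_matches(matches, min_score, max_e)
    out = dedupe_by_midpoint(out, rounding)
    return drop_promiscuous(out, max_chroms, genomes)


# ---------------------------------------------------------------------------
# collinear blocks


@dataclass
class SyntenyBlock:
    group: str
    cm_start: float
    cm_end: float
    genome: str
    chromosome: str
    bp_start: int
    bp_end: int
    n_markers: int
    markers: tuple = ()


def _best_per_marker(matches) -> dict[tuple, SyntenyMatch]:
    """Best retained match per (query, genome): bit score, then E-value."""
    best: dict[tuple, SyntenyMatch] = {}
    for m in matches:
        key = (m.query_id, m.genome)
        cur = best.get(key)
        if cur is None or (-m.bit_score, m.evalue, m.chromosome) < \
                (-cur.bit_score, cur.evalue, cur.chromosome):
            best[key] = m
    return best


def infer_blocks(matches, oat_map: LinkageMap, min_run: int = 3,
                 max_interrupt: int = 1) -> list[SyntenyBlock]:
    """Runs of consecutively mapped markers matching one target chromosome.

    Markers of each oat group are walked in cM order (only markers with a
    retained match participate).  A block is a maximal run of at least
    ``min_run`` markers anchored to one chromosome, tolerating up to
    ``max_interrupt`` interleaved markers anchored elsewhere in total (so
    alternating singletons never chain into a block).  Overlapping
    candidate runs on different target chromosomes are resolved greedily
    by size so that block intervals are non-overlapping per (group,
    genome).
    """
    best = _best_per_marker(matches)
    genomes = sorted({g for _, g in best})
    blocks: list[SyntenyBlock] = []
    for group in oat_map.groups:
        markers = oat_map.markers_of(group)
        for genome in genomes:
            anchored = [
                (row.marker, float(row.position_cm), best[(row.marker, genome)])
                for row in markers.itertuples()
                if (row.marker, genome) in best
            ]
            if not anchored:
                continue
            runs = []
            chrom_list = sorted({m.chromosome for _, _, m in anchored})
            for chrom in chrom_list:
                idx = [i for i, (_, _, m) in enumerate(anchored)
                       if m.chromosome == chrom]
                # maximal windows with at most max_interrupt interlopers
                b = 0
                last_end = -1
                for a in range(len(idx)):
                    b = max(b, a)
                    while b + 1 < len(idx) and \
                            (idx[b + 1] - idx[a]) - (b + 1 - a) <= max_interrupt:
                        b += 1
                    if b - a + 1 >= min_run and b > last_end:
                        runs.append((chrom, idx[a:b + 1]))
                        last_end = b
            # greedy non-overlap resolution: larger runs first
            runs.sort(key=lambda t: (-len(t[1]), t[1][0], t[0]))
            taken: list[tuple[int, int]] = []
            for chrom, members in runs:
                lo, hi = members[0], members[-1]
                if any(not (hi < a or lo > b) for a, b in taken):
                    continue
                taken.append((lo, hi))
                rows = [anchored[i] for i in members]
                mids = [m.midpoint for _, _, m in rows]
                blocks.append(SyntenyBlock(
                    group=group,
                    cm_start=rows[0][1],
                    cm_end=rows[-1][1],
                    genome=genome,
                    chromosome=chrom,
                    bp_start=int(min(mids)),
                    bp_end=int(max(mids)),
                    n_markers=len(rows),
                    markers=tuple(r[0] for r in rows),
                ))
    blocks.sort(key=lambda b: (b.group, b.genome, b.cm_start, b.chromosome))
    return blocks


def write_blocks_tsv(blocks, path) -> None:
    header = ("group\tcm_start\tcm_end\tgenome\tchromosome\t"
              "bp_start\tbp_end\tn_markers\n")
    with open(path, "w") as fh:
        fh.write(header)
        for b in blocks:
            fh.write(f"{b.group}\t{b.cm_start:g}\t{b.cm_end:g}\t{b.genome}\t"
                     f"{b.chromosome}\t{b.bp_start}\t{b.bp_end}\t"
                     f"{b.n_markers}\n")


def plot_blocks(blocks, ax=None):
    """Chromosome-painting view: one horizontal lane per oat group, block
    spans colored by target chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    groups = sorted({b.group for b in blocks})
    chroms = sorted({(b.genome, b.chromosome) for b in blocks})
    cmap = plt.get_cmap("tab20")
    color = {c: cmap(i % 20) for i, c in enumerate(chroms)}
    for y, group in enumerate(groups):
        for b in blocks:
            if b.group != group:
                continue
            ax.barh(y, b.cm_end - b.cm_start or 0.5, left=b.cm_start,
                    height=0.6, color=color[(b.genome, b.chromosome)],
                    edgecolor="black", linewidth=0.3)
    ax.set_yticks(range(len(groups)), groups)
    ax.set_xlabel("position (cM)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=color[c]) for c in chroms]
    ax.legend(handles, [f"{g} {c}" for g, c in chroms], fontsize=7, ncol=2)
    return ax
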