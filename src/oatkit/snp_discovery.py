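"""Multi-variety pileup tabulation, candidate SNP calling and filter ledgers.

The calling model is the one that makes SNP discovery workable in an
allohexaploid: a column is only a candidate when at least two varieties
each give a *pure* consensus base (at least two reads, one distinct base)
and the pure bases disagree between varieties.  Homoeolog collapse — reads
from diverged subgenome copies stacked on one template — shows up as
within-variety mixtures instead, and is flagged rather than called.

Filters only ever add status flags; records are never deleted, so
attrition accounting falls out of flag counts.  Selection happens last, by
predicted minor-allele frequency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .assembly import (AssemblyParams, assemble_greedy, composite_assemble,
                       condense_contig, place_reads_multi)
from .formats import Assembly

IMPURE = "IMPURE"
ABSENT = "ABSENT"

_BASES = "ACGTN*"
_CODE = {c: i for i, c in enumerate(_BASES)}
_LUT = np.full(256, -1, dtype=np.int8)
for _c, _i in _CODE.items():
    _LUT[ord(_c)] = _i

FLAG_ORDER = ("DEPTH", "HET_WITHIN_VARIETY", "INDEL", "AMBIG_REF", "LOW_MAF",
              "SHORT_FLANK", "LOW_SCORE", "REDUNDANT")


@dataclass(frozen=True)
class CandidateSnp:
    """One bi-allelic candidate site on a template."""

    template_id: str
    position: int  # 1-based unpadded
    ref: str
    alt: str
    depth: int
    variety_alleles: dict
    n_var_ref: int
    n_var_alt: int
    n_var_impure: int
    maf_pred: float
    flank_left: int
    flank_right: int
    design_score: float | None = None
    flags: frozenset = frozenset()
    context: str = ""

    @property
    def id(self) -> str:
        return f"{self.template_id}:{self.position}"

    @property
    def status(self) -> tuple[str, ...]:
        """Ordered filter flags; PASS when no filter fired."""
        if not self.flags:
            return ("PASS",)
        return tuple(f for f in FLAG_ORDER if f in self.flags)

    @property
    def passed(self) -> bool:
        return not self.flags

    def with_flags(self, *new: str) -> "CandidateSnp":
        return dataclasses.replace(self, flags=self.flags | set(new))

    @property
    def context_sequence(self) -> str:
        """Context with the ref allele substituted for the [ref/alt] site."""
        left, _, rest = self.context.partition("[")
        return left + self.ref + rest.partition("]")[2]


@dataclass
class PileupColumn:
    template_id: str
    position: int  # 1-based unpadded
    ref: str
    counts: dict  # variety -> {base: n}
    depth: int


class Pileup:
    """Per-column, per-variety base counts over a template's unpadded axis.

    Backed by a (columns, varieties, 6) count array over the base alphabet
    ``ACGTN*``; behaves as a sequence of :class:`PileupColumn`.
    """

    def __init__(self, template_id: str, ref: str, varieties: list[str],
                 counts: np.ndarray, pad_adjacent: np.ndarray):
        self.template_id = template_id
        self.ref = ref
        self.varieties = varieties
        self.counts = counts
        self.pad_adjacent = pad_adjacent

    def __len__(self) -> int:
        return len(self.ref)

    def __getitem__(self, i: int) -> PileupColumn:
        if not 0 <= i < len(self):
            raise IndexError(i)
        col = {}
        for v, variety in enumerate(self.varieties):
            d = {b: int(n) for b, n in zip(_BASES, self.counts[i, v]) if n}
            if d:
                col[variety] = d
        return PileupColumn(self.template_id, i + 1, self.ref[i], col,
                            int(self.counts[i].sum()))

    def depth(self, position: int) -> int:
        return int(self.counts[position - 1].sum())


def build_pileup(assembly: Assembly, variety_tags=None,
                 varieties=None) -> Pileup:
    """Tabulate the per-variety pileup of a (padded) assembly.

    One column per unpadded consensus position; read gap characters are
    recorded under ``*``.  Every placed read must carry a variety tag,
    either on its placement or through ``variety_tags``.
    """
    cons = np.frombuffer(assembly.padded_consensus.encode(), dtype=np.uint8)
    nonpad = cons != ord("*")
    upos = np.cumsum(nonpad) - 1  # padded index -> unpadded index
    n_cols = int(nonpad.sum())
    ref = assembly.unpadded_consensus

    tags = {}
    for p in assembly.placements:
        variety = p.variety
        if variety is None and variety_tags is not None:
            variety = variety_tags.get(p.read_id)
        if variety is None:
            raise ValueError(f"read {p.read_id!r} has no variety tag")
        tags[p.read_id] = variety
    if varieties is None:
        varieties = sorted(set(tags.values()))
    vidx = {v: i for i, v in enumerate(varieties)}

    counts = np.zeros((n_cols, len(varieties), 6), dtype=np.uint16)
    for p in assembly.placements:
        codes = _LUT[np.frombuffer(p.padded_sequence.encode(), dtype=np.uint8)]
        cols = np.arange(p.start - 1, p.start - 1 + len(codes))
        keep = nonpad[cols] & (codes >= 0)
        np.add.at(counts, (upos[cols[keep]], vidx[tags[p.read_id]],
                           codes[keep]), 1)

    # unpadded columns whose padded neighbourhood contains a pad
    pad_cols = np.where(~nonpad)[0]
    pad_adjacent = np.zeros(n_cols, dtype=bool)
    for pc in pad_cols:
        for nb in (pc - 1, pc + 1):
            if 0 <= nb < len(cons) and nonpad[nb]:
                pad_adjacent[upos[nb]] = True
    return Pileup(assembly.contig_id, ref, list(varieties), counts,
                  pad_adjacent)


# ---------------------------------------------------------------------------
# per-variety consensus and candidate calling


def variety_consensus(column: PileupColumn, min_variety_depth: int = 2) -> dict:
    """Per-variety allele, IMPURE (mixed bases) or ABSENT (too few reads)."""
    out = {}
    for variety, d in column.counts.items():
        depth = sum(d.values())
        if len(d) >= 2 and depth >= 2:
            out[variety] = IMPURE
        elif depth >= min_variety_depth:
            out[variety] = next(iter(d))
        else:
            out[variety] = ABSENT
    return out


def _variety_status(counts: np.ndarray, min_variety_depth: int):
    """Vectorized variety consensus: >=0 base code, -1 IMPURE, -2 ABSENT."""
    depth_v = counts.sum(axis=2)
    distinct = (counts > 0).sum(axis=2)
    status = np.full(depth_v.shape, -2, dtype=np.int8)
    pure = (depth_v >= min_variety_depth) & (distinct == 1)
    status[pure] = counts[pure].argmax(axis=1)
    status[(distinct >= 2) & (depth_v >= 2)] = -1
    return status


def call_candidates(pileup: Pileup, min_variety_depth: int = 2,
                    context_flank: int = 50) -> list[CandidateSnp]:
    """Call bi-allelic candidate sites from a multi-variety pileup.

    A column yields a candidate iff at least two varieties have pure
    consensus bases and at least two distinct bases occur among them.
    Ref is the template base and alt the most frequent non-ref pure base.
    Sites at or next to padded columns are flagged INDEL; a non-ACGT ref
    or a third allele among pure varieties is flagged AMBIG_REF.  Flanks
    count contiguous non-variable columns (no other candidate, no gap
    character, unanimous reads agreeing with the template).
    """
    status = _variety_status(pileup.counts, min_variety_depth)  # (U, V)
    U, V = status.shape
    pure = status >= 0
    ref_codes = _LUT[np.frombuffer(pileup.ref.encode(), dtype=np.uint8)]

    presence = np.zeros((U, 6), dtype=bool)
    for b in range(6):
        presence[:, b] = (pure & (status == b)).any(axis=1)
    n_pure = pure.sum(axis=1)
    distinct_pure = presence.sum(axis=1)
    cand_cols = np.where((n_pure >= 2) & (distinct_pure >= 2))[0]
    is_cand = np.zeros(U, dtype=bool)
    is_cand[cand_cols] = True

    # non-variable columns for flank accounting
    total = pileup.counts.sum(axis=1)  # (U, 6)
    distinct_all = (total > 0).sum(axis=1)
    col_depth = total.sum(axis=1)
    sole = total.argmax(axis=1)
    clean = (~is_cand) & (total[:, _CODE["*"]] == 0) & (distinct_all <= 1) \
        & ((col_depth == 0) | (sole == ref_codes))

    candidates: list[CandidateSnp] = []
    for u in cand_cols:
        ref = pileup.ref[u]
        var_bases = status[u]
        base_var_counts = np.bincount(var_bases[pure[u]], minlength=6)
        ref_code = _CODE.get(ref, -1)
        alt_counts = base_var_counts.copy()
        if ref_code >= 0:
            alt_counts[ref_code] = 0
        alt_code = int(alt_counts.argmax())  # argmax ties -> alphabetical
        alt = _BASES[alt_code]

        flags = set()
        if presence[u, _CODE["*"]] or pileup.pad_adjacent[u]:
            flags.add("INDEL")
        if ref not in "ACGT":
            flags.add("AMBIG_REF")
        if distinct_pure[u] > 2:
            flags.add("AMBIG_REF")  # multi-allelic site

        n_var_ref = int(base_var_counts[ref_code]) if ref_code >= 0 else 0
        n_var_alt = int(base_var_counts[alt_code])
        n_var_impure = int((status[u] == -1).sum())

        fl = 0
        j = u - 1
        while j >= 0 and clean[j]:
            fl += 1
            j -= 1
        fr = 0
        j = u + 1
        while j < U and clean[j]:
            fr += 1
            j += 1

        left = pileup.ref[max(0, u - context_flank):u]
        right = pileup.ref[u + 1:u + 1 + context_flank]
        alleles = {}
        for v, variety in enumerate(pileup.varieties):
            s = status[u, v]
            if s == -1:
                alleles[variety] = IMPURE
            elif s == -2:
                alleles[variety] = ABSENT
            else:
                alleles[variety] = _BASES[s]

        informative = n_var_ref + n_var_alt
        candidates.append(CandidateSnp(
            template_id=pileup.template_id,
            position=int(u) + 1,
            ref=ref,
            alt=alt,
            depth=int(col_depth[u]),
            variety_alleles=alleles,
            n_var_ref=n_var_ref,
            n_var_alt=n_var_alt,
            n_var_impure=n_var_impure,
            maf_pred=predict_maf(n_var_alt, informative) if informative else 0.0,
            flank_left=fl,
            flank_right=fr,
            flags=frozenset(flags),
            context=f"{left}[{ref}/{alt}]{right}",
        ))
    return candidates


def predict_maf(n_differing: int, n_total: int) -> float:
    """Predicted minor-allele frequency from the differing-variety count.

    The raw fraction is folded at 0.5 so the value is always the *minor*
    allele's frequency: 6 differing varieties out of 20 surveyed gives 0.30.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_differing <= n_total:
        raise ValueError("n_differing outside [0, n_total]")
    f = n_differing / n_total
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# filter ledgers


def filter_sta(candidates, min_depth: int = 5):
    """Single-template filter ledger: total read depth and varietal purity.

    Flags DEPTH below ``min_depth`` total reads and HET_WITHIN_VARIETY when
    any variety is a within-variety base mixture; INDEL and AMBIG_REF come
    pre-computed from calling.  Records are flagged, never removed.
    """
    out = []
    for c in candidates:
        flags = []
        if c.depth < min_depth:
            flags.append("DEPTH")
        if c.n_var_impure >= 1:
            flags.append("HET_WITHIN_VARIETY")
        out.append(c.with_flags(*flags) if flags else c)
    return out


def filter_cta(candidates, min_maf: float = 0.10, min_flank: int = 50):
    """Composite-template filter ledger: purity, predicted MAF, flanks."""
    out = []
    for c in candidates:
        flags = []
        if c.n_var_impure >= 1:
            flags.append("HET_WITHIN_VARIETY")
        if c.maf_pred < min_maf:
            flags.append("LOW_MAF")
        if c.flank_left < min_flank or c.flank_right < min_flank:
            flags.append("SHORT_FLANK")
        out.append(c.with_flags(*flags) if flags else c)
    return out


def surrogate_design_score(candidate: CandidateSnp,
                           neighbor_within: int = 20,
                           has_neighbor: bool | None = None) -> float:
    """Documented stand-in for a proprietary assay design score.

    score = 1 - 0.5 * (ambiguous bases in context) / (context length)
              - 0.3 * [GC outside 0.25-0.75]
              - 0.2 * [another candidate within ``neighbor_within`` bp]
    """
    seq = candidate.context_sequence
    if not seq:
        return 0.0
    ambiguous = sum(1 for ch in seq if ch not in "ACGT")
    gc = sum(1 for ch in seq if ch in "GC") / len(seq)
    score = 1.0 - 0.5 * ambiguous / len(seq)
    if not 0.25 <= gc <= 0.75:
        score -= 0.3
    if has_neighbor:
        score -= 0.2
    return max(0.0, score)


def score_filter(candidates, scores=None, min_score: float = 0.8,
                 neighbor_within: int = 20):
    """Flag LOW_SCORE unless the design score strictly exceeds ``min_score``.

    External scores (mapping candidate id -> score) always take precedence;
    otherwise the documented surrogate is computed.
    """
    candidates = list(candidates)
    positions: dict[str, list[int]] = {}
    for c in candidates:
        positions.setdefault(c.template_id, []).append(c.position)
    out = []
    for c in candidates:
        if scores is not None and c.id in scores:
            score = float(scores[c.id])
        else:
            neighbor = any(0 < abs(p - c.position) <= neighbor_within
                           for p in positions[c.template_id])
            score = surrogate_design_score(c, neighbor_within, neighbor)
        c = dataclasses.replace(c, design_score=score)
        if score <= min_score:
            c = c.with_flags("LOW_SCORE")
        out.append(c)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def redundant_clusters(candidates, identity: float = 0.95,
                       min_cover: int = 90) -> list[list[int]]:
    """Single-linkage clusters of candidates with near-identical contexts.

    Two candidates are linked when their flanking contexts align (either
    strand) at >= ``identity`` over >= ``min_cover`` aligned columns.
    Returns index clusters over the input order.
    """
    candidates = list(candidates)
    seqs = [c.context_sequence for c in candidates]
    uf = _UnionFind(len(seqs))
    # k-mer prefilter keeps this near-linear on non-redundant sets
    kindex: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        for variant in (s, _align.revcomp(s)):
            for km, _ in _align.kmers(variant):
                kindex.setdefault(km, []).append(i)
    pairs = set()
    for hits in kindex.values():
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                if hits[a] != hits[b]:
                    pairs.add((min(hits[a], hits[b]), max(hits[a], hits[b])))
    for i, j in sorted(pairs):
        if uf.find(i) == uf.find(j):
            continue
        aln = _align.overlap_align(seqs[i], seqs[j], both_strands=True)
        if aln and aln.columns >= min_cover and aln.identity >= identity:
            uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        clusters.setdefault(uf.find(i), []).append(i)
    return sorted(clusters.values())


def remove_redundant(candidates, identity: float = 0.95,
                     min_cover: int = 90):
    """Flag all but the best member of each redundant-context cluster.

    The kept member has the highest predicted MAF (ties: lowest id); the
    rest are flagged REDUNDANT.
    """
    candidates = list(candidates)
    out = list(candidates)
    for cluster in redundant_clusters(candidates, identity, min_cover):
        if len(cluster) < 2:
            continue
        keep = min(cluster,
                   key=lambda i: (-candidates[i].maf_pred, candidates[i].id))
        for i in cluster:
            if i != keep:
                out[i] = candidates[i].with_flags("REDUNDANT")
    return out


def rank_select(candidates, k: int | None = None):
    """PASS candidates sorted by predicted MAF descending.

    Ties break by depth descending then id ascending; the first ``k`` are
    returned (the whole pool when ``k`` exceeds it).
    """
    pool = [c for c in candidates if c.passed]
    pool.sort(key=lambda c: (-c.maf_pred, -c.depth, c.id))
    return pool if k is None else pool[:k]


# ---------------------------------------------------------------------------
# end-to-end pipelines


@dataclass
class DiscoveryResult:
    templates: list[Assembly]
    candidates: list[CandidateSnp]
    panel: list[str] = field(default_factory=list)

    @property
    def passing(self):
        return [c for c in self.candidates if c.passed]


def _group_by_variety(reads) -> dict[str, list]:
    groups: dict[str, list] = {}
    for r in reads:
        groups.setdefault(r.variety, []).append(r)
    return groups


def cta_discover(reads, params: AssemblyParams | None = None,
                 min_variety_depth: int = 2, min_maf: float = 0.10,
                 min_flank: int = 50, min_fragment: int = 40,
                 both_strands: bool = False) -> DiscoveryResult:
    """Composite-template SNP discovery.

    Within each variety, reads are assembled at high stringency and the
    contigs condensed to their concordant depth>2 cores; fragments from all
    varieties are then assembled into composite templates at relaxed
    stringency, the original reads are competitively re-placed on the
    composites, and candidates are called and run through the composite
    filter ledger (purity, MAF, flank length).
    """
    params = params or AssemblyParams()
    fragments: list = []
    groups = _group_by_variety(reads)
    for variety in sorted(groups):
        contigs = assemble_greedy(
            groups[variety],
            identity=params.within_variety_identity,
            min_overlap=params.min_overlap,
            both_strands=both_strands,
            contig_prefix=f"{variety}_c",
        )
        for contig in contigs:
            fragments.extend(condense_contig(contig, min_fragment))
    composites = composite_assemble(
        fragments, identity=params.composite_identity,
        min_overlap=params.min_overlap, both_strands=both_strands)
    placed = place_reads_multi(
        composites, reads,
        placement_identity=params.placement_identity,
        placement_min_cover=params.placement_min_cover,
        both_strands=both_strands,
    )
    panel = sorted({r.variety for r in reads})
    candidates: list[CandidateSnp] = []
    for assembly in placed:
        if not assembly.placements:
            continue
        pileup = build_pileup(assembly, varieties=panel)
        candidates.extend(call_candidates(pileup, min_variety_depth))
    candidates = filter_cta(candidates, min_maf=min_maf, min_flank=min_flank)
    return DiscoveryResult(placed, candidates, panel)


def sta_discover(reads, reference_varieties, params: AssemblyParams | None = None,
                 min_variety_depth: int = 2, min_depth: int = 5,
                 both_strands: bool = False) -> DiscoveryResult:
    """Single-template SNP discovery against per-variety reference assemblies.

    Each reference variety's reads are assembled at high stringency; all
    panel reads are competitively mapped back onto each reference; sites
    are called per reference and run through the single-template ledger
    (depth, purity); candidates are unioned across references with
    redundancy removal.
    """
    params = params or AssemblyParams()
    groups = _group_by_variety(reads)
    panel = sorted(groups)
    all_templates: list[Assembly] = []
    candidates: list[CandidateSnp] = []
    for ref_variety in reference_varieties:
        if ref_variety not in groups:
            raise ValueError(f"no reads for reference variety {ref_variety!r}")
        reference = assemble_greedy(
            groups[ref_variety],
            identity=params.within_variety_identity,
            min_overlap=params.min_overlap,
            both_strands=both_strands,
            contig_prefix=f"{ref_variety}_ref",
        )
        placed = place_reads_multi(
            reference, reads,
            placement_identity=params.placement_identity,
            placement_min_cover=params.placement_min_cover,
            both_strands=both_strands,
        )
        all_templates.extend(placed)
        for assembly in placed:
            if not assembly.placements:
                continue
            pileup = build_pileup(assembly, varieties=panel)
            candidates.extend(
                filter_sta(call_candidates(pileup, min_variety_depth),
                           min_depth=min_depth))
    candidates = remove_redundant(candidates)
    return DiscoveryResult(all_templates, candidates, panel)
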