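"""Greedy overlap-consensus assembly and read placement.

A desk-scale surrogate for the commercial assemblers/mappers used in
polyploid SNP pipelines: reads are processed longest-first and joined to
an existing contig when their best gapped overlap reaches the identity
threshold over a minimum overlap (gaps count as mismatches); the consensus
is the column-wise majority with alphabetical tie-break.  Two identity
tiers drive the composite-template pipeline: a high within-variety
stringency (default 0.98) that keeps homoeologous subgenome copies in
separate contigs, and a relaxed cross-variety stringency (default 0.90)
that merges the same locus across varieties into one composite template.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from .formats import Assembly, Placement, Read

_CONSENSUS_ORDER = {c: i for i, c in enumerate("ACGTN*")}


@dataclass
class AssemblyParams:
    within_variety_identity: float = 0.98
    composite_identity: float = 0.90
    min_overlap: int = 40
    placement_identity: float = 0.90
    placement_min_cover: float = 0.80

    def __post_init__(self) -> None:
        for name in ("within_variety_identity", "composite_identity",
                     "placement_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def _majority(counts: dict[str, int]) -> str:
    return min(counts, key=lambda c: (-counts[c], _CONSENSUS_ORDER[c]))


class _Contig:
    """Padded multiple alignment built incrementally from pairwise overlaps."""

    def __init__(self, contig_id: str, fixed_consensus: str | None = None):
        self.contig_id = contig_id
        self.fixed = fixed_consensus is not None
        self.counts: list[dict[str, int]] = []
        self.consensus: list[str] = []
        # (read_id, start0, chars, reverse, variety)
        self.reads: list[tuple[str, int, list[str], bool, str | None]] = []
        self._cache: tuple[str, dict, list[int]] | None = None
        if fixed_consensus is not None:
            self.consensus = list(fixed_consensus)
            self.counts = [{} for _ in self.consensus]

    # -- consensus bookkeeping ------------------------------------------

    def _touch(self) -> None:
        self._cache = None

    def _bump(self, col: int, ch: str) -> None:
        d = self.counts[col]
        d[ch] = d.get(ch, 0) + 1
        if not self.fixed:
            self.consensus[col] = _majority(d)

    def target(self):
        """(unpadded consensus, k-mer index, unpadded->padded map), cached."""
        if self._cache is None:
            pad_of = [i for i, c in enumerate(self.consensus) if c != "*"]
            unpadded = "".join(self.consensus[i] for i in pad_of)
            self._cache = (unpadded, _align.index_sequence(unpadded), pad_of)
        return self._cache

    def _insert_pad(self, at: int) -> None:
        self.counts.insert(at, {})
        self.consensus.insert(at, "*")
        updated = []
        for rid, start, chars, rev, var in self.reads:
            if start >= at:
                start += 1
            elif start < at <= start + len(chars) - 1:
                chars.insert(at - start, "*")
                self.counts[at]["*"] = self.counts[at].get("*", 0) + 1
            updated.append((rid, start, chars, rev, var))
        self.reads = updated

    def _prepend(self, n: int) -> None:
        self.counts[:0] = [{} for _ in range(n)]
        self.consensus[:0] = ["N"] * n
        self.reads = [(rid, start + n, chars, rev, var)
                      for rid, start, chars, rev, var in self.reads]

    def _append(self, n: int) -> None:
        self.counts.extend({} for _ in range(n))
        self.consensus.extend("N" * n)

    # -- read addition --------------------------------------------------

    def seed(self, read: Read) -> None:
        self.counts = [{} for _ in read.sequence]
        self.consensus = list(read.sequence)
        chars = list(read.sequence)
        self.reads.append((read.id, 0, chars, False, read.variety))
        for i, ch in enumerate(chars):
            self.counts[i][ch] = 1
        self._touch()

    def try_align(self, sequence: str, both_strands: bool):
        unpadded, index, _ = self.target()
        return _align.overlap_align(unpadded, sequence,
                                    target_index=index,
                                    both_strands=both_strands)

    def add_aligned(self, read: Read, aln: _align.OverlapAlignment) -> bool:
        """Place a read according to a previously computed alignment.

        Returns False when the alignment implies a conflicting overhang
        (read extends where the contig continues); the caller then treats
        the read as unjoinable.
        """
        seq = _align.revcomp(read.sequence) if aln.reverse else read.sequence
        _, _, pad_of = self.target()
        u_len = len(pad_of)
        left_over = aln.q_start
        right_over = len(seq) - aln.q_end
        if (left_over and aln.t_start > 0) or (right_over and aln.t_end < u_len):
            return False
        if self.fixed and (left_over or right_over):
            return False

        if left_over:
            self._prepend(left_over)
            pad_of = [p + left_over for p in pad_of]
        start0 = pad_of[aln.t_start] - left_over
        chars: list[str] = []
        pcur = start0
        for ch in seq[:left_over]:
            chars.append(ch)
            self._bump(pcur, ch)
            pcur += 1
        ti, qi = aln.t_start, aln.q_start
        inserted = 0
        for n, op in aln.cigar:
            if op in "=X":
                for _ in range(n):
                    pt = pad_of[ti] + inserted
                    while pcur < pt:  # pre-existing pad columns
                        chars.append("*")
                        self._bump(pcur, "*")
                        pcur += 1
                    chars.append(seq[qi])
                    self._bump(pcur, seq[qi])
                    qi += 1
                    ti += 1
                    pcur += 1
            elif op == "D":  # read gap over consensus columns
                for _ in range(n):
                    pt = pad_of[ti] + inserted
                    while pcur <= pt:
                        chars.append("*")
                        self._bump(pcur, "*")
                        pcur += 1
                    ti += 1
            elif op == "I":  # read insertion: new pad column in consensus
                for _ in range(n):
                    self._insert_pad(pcur)
                    chars.append(seq[qi])
                    self._bump(pcur, seq[qi])
                    qi += 1
                    inserted += 1
                    pcur += 1
        if right_over:
            need = pcur + right_over - len(self.consensus)
            if need > 0:
                self._append(need)
            for ch in seq[aln.q_end:]:
                chars.append(ch)
                self._bump(pcur, ch)
                pcur += 1
        self.reads.append((read.id, start0, chars, aln.reverse, read.variety))
        self._touch()
        return True

    def to_assembly(self) -> Assembly:
        placements = [
            Placement(rid, start + 1, "".join(chars), reverse=rev, variety=var)
            for rid, start, chars, rev, var in self.reads
        ]
        return Assembly(self.contig_id, "".join(self.consensus), placements)


# ---------------------------------------------------------------------------


def _canonical(reads) -> list[Read]:
    return sorted(reads, key=lambda r: (-len(r.sequence), r.id))


class _CandidateIndex:
    """k-mer -> contig ids, used to shortlist join candidates."""

    def __init__(self, k: int = _align.DEFAULT_K):
        self.k = k
        self.index: dict[str, set[int]] = {}

    def add(self, sequence: str, contig_no: int) -> None:
        for km, _ in _align.kmers(sequence, self.k):
            self.index.setdefault(km, set()).add(contig_no)

    def candidates(self, sequence: str, both_strands: bool,
                   limit: int = 4) -> list[int]:
        tally: dict[int, int] = {}
        seqs = [sequence]
        if both_strands:
            seqs.append(_align.revcomp(sequence))
        for s in seqs:
            for km, _ in _align.kmers(s, self.k):
                for cid in self.index.get(km, ()):
                    tally[cid] = tally.get(cid, 0) + 1
        ranked = sorted(tally, key=lambda c: (-tally[c], c))
        return ranked[:limit]


def assemble_greedy(reads, identity: float = 0.98, min_overlap: int = 40,
                    both_strands: bool = True,
                    contig_prefix: str = "c") -> list[Assembly]:
    """Greedy overlap-layout-consensus assembly.

    Reads are processed in canonical order (length descending, then id) so
    the result is invariant to input permutation.  A read joins the contig
    with the best-matching overlap whose identity reaches the threshold
    over at least ``min_overlap`` aligned columns; otherwise it seeds a new
    contig.  Every read is placed exactly once.
    """
    contigs: list[_Contig] = []
    cindex = _CandidateIndex()
    for read in _canonical(reads):
        placed = False
        best: tuple[_align.OverlapAlignment, int] | None = None
        for cno in cindex.candidates(read.sequence, both_strands):
            aln = contigs[cno].try_align(read.sequence, both_strands)
            if aln is None or aln.columns < min_overlap:
                continue
            if aln.identity < identity:
                continue
            if best is None or aln.matches > best[0].matches:
                best = (aln, cno)
        if best is not None:
            aln, cno = best
            placed = contigs[cno].add_aligned(read, aln)
            if placed:
                cindex.add(read.sequence, cno)
        if not placed:
            contig = _Contig(f"{contig_prefix}{len(contigs):05d}")
            contig.seed(read)
            contigs.append(contig)
            cindex.add(read.sequence, len(contigs) - 1)
    return [c.to_assembly() for c in contigs]


# ---------------------------------------------------------------------------
# condensation (composite-template pipeline step)


def condense_contig(assembly: Assembly, min_length: int = 40) -> list[Read]:
    """Trim a contig to its well-supported, fully concordant regions.

    Output fragments are the maximal runs of unpadded consensus columns
    where the spanning-read depth is strictly greater than two and every
    covering read agrees with the consensus base; runs shorter than
    ``min_length`` are dropped.  Fragments keep the variety tag of the
    source contig's reads (within-variety assembly).
    """
    cons = assembly.padded_consensus
    n = len(cons)
    depth = [0] * n
    discord = [0] * n
    for p in assembly.placements:
        s0 = p.start - 1
        for off, ch in enumerate(p.padded_sequence):
            col = s0 + off
            depth[col] += 1
            if ch != cons[col]:
                discord[col] += 1

    varieties = {p.variety for p in assembly.placements if p.variety}
    variety = varieties.pop() if len(varieties) == 1 else None

    fragments: list[Read] = []
    run: list[str] = []
    run_start: int | None = None  # 1-based unpadded
    upos = 0

    def _flush():
        nonlocal run, run_start
        if run and len(run) >= min_length:
            fragments.append(Read(
                f"{assembly.contig_id}:{run_start}-{run_start + len(run) - 1}",
                variety if variety is not None else "",
                "".join(run),
            ))
        run, run_start = [], None

    for col, ch in enumerate(cons):
        if ch == "*":
            continue
        upos += 1
        if depth[col] > 2 and discord[col] == 0:
            if not run:
                run_start = upos
            run.append(ch)
        else:
            _flush()
    _flush()
    return fragments


def composite_assemble(fragments_by_variety, identity: float = 0.90,
                       min_overlap: int = 40,
                       both_strands: bool = True) -> list[Assembly]:
    """Cross-variety composite assembly of condensed fragments.

    Accepts either a mapping variety -> fragments or a flat fragment list;
    fragments retain their variety tags and the same greedy contract as
    ``assemble_greedy`` applies at the relaxed identity tier.
    """
    if isinstance(fragments_by_variety, dict):
        pool = [f for frags in fragments_by_variety.values() for f in frags]
    else:
        pool = list(fragments_by_variety)
    return assemble_greedy(pool, identity=identity, min_overlap=min_overlap,
                           both_strands=both_strands, contig_prefix="comp")


# ---------------------------------------------------------------------------
# read placement


def _template_of(template) -> tuple[str, str]:
    if isinstance(template, Assembly):
        return template.contig_id, template.unpadded_consensus
    if isinstance(template, Read):
        return template.id, template.sequence
    return "template", str(template)


def _accept(aln, read, identity, min_cover):
    return (aln is not None and aln.identity >= identity
            and aln.query_cover >= min_cover * len(read.sequence))


def place_reads(template, reads, placement_identity: float = 0.90,
                placement_min_cover: float = 0.80,
                both_strands: bool = True) -> Assembly:
    """Map reads onto a single fixed template (non-competitive).

    Each read is placed at its best-scoring gapped alignment when identity
    reaches ``placement_identity`` over at least ``placement_min_cover`` of
    its length; otherwise it is left out.  Read ends overhanging the
    template are clipped from the placement.  Ties break leftmost, then
    forward orientation.
    """
    tid, consensus = _template_of(template)
    if not consensus:
        raise ValueError("empty template")
    contig = _Contig(tid, fixed_consensus=consensus)
    index = _align.index_sequence(consensus)
    for read in _canonical(reads):
        aln = _best_placement(consensus, index, read, both_strands)
        if _accept(aln, read, placement_identity, placement_min_cover):
            _add_clipped(contig, read, aln)
    return contig.to_assembly()


def _best_placement(consensus, index, read, both_strands):
    """Best alignment of a read on a template; leftmost-then-forward ties."""
    best = None
    candidates = [(read.sequence, False)]
    if both_strands:
        candidates.append((_align.revcomp(read.sequence), True))
    for seq, rev in candidates:
        d = _align.best_diagonal(index, seq)
        if d is None:
            continue
        aln = _align.align_window(consensus, seq, d, reverse=rev)
        if aln is None:
            continue
        key = (-aln.matches, aln.t_start, rev)
        if best is None or key < best[0]:
            best = (key, aln)
    return best[1] if best else None


def _add_clipped(contig: _Contig, read: Read, aln) -> None:
    """Place only the aligned portion of the read (soft-clip overhangs)."""
    seq = _align.revcomp(read.sequence) if aln.reverse else read.sequence
    clipped = Read(read.id, read.variety, seq[aln.q_start:aln.q_end])
    sub = _align.OverlapAlignment(
        aln.t_start, aln.t_end, 0, aln.q_end - aln.q_start,
        aln.cigar, aln.matches, aln.columns, aln.reverse)
    contig.add_aligned(
        Read(read.id, read.variety,
             _align.revcomp(clipped.sequence) if aln.reverse
             else clipped.sequence),
        sub,
    )


def place_reads_multi(templates, reads, placement_identity: float = 0.90,
                      placement_min_cover: float = 0.80,
                      both_strands: bool = True,
                      max_candidates: int = 3) -> list[Assembly]:
    """Competitively map each read to its best template among many.

    This is the mapper role of the SNP pipelines: the read goes to the
    single template with the best-matching alignment (ties: first template
    in input order), subject to the same identity/cover acceptance rule as
    ``place_reads``.
    """
    entries = [_template_of(t) for t in templates]
    cindex = _CandidateIndex()
    consensi: list[str] = []
    indexes: list[dict] = []
    for i, (_, cons) in enumerate(entries):
        if not cons:
            raise ValueError("empty template")
        cindex.add(cons, i)
        consensi.append(cons)
        indexes.append(_align.index_sequence(cons))
    contigs = [_Contig(tid, fixed_consensus=cons) for tid, cons in entries]
    for read in _canonical(reads):
        best = None
        for tno in cindex.candidates(read.sequence, both_strands,
                                     limit=max_candidates):
            aln = _best_placement(consensi[tno], indexes[tno], read,
                                  both_strands)
            if not _accept(aln, read, placement_identity, placement_min_cover):
                continue
            key = (-aln.matches, tno)
            if best is None or key < best[0]:
                best = (key, tno, aln)
        if best is not None:
            _, tno, aln = best
            _add_clipped(contigs[tno], read, aln)
    return [c.to_assembly() for c in contigs]
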