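"""Truth-table recovery measurements shared by unit and acceptance tests.

These helpers locate planted SNPs on assembled templates by aligning the
true copy sequence to the template consensus, then score eligibility and
recall from the realized pileup.  They consume simulator truth only in
assertions, never inside the pipeline under test.
"""

from __future__ import annotations

import collections

from oatkit import _align
from oatkit.assembly import _CandidateIndex, assemble_greedy, place_reads
from oatkit.snp_discovery import build_pileup, call_candidates, filter_sta


def _origin_copy(read_id: str) -> str:
    """Simulator read ids encode their origin as variety.copy.n"""
    return read_id.split(".")[1]


def map_position(aln: _align.OverlapAlignment, q_pos0: int) -> int | None:
    """Map a 0-based query position through an alignment to the target."""
    ti, qi = aln.t_start, aln.q_start
    for n, op in aln.cigar:
        if op in "=X":
            if qi <= q_pos0 < qi + n:
                return ti + (q_pos0 - qi)
            qi += n
            ti += n
        elif op == "I":
            if qi <= q_pos0 < qi + n:
                return None  # inside a query-only insertion
            qi += n
        elif op == "D":
            ti += n
    return None


def cta_recall(result, haplotypes, truth, min_variety_depth: int = 2):
    """Recall of eligible planted SNPs on composite templates.

    A planted SNP is *eligible* when, at its located composite column, at
    least two carrier varieties and two non-carrier varieties are present
    at the purity depth.  It is *recalled* when a candidate with the
    planted allele pair was called at that column.  Returns
    ``(n_eligible, n_recalled)``.
    """
    varieties = sorted(haplotypes)
    by_template = {a.contig_id: a for a in result.templates}
    candidates = collections.defaultdict(dict)
    for c in result.candidates:
        candidates[c.template_id][c.position] = c

    copy_to_comps = collections.defaultdict(collections.Counter)
    for a in result.templates:
        for p in a.placements:
            copy_to_comps[_origin_copy(p.read_id)][a.contig_id] += 1

    pileups: dict[str, object] = {}

    def _pileup(cid):
        if cid not in pileups:
            pileups[cid] = build_pileup(by_template[cid], varieties=varieties)
        return pileups[cid]

    n_eligible = n_recalled = 0
    for snp in truth.snps:
        noncarriers = [v for v in varieties if v not in snp.carriers]
        if not noncarriers:
            continue
        copy_seq = haplotypes[noncarriers[0]][snp.template]
        eligible = recalled = False
        for cid in copy_to_comps.get(snp.template, ()):  # noqa: B007
            consensus = by_template[cid].unpadded_consensus
            aln = _align.overlap_align(consensus, copy_seq)
            if aln is None or aln.identity < 0.95:
                continue
            t_col = map_position(aln, snp.position - 1)
            if t_col is None:
                continue
            pu = _pileup(cid)
            depth_v = pu.counts[t_col].sum(axis=1)
            present = {v for v, d in zip(varieties, depth_v)
                       if d >= min_variety_depth}
            n_car = len(present & snp.carriers)
            n_non = len(present - snp.carriers)
            if n_car >= 2 and n_non >= 2:
                eligible = True
                cand = candidates[cid].get(t_col + 1)
                if cand is not None and {cand.ref, cand.alt} == \
                        {snp.ref, snp.alt}:
                    recalled = True
        if eligible:
            n_eligible += 1
            n_recalled += bool(recalled)
    return n_eligible, n_recalled


def collapse_experiment(reads, haplotypes, truth, reference_variety: str,
                        placement_identity: float = 0.85):
    """Force homoeolog collapse via relaxed per-template read placement.

    Assembles the reference variety's reads at high stringency, then
    places *all* panel reads onto each reference template independently at
    the given (relaxed) identity, calls candidates, and classifies the
    false candidates that sit on homoeolog divergence columns.  Returns
    ``(n_collapse_artifacts, n_flagged_het)``.
    """
    ref_reads = [r for r in reads if r.variety == reference_variety]
    reference = assemble_greedy(ref_reads, identity=0.98, both_strands=False)
    varieties = sorted(haplotypes)

    divergence = {f.family: f.divergent_positions for f in truth.families}
    planted = collections.defaultdict(set)
    for s in truth.snps:
        planted[s.template].add(s.position)

    # non-competitive: every read sharing k-mers with a template is offered
    cindex = _CandidateIndex()
    for i, contig in enumerate(reference):
        cindex.add(contig.unpadded_consensus, i)
    offered = collections.defaultdict(list)
    for read in reads:
        for cno in cindex.candidates(read.sequence, both_strands=False,
                                     limit=6):
            offered[cno].append(read)

    n_artifact = n_flagged = 0
    for cno, contig in enumerate(reference):
        copies = collections.Counter(
            _origin_copy(p.read_id) for p in contig.placements)
        if not copies:
            continue
        copy_id = copies.most_common(1)[0][0]
        family = copy_id.rsplit("_s", 1)[0]
        copy_seq = haplotypes[reference_variety][copy_id]
        placed = place_reads(contig, offered.get(cno, []),
                             placement_identity=placement_identity,
                             both_strands=False)
        if not placed.placements:
            continue
        pileup = build_pileup(placed, varieties=varieties)
        calls = filter_sta(call_candidates(pileup))
        aln = _align.overlap_align(copy_seq, placed.unpadded_consensus)
        if aln is None:
            continue
        for cand in calls:
            copy_pos0 = map_position(aln, cand.position - 1)
            if copy_pos0 is None:
                continue
            pos = copy_pos0 + 1
            if pos in planted[copy_id]:
                continue  # a true planted SNP, not an artifact
            if pos in divergence[family]:
                n_artifact += 1
                n_flagged += "HET_WITHIN_VARIETY" in cand.flags
    return n_artifact, n_flagged
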