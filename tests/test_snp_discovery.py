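"""Candidate calling, MAF prediction, filter ledgers and selection."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oatkit import snp_discovery as sd
from oatkit.formats import Assembly, Placement
from oatkit.snp_discovery import (CandidateSnp, PileupColumn, build_pileup,
                                  call_candidates, filter_cta, filter_sta,
                                  predict_maf, rank_select, remove_redundant,
                                  score_filter, variety_consensus)


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _panel_assembly(template: str, site0: int, carriers: int = 6,
                    total: int = 20, alt: str = "C",
                    reads_per_variety: int = 2) -> Assembly:
    """All varieties tiled full-length; carriers differ at one column."""
    placements = []
    for v in range(total):
        seq = template
        if v < carriers:
            seq = template[:site0] + alt + template[site0 + 1:]
        for k in range(reads_per_variety):
            placements.append(
                Placement(f"v{v:02d}.r{k}", 1, seq, variety=f"v{v:02d}"))
    return Assembly("tpl", template, placements)


# -- pileup -----------------------------------------------------------------


def test_pileup_counts_and_depth():
    asm = Assembly("t", "CT", [
        Placement("x1", 1, "CT", variety="X"),
        Placement("x2", 1, "CT", variety="X"),
        Placement("y1", 1, "TT", variety="Y"),
    ])
    pu = build_pileup(asm)
    col = pu[0]
    assert col.counts == {"X": {"C": 2}, "Y": {"T": 1}}
    assert col.depth == 3


def test_pileup_excludes_padded_columns():
    asm = Assembly("t", "AC*GT", [Placement("r", 1, "AC*GT", variety="X")])
    pu = build_pileup(asm)
    assert len(pu) == 4
    assert pu.ref == "ACGT"
    assert pu.pad_adjacent.tolist() == [False, True, True, False]


def test_pileup_depths_match_bruteforce_span_count():
    rng = random.Random(0)
    tpl = _random_seq(rng, 120)
    placements = []
    for i in range(20):
        s = rng.randrange(0, 80)
        ln = rng.randrange(20, 40)
        placements.append(
            Placement(f"r{i}", s + 1, tpl[s:s + ln], variety=f"v{i % 4}"))
    asm = Assembly("t", tpl, placements)
    pu = build_pileup(asm)
    for col in range(120):
        brute = sum(1 for p in placements
                    if p.start <= col + 1 <= p.end)
        assert pu.depth(col + 1) == brute


def test_pileup_requires_variety_tags():
    asm = Assembly("t", "ACGT", [Placement("r", 1, "ACGT")])
    with pytest.raises(ValueError, match="variety"):
        build_pileup(asm)


# -- variety consensus ------------------------------------------------------


@pytest.mark.parametrize("counts,expected", [
    ({"C": 3}, "C"),
    ({"C": 2, "T": 1}, sd.IMPURE),
    ({"C": 1}, sd.ABSENT),
    ({"*": 2}, "*"),
])
def test_variety_consensus_rules(counts, expected):
    col = PileupColumn("t", 1, "C", {"v": counts}, sum(counts.values()))
    assert variety_consensus(col)["v"] == expected


# -- candidate calling ------------------------------------------------------


def test_call_candidates_basic_construction():
    rng = random.Random(1)
    tpl = _random_seq(rng, 200)
    site0 = 99
    tpl = tpl[:site0] + "T" + tpl[site0 + 1:]
    asm = _panel_assembly(tpl, site0, carriers=6, total=20, alt="C")
    (cand,) = call_candidates(build_pileup(asm))
    assert (cand.position, cand.ref, cand.alt) == (100, "T", "C")
    assert (cand.n_var_ref, cand.n_var_alt) == (14, 6)
    assert cand.depth == 40
    assert cand.maf_pred == pytest.approx(0.30)
    assert cand.passed
    assert cand.flank_left == 99 and cand.flank_right == 100


def test_call_candidates_flags_indel_near_pad():
    tpl = "ACGTT" + "A" * 60
    carriers, others = "v00 v01".split(), [f"v{i:02d}" for i in range(2, 6)]
    placements = []
    padded = tpl[:3] + "*" + tpl[3:]
    for v in carriers:
        seq = padded[:6] + "C" + padded[7:]  # alt at unpadded position 6
        placements += [Placement(f"{v}.{k}", 1, seq, variety=v)
                       for k in range(2)]
    for v in others:
        placements += [Placement(f"{v}.{k}", 1, padded, variety=v)
                       for k in range(2)]
    asm = Assembly("t", padded, placements)
    (cand,) = call_candidates(build_pileup(asm))
    assert cand.position == 6
    assert "INDEL" not in cand.flags  # pad not adjacent to site 6
    # move the variant next to the pad: column 4 neighbours the '*'
    placements2 = []
    for v in carriers:
        seq = padded[:4] + "C" + padded[5:]
        placements2 += [Placement(f"{v}.{k}", 1, seq, variety=v)
                        for k in range(2)]
    for v in others:
        placements2 += [Placement(f"{v}.{k}", 1, padded, variety=v)
                        for k in range(2)]
    (cand2,) = call_candidates(build_pileup(Assembly("t", padded, placements2)))
    assert "INDEL" in cand2.flags


def test_call_candidates_third_allele_is_ambiguous():
    rng = random.Random(2)
    tpl = _random_seq(rng, 120)
    site0 = 60
    tpl = tpl[:site0] + "T" + tpl[site0 + 1:]
    placements = []
    for v, base in (("v1", "T"), ("v2", "T"), ("v3", "C"), ("v4", "G")):
        seq = tpl[:site0] + base + tpl[site0 + 1:]
        placements += [Placement(f"{v}.{k}", 1, seq, variety=v)
                       for k in range(2)]
    (cand,) = call_candidates(build_pileup(Assembly("t", tpl, placements)))
    assert "AMBIG_REF" in cand.flags


def test_cta_recall_on_simulated_panel(tiny_config, tiny_panel, tiny_reads):
    from _recovery import cta_recall

    haplotypes, truth = tiny_panel
    result = sd.cta_discover(tiny_reads)
    n_eligible, n_recalled = cta_recall(result, haplotypes, truth)
    assert n_eligible >= 5
    assert n_recalled >= 0.8 * n_eligible  # full-scale bar lives in acceptance


# -- predicted MAF ----------------------------------------------------------


@pytest.mark.parametrize("d,n,expected", [(6, 20, 0.30), (0, 20, 0.0),
                                          (15, 20, 0.25)])
def test_predict_maf_examples(d, n, expected):
    assert predict_maf(d, n) == pytest.approx(expected)


@given(n=st.integers(1, 200), d=st.integers(0, 200))
def test_predict_maf_folded_and_symmetric(n, d):
    d = min(d, n)
    value = predict_maf(d, n)
    assert 0.0 <= value <= 0.5
    assert value == pytest.approx(predict_maf(n - d, n))


def test_predict_maf_rejects_bad_input():
    with pytest.raises(ValueError):
        predict_maf(1, 0)
    with pytest.raises(ValueError):
        predict_maf(5, 4)


# -- filters ----------------------------------------------------------------


def _cand(**kw):
    base = dict(template_id="t", position=100, ref="T", alt="C", depth=10,
                variety_alleles={}, n_var_ref=10, n_var_alt=5,
                n_var_impure=0, maf_pred=0.33, flank_left=60, flank_right=60,
                context="A" * 50 + "[T/C]" + "G" * 50)
    base.update(kw)
    return CandidateSnp(**base)


def test_filter_sta_depth_boundary_and_purity():
    cands = [_cand(depth=4), _cand(depth=5), _cand(n_var_impure=1)]
    out = filter_sta(cands)
    assert "DEPTH" in out[0].flags
    assert out[1].passed
    assert "HET_WITHIN_VARIETY" in out[2].flags
    assert filter_sta(out) == out  # idempotent


def test_filter_cta_boundaries():
    cands = [_cand(maf_pred=0.09), _cand(maf_pred=0.10),
             _cand(flank_left=49, flank_right=120),
             _cand(flank_left=50, flank_right=50)]
    out = filter_cta(cands)
    assert "LOW_MAF" in out[0].flags and out[1].passed
    assert "SHORT_FLANK" in out[2].flags and out[3].passed
    assert filter_cta(out) == out


def test_filters_are_monotone_and_preserve_records():
    cands = [_cand(depth=4, maf_pred=0.05), _cand()]
    out = filter_cta(filter_sta(cands))
    assert len(out) == len(cands)
    assert out[0].flags >= filter_sta(cands)[0].flags


def test_score_filter_strict_threshold_and_surrogate():
    ext = {_cand().id: 0.80}
    (flagged,) = score_filter([_cand()], scores=ext)
    assert "LOW_SCORE" in flagged.flags
    (clean,) = score_filter([_cand()], scores={_cand().id: 0.81})
    assert clean.passed and clean.design_score == 0.81
    # clean 101-bp context, GC 0.5, no neighbours -> surrogate 1.0
    ctx = ("AT" * 25) + "[G/C]" + ("GC" * 25)
    (surr,) = score_filter([_cand(context=ctx, ref="G", alt="C")])
    assert surr.design_score == pytest.approx(1.0)
    assert surr.passed
    again = score_filter([surr], scores=None)
    assert again[0].flags == surr.flags


def test_surrogate_penalizes_neighbors_and_gc():
    a = _cand(position=100)
    b = _cand(position=110)
    out = score_filter([a, b])
    assert all(c.design_score == pytest.approx(0.8) for c in out)
    assert all("LOW_SCORE" in c.flags for c in out)
    gc_ctx = "G" * 50 + "[G/C]" + "C" * 50
    (gc,) = score_filter([_cand(context=gc_ctx, ref="G", alt="C")])
    assert gc.design_score == pytest.approx(0.7)


# -- redundancy -------------------------------------------------------------


def test_remove_redundant_keeps_highest_maf():
    rng = random.Random(3)
    ctx_seq = _random_seq(rng, 50) + "T" + _random_seq(rng, 50)
    ctx = ctx_seq[:50] + "[T/C]" + ctx_seq[51:]
    a = _cand(template_id="a", maf_pred=0.3, context=ctx)
    b = _cand(template_id="b", maf_pred=0.2, context=ctx)
    out = remove_redundant([a, b])
    assert out[0].passed
    assert "REDUNDANT" in out[1].flags


def test_remove_redundant_ignores_diverged_contexts():
    rng = random.Random(4)
    s1 = _random_seq(rng, 101)
    s2 = "".join(rng.choice([c for c in "ACGT" if c != ch])
                 if rng.random() < 0.2 else ch for ch in s1)
    a = _cand(template_id="a", context=s1[:50] + "[T/C]" + s1[51:])
    b = _cand(template_id="b", context=s2[:50] + "[T/C]" + s2[51:])
    assert all(c.passed for c in remove_redundant([a, b]))


def _bruteforce_clusters(cands, identity=0.95, min_cover=90):
    """All-pairs full-DP transitive closure (Bio.Align as independent path)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    n = len(cands)
    adj = [[False] * n for _ in range(n)]
    from oatkit._align import revcomp
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = cands[i].context_sequence, cands[j].context_sequence
            for q in (sj, revcomp(sj)):
                aln = aligner.align(si, q)[0]
                cols = matches = 0
                for (ts, te), (qs, qe) in zip(*aln.aligned):
                    cols += te - ts
                    matches += sum(si[ts + k] == q[qs + k]
                                   for k in range(te - ts))
                if cols >= min_cover and matches / cols >= identity:
                    adj[i][j] = adj[j][i] = True
    seen, clusters = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(v for v in range(n) if adj[u][v])
        clusters.append(sorted(comp))
    return sorted(clusters)


def test_redundancy_clustering_matches_bruteforce():
    rng = random.Random(5)
    cands = []
    for c in range(6):  # six seed contexts, ~5 mutated variants each
        seed_seq = _random_seq(rng, 101)
        for k in range(5):
            seq = "".join(rng.choice("ACGT") if rng.random() < 0.02 else ch
                          for ch in seed_seq)
            ctx = seq[:50] + f"[{seq[50]}/C]" + seq[51:]
            cands.append(_cand(template_id=f"c{c}k{k}", ref=seq[50],
                               context=ctx))
    ours = sd.redundant_clusters(cands)
    brute = _bruteforce_clusters(cands)
    assert ours == brute


# -- selection --------------------------------------------------------------


def test_rank_select_order_and_bounds():
    pool = [
        _cand(template_id="a", maf_pred=0.5, depth=10),
        _cand(template_id="b", maf_pred=0.3, depth=20),
        _cand(template_id="c", maf_pred=0.3, depth=10),
        _cand(template_id="d", maf_pred=0.1, depth=10),
        _cand(template_id="e", maf_pred=0.45, flank_left=0,
              flags=frozenset({"SHORT_FLANK"})),
    ]
    top2 = rank_select(pool, 2)
    assert [c.template_id for c in top2] == ["a", "b"]
    assert len(rank_select(pool, 99)) == 4  # PASS pool only, no error
    shuffled = list(pool)
    random.Random(7).shuffle(shuffled)
    assert rank_select(shuffled, 4) == rank_select(pool, 4)
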