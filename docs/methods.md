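# Methods

This note documents the models, algorithms and numerical choices behind
`oatkit`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## The polyploid SNP-calling model

Cultivated oat carries three diverged subgenomes (A, C, D).  Any template
built from mixed reads therefore risks *homoeolog collapse*: reads from two
subgenome copies stack on one template and their fixed differences imitate
SNPs.  The calling model used throughout the toolkit neutralizes this with
a within-variety purity rule.  For a pileup column, each variety's reads
are summarized as

- a **pure base** when the variety has at least `min_variety_depth`
  (default 2) reads and a single distinct character,
- **IMPURE** when it shows two or more distinct characters at depth ≥2,
- **ABSENT** below the depth floor.

A column is a candidate SNP only when ≥2 varieties are pure and their pure
bases disagree; the template base is the reference allele and the most
frequent non-reference pure base the alternate.  The key property is that
collapse cannot masquerade as polymorphism: every variety contains both
homoeologs, so a collapsed column is a *within*-variety mixture and the
site is flagged `HET_WITHIN_VARIETY`.  True inter-varietal SNPs instead
partition the panel into pure reference and pure alternate varieties.
Purity is deliberately strict — one discordant read makes a variety
impure.  A single mis-tracked read then costs one variety's vote, not a
false call; the resulting heavy flag attrition at realistic error rates is
intended behaviour, with candidates retained and flagged rather than
deleted so attrition accounting falls out of flag counts.

Predicted minor-allele frequency is the differing-variety fraction folded
at 0.5: `predict_maf(d, n) = min(d/n, 1 - d/n)`.  For called candidates
the denominator is the number of varieties with a pure call at the site;
the classic worked case (6 of 20 varieties → 30%) is the full-panel form.

### Filter ledgers

Single-template (STA) ledger: `DEPTH` (total pileup depth <5),
`HET_WITHIN_VARIETY`, `INDEL` (a pure variety consensus of `*`, or the
column is adjacent to a padded column), `AMBIG_REF` (non-ACGT reference or
a third allele among pure varieties).  Composite-template (CTA) ledger:
`HET_WITHIN_VARIETY`, `LOW_MAF` (<0.10), `SHORT_FLANK` (<50 non-variable
bases on either side, where non-variable means: not itself a candidate, no
gap character, and unanimous reads agreeing with the template).  The
design-score filter keeps scores strictly >0.8; external scores always
take precedence over the built-in surrogate

```
score = 1 - 0.5*(ambiguous bases)/(context length)
          - 0.3*[GC outside 0.25-0.75]
          - 0.2*[another candidate within 20 bp]
```

which stands in for a proprietary assay-design metric and exists so the
ledger is runnable end-to-end.  Redundancy is flagged by single-linkage
clustering of flank contexts that align (either strand) at ≥0.95 identity
over ≥90 columns, keeping the highest-MAF member per cluster (tie: lowest
id).  Selection sorts PASS candidates by predicted MAF descending (ties:
depth descending, id ascending).

Flags are monotone — a later stage never clears an earlier flag — and
`PASS` is derived (no flags), so filters commute with re-application
(idempotent).

## Assembly surrogate

The production assemblers of such pipelines are replaced by a greedy
overlap-layout-consensus assembler whose *thresholds* are the semantic
contract: 0.98 overlap identity within varieties (separates homoeologs),
0.90 for the cross-variety composite (merges varieties, still separates
homoeologs), 0.90/0.80 identity/cover for read placement.  Identity is
computed over the aligned columns of the best gapped overlap with gaps
counted as mismatches.  Determinism: reads are processed longest-first
(ties by id), so output is invariant to input permutation; consensus is
column-wise majority with alphabetical tie-break (`A<C<G<T<N`, pad last).

Alignment engine: shared 16-mers between read and contig vote for a
diagonal; the implied overlap window is aligned end-to-end with edlib
(unit-cost Needleman-Wunsch) and window-edge gap runs are trimmed.  This
is exact for substitution-dominated reads and tolerant of occasional
indels (the dominant segment wins the vote and the residual shift is
absorbed as trimmable end gaps); the test suite checks it against an
exhaustive all-offsets oracle and a full-DP aligner.  Reads whose
alignment implies a conflicting overhang (extension where the contig
continues) seed their own contig rather than being force-fit.

Condensation trims each within-variety contig to maximal runs of unpadded
columns with spanning depth strictly >2 and perfect read-consensus
concordance, dropping runs shorter than 40 bp.  Re-placement onto
composite templates uses the *original* reads, competitively (best
template wins), because the depth/purity tabulation needs read-level
per-variety depth; single-template `place_reads` is non-competitive and
soft-clips template overhangs.

## Linkage QC and grouping

Markers are removed for segregation distortion (allele-A share of
non-missing calls ≤0.25 or ≥0.75; H counts half) or missingness (≥10%);
the rules act independently and the report names each trigger, so either
reading of the joint criterion is recoverable.  Observed recombinant
fraction between markers is R = mismatches / non-missing homozygous pairs
(H-containing pairs excluded); the meiotic estimate r = R/(2−2R), capped
at 0.5, inverts the selfed-RIL relation R = 2r/(1+2r).  Grouping takes
connected components of the graph with edges where R ≤ threshold;
thresholds apply to observed R (what grouping software consumes), with r
reported alongside.  Components are monotone in the threshold, so the
0.15 → 0.25 ladder only ever merges groups.  Ordering within groups is
out of scope.

## Chromosome anchoring

**SNP deletion.**  Informative loci have maternal-background call A and
paternal call B.  In a monosomic F1, a B call means the maternal copy is
absent (hemizygous); H is the normal heterozygote; an A call is recorded
as a univalent-shift / disomic-reversion anomaly and never anchors.  Each
linkage group is assigned to the missing chromosome of the stock with the
strictly greatest hemizygous-locus count, provided it reaches
`min_anchors = 2` (one locus is never allowed to anchor a chromosome);
ties and under-supported groups stay UNASSIGNED with the full count table
reported.

**Dose dilution.**  A marker on the missing chromosome hybridizes at half
dose.  Per background, a representation is analyzed only when its
intensity CV ≥ 0.2 — a genuine two-dose mixture inflates the CV well past
a single log-normal's, which is exactly why the gate also suppresses
pure-noise representations.  Fuzzy c-means with k=2 (one missing homolog
halves copy number, so two doses) splits the intensities; the spec-free
notion of "signals between distribution tails" is operationalized as:
lower/upper center ratio ≤ 0.75 (separation gate) and lower-cluster
membership ≥ 0.8 (call).  All three constants are parameters.  Calls vote
group → chromosome under the same strict-max/min-anchor rule.

`FuzzyKMeans` is the standard Bezdek alternation (fuzziness m = 2,
tolerance 1e-6 on the objective decrease, ≤300 iterations, best of 5
seeded restarts); the objective Σ u^m d² is asserted non-increasing each
iteration, membership rows sum to 1, and points coincident with a center
get crisp membership.  Fewer than k distinct values is a degenerate-input
error.

## Macro-synteny

Canonical filter order: significance (bit score >100 **or** E <5e-20,
both strict), then best hit per (query, genome, chromosome, integer-Mb
midpoint bin), then removal of queries hitting more than 3 chromosomes of
a genome — repetitive sequence falls out here without a curated list.
"Integer-rounded" is read as round-half-up (floor available).  The
promiscuity rule is applied per target genome symmetrically (restrictable).
Blocks are maximal runs of ≥3 consecutively mapped markers (in cM order)
matching one target chromosome, tolerating ≤1 interleaved marker matching
elsewhere *in total* — the per-gap reading would chain alternating
singletons into blocks.  Overlapping candidate runs on different target
chromosomes are resolved greedily by size so block intervals are
non-overlapping per (group, genome).  Block cM bounds come from member
markers and bp bounds from their match midpoints, so boundaries are
accurate to one marker by construction.

## The synthetic-data generator

The generator emulates the *structure* of an inter-varietal hexaploid 454
survey, with one global seed fanned out to fixed per-stage streams so any
stage can be rerun in isolation and everything is bit-reproducible.

| parameter | default | rationale |
|---|---|---|
| varieties | 20 | discovery-panel size of the emulated survey |
| template families × length | 200 × 600 bp | cDNA-like templates at desk scale |
| subgenomes | 3 | A/C/D hexaploid |
| homoeolog divergence | 0.16 (pairwise substitution fraction) | >3σ clear of the 0.90 composite/placement tiers on read-length windows, so subgenome separation is a property of the data, not luck; 5% is used where tests exercise the collapse regime deliberately |
| planted SNPs | 2 per family, carrier fraction drawn from {0.1..0.5}, carriers a non-empty proper subset | spans the MAF filter boundary |
| reads | 350 ± 50 bp, coverage 8 per copy per variety | GS-FLX-Titanium-like lengths; coverage matching the study design |
| substitution error | 0.002/base | the substitution component of 454 error; homopolymer slips are a separate channel, off by default |

RIL transmission is simulated marker-to-marker (first-order Markov) with
switch probability R = 2r/(1+2r), r from the Haldane inverse of the cM
interval — adequate for pairwise rf statistics, not for interference or
multi-locus haplotype patterns.  Monosomic panels render every map locus
informative; real panels are diluted by uninformative loci, which lowers
anchor counts but not the arg-max logic.  Intensities are log-normal with
mean equal to the dose center (μ = ln c − σ²/2).

Not emulated: flowgram-level 454 noise, population structure and LD,
paralogy beyond the three homoeologs, partial chromosome deletions, and
assay chemistry.  Passing recovery tests therefore demonstrates the
pipeline logic under its stated assumptions, not performance on raw
instrument data.

## Problem sizes and reproducibility

The study-scale recovery experiments in the test suite use: CTA recall on
the full default panel (200 families, 20 varieties, coverage 8; ~96k
reads, ~5 minutes); homoeolog-collapse flagging on 40 families at 5%
divergence with placement identity relaxed to 0.85 (several hundred
divergence columns); 21 linkage groups × 12 loci with 15 stocks at 5%
call noise; 20 samples × 40 representations at dose ratio 0.5, cv 0.1;
rf grouping on 3 chromosomes × 10 markers at 10 cM, n=200 RILs; and
closed-form RIL checks at n=2000.  Distributional assertions use 99%
binomial/CLT intervals.  All seeds are fixed; `scripts/acceptance.py`
accepts `--seed` and derives every stream from it.

## Known limitations

- The greedy assembler is a surrogate: no quality-aware consensus, no
  scaffolding, not intended for large genomes; external assemblies can be
  imported via ACE.
- Multi-allelic sites are flagged `AMBIG_REF`, not genotyped.
- The design score is an explicit surrogate; externally supplied scores
  always win.
- `estimate_rf` ignores H-containing pairs; fine for near-homozygous RILs,
  lossy for F2-like data.
- Non-competitive `place_reads` soft-clips template overhangs, so clipped
  bases are absent from ACE round-trips of placements (the read itself is
  unchanged).
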