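# oatkit

SNP discovery, chromosome anchoring and comparative-mapping toolkit for
hexaploid oat-like genomes (*2n = 6x = 42*, AACCDD).

Discovering usable SNP markers in an allohexaploid is hard for one central
reason: every locus exists as three diverged homoeologous copies, and reads
from different subgenomes stacked on one template look exactly like
polymorphisms.  `oatkit` reimplements, at desk scale, a marker-development
program built around that problem:

- **Single- and composite-template SNP discovery** (STA/CTA) from
  variety-tagged 454-style reads.  The CTA assembles reads *within* each
  variety at high stringency (98% identity, which keeps homoeologs apart),
  condenses contigs to their concordant depth>2 cores, reassembles the
  fragments *across* varieties into composite templates at 90% identity,
  re-places the original reads, and tabulates per-variety pileups.
- **The purity filter ledger.**  A column is a candidate SNP only when at
  least two varieties each show a pure consensus base and the pure bases
  disagree.  A variety whose own reads are mixed at the column is IMPURE —
  the signature of homoeolog collapse — and the site is flagged
  `HET_WITHIN_VARIETY` rather than called.  Further flags cover read depth
  (<5), indel proximity, ambiguous reference, predicted minor-allele
  frequency (<10%), flank length (<50 non-variable bases), design score
  (<=0.8) and flank-context redundancy.  Filters only ever add flags;
  selection takes the PASS set sorted by predicted MAF.
- **Predicted MAF**: if *d* of *n* surveyed varieties differ from the
  reference allele, MAF = min(d/n, 1 − d/n) — e.g. 6 of 20 → 30%.
- **Linkage QC and grouping**: segregation-distortion (≤0.25 or ≥0.75)
  and missingness (≥10%) marker removal; pairwise observed recombinant
  fraction R with the selfed-RIL correction r = R/(2−2R) (forward
  R = 2r/(1+2r)); linkage groups as connected components under an rf
  threshold ladder (0.15 → 0.25).
- **Chromosome anchoring** by aneuploid deletion: in an F1 of a monosomic
  maternal stock × euploid paternal line, loci on the missing chromosome
  carry only the paternal allele (hemizygous), so paternal-homozygous calls
  where heterozygotes are expected anchor a linkage group to that stock's
  chromosome (strict arg-max over stocks, minimum two anchors).  Confirmed
  by **DArT dose dilution**: fuzzy c-means (a scikit-learn-style
  `FuzzyKMeans` estimator) separates full- from half-dose hybridization
  intensities and dose-affected markers vote for their group's chromosome.
- **Macro-synteny** against rice/Brachypodium: significance filter
  (bit score >100 or E <5e-20), best-hit-per-integer-Mb dedupe,
  promiscuous-query removal (>3 chromosomes), and collinear block inference
  along each linkage group.
- **A truth-table simulator** for all of the above: hexaploid panels with
  configurable homoeolog divergence, planted inter-varietal SNPs, 454-like
  reads, selfed-RIL transmission (Haldane), monosomic F1 panels with
  univalent-shift anomalies, and two-dose log-normal intensities.

## Worked example

Simulate a small panel (error-free reads for a compact demonstration) and
run composite-template discovery:

```python
from oatkit import simulate, snp_discovery

cfg = simulate.SimulationConfig(seed=42, n_templates=4, error_rate_sub=0.0)
haplotypes, truth = simulate.simulate_panel(cfg)
reads = simulate.simulate_reads(haplotypes, cfg)
print(f"{len(reads)} reads from {cfg.n_varieties} varieties, "
      f"{len(truth.snps)} SNPs planted")

result = snp_discovery.cta_discover(reads)
print(f"{len(result.templates)} composite templates, "
      f"{len(result.candidates)} candidate sites, "
      f"{len(result.passing)} pass all filters")
for c in snp_discovery.rank_select(result.candidates, 3):
    print(f"  {c.template_id}:{c.position} {c.ref}>{c.alt} depth={c.depth} "
          f"varieties {c.n_var_alt}/{c.n_var_alt + c.n_var_ref} "
          f"-> MAF {c.maf_pred:.2f}")
```

prints

```
1918 reads from 20 varieties, 8 SNPs planted
12 composite templates, 8 candidate sites, 7 pass all filters
  comp00005:124 A>G depth=102 varieties 10/19 -> MAF 0.47
  comp00003:330 G>C depth=152 varieties 9/20 -> MAF 0.45
  comp00004:405 T>A depth=125 varieties 9/20 -> MAF 0.45
```

Each selected line reads: on composite template `comp00005`, position 124,
ten of the nineteen varieties informative at the site carry G instead of
the reference A, predicting a 47% minor-allele frequency at a read depth
of 102.  With realistic sequencing error the same pipeline still discovers
the planted sites but flags most of them (flank unanimity is strict by
design); candidate attrition, not candidate loss, is the intended
behaviour of the filter ledger.

The same stages are scriptable from the shell:

```sh
oatkit simulate panel --seed 42 --templates 4 --out-fasta reads.fasta --out-truth truth.json
oatkit discover --mode cta --reads reads.fasta --out snps.tsv
oatkit group --genotypes rils.csv --threshold 0.25 --ladder 0.15:0.25:0.05
```

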