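# sexscan

Multi-evidence detection of sex-linked genomic regions and classification
of a species' sex-determination system (XX/XY vs ZZ/ZW) from sexed
whole-genome resequencing cohorts.

Many fishes, amphibians and invertebrates carry *homomorphic* sex
chromosomes: no karyotypic difference, no large coverage signal, often a
sex-determining region only tens of kilobases wide. Closely related
species can even disagree on which sex is heterogametic. `sexscan` is for
researchers who have resequenced a few dozen phenotypically sexed
individuals and want a reproducible, testable answer to two questions:
*where* is the sex-linked region, and *which* sex is heterogametic?

## The evidence model

Three independent footprints of a genetic sex-determination system are
scanned and then forced to agree:

1. **Coverage** (degenerated Y/W): in 1 kb windows, the adjusted log2
   ratio `log2((d_M+ε)/(AC·(d_F+ε)))` with `AC = median(d_M)/median(d_F)`
   sits at 0 on autosomes and at −1 where males are hemizygous.
2. **SNPs** (recombination-suppressed X–Y or Z–W differences): per-site
   Weir–Cockerham intersex F_ST (θ̂ = a/(a+b+c)); per-sex SNP density in
   10 kb windows with an exact sex-label permutation test
   (p = (1+#{D* ≥ D})/(1+N), D = |density_M − density_F|); per-sex
   nucleotide diversity π; and a 1-df allelic χ² association. A window is
   a *candidate* only if it ranks in the top-K of **all four** metrics,
   and a sex-randomisation control must abolish it.
3. **K-mers** (sequence absent from one sex entirely): canonical 31-mer
   presence/absence across samples, filtered (support ≥ 5 samples,
   count ≥ 2 in ≥ 20% of carriers, MAF ≥ 0.05, MAC ≥ 5) and tested with
   the same allelic χ² (two carrier alleles per sample — under perfect
   separation χ² equals the total allele count, e.g. χ² = 32 →
   p = 1.54 × 10⁻⁸ for 16 diploids). Significant k-mers are assembled
   into de Bruijn unitigs and placed on the reference.

Candidate regions are validated by genotype patterns (a SNP supports XY
when ≥ 50% of males are heterozygous and ≥ 50% of females homozygous; ZW
under the mirror rule) and by classical MDS of an allele-sharing distance
matrix. The verdict — XY, ZW or UNDETERMINED — requires the SNP-pattern
majority and the sex-specific k-mer share (≥ 2/3 one-sided) to agree.

A synthetic-cohort generator (`sexscan.simulate`) implants all of the
above — sex-linked SNP blocks with penetrance noise, population-specific
sex regions, hemizygous blocks, sex-limited inserts — with ground truth,
so every stage is testable end to end. See `docs/methods.md` for the full
model description and known limitations.

## Worked example

Simulate an XY cohort (10 males + 10 females, 2 × 100 kb genome, a 10 kb
sex-linked region with 50 fully sex-linked SNPs and a 300 bp Y-limited
insert) and run every stage:

```
$ cat run.cfg
sim.system = XY
sim.seed = 7
sim.reference_carries_sexlimited = true
scan.n_perm = 2000
scan.seed = 7
auto_top_k = true
randomisation_rounds = 5

$ sexscan all --config run.cfg --outdir example_run
verdict: XY (1 SNP candidate region(s))
```

What the output files say, and what the numbers mean:

* `snp_candidates.json` — one candidate region, `chr1:20000-30000`: the
  only window ranked top in all four SNP metrics, exactly the implanted
  interval.
* `call.json`:

  ```json
  {
    "verdict": "XY",
    "snp_vote": "XY",
    "kmer_vote": "XY",
    "n_xy_pattern_snps": 61,
    "n_zw_pattern_snps": 11,
    "n_male_specific_kmers": 329,
    "n_female_specific_kmers": 0,
    "specificity_share": 1.0
  }
  ```

  61 of the region's 105 SNPs show the male-heterozygous pattern (the 50
  implanted sites plus background SNPs that cross the 50% thresholds by
  chance, 11 of them in the mirror direction) → SNP vote XY. All 329
  significant k-mers (the insert's 31-mers and its junction k-mers) are
  male-specific → k-mer vote XY. The channels agree → XY.
* `validation_summary.json` — MDS of the region's SNPs separates the
  sexes perfectly on axis 1: concordance `10/10` males, `10/10` females.
* `contig_placements.tsv` — the 329 k-mers assemble into a single contig
  placed inside the candidate region (the simulated reference individual
  was male, so the Y-limited sequence is present in the reference; with a
  female-type reference the contig is reported unplaced, as W-derived
  contigs are against a male reference).
* `randomisation_report.json` — re-sexing the cohort at random abolished
  the candidate in 5/5 rounds (`validated: true`).
* `coverage_summary.json` — `AC ≈ 1.000`; no window beyond the two-fold
  threshold, as expected for a homomorphic pair without a hemizygous
  block.
* `manifest.json` — SHA-256 of every output; rerunning the same config
  reproduces the manifest bit for bit.

Each stage is also available separately (`sexscan simulate | filter |
coverage | snp-scan | kmer-scan | validate | call`) and as library
functions.

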