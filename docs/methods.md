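# Methods

`sexscan` infers the genetic sex-determination system of a species from a
sexed resequencing cohort by looking for the three genomic footprints that
a young or homomorphic sex-chromosome pair leaves in short-read data, and
by refusing to call a system when the footprints disagree or are absent.
This note documents the models, the parameters that matter, the synthetic
cohorts the test-suite runs on, and the numerical choices and limitations
a user should know about.

## Evidence channels

### Coverage-ratio scan

A degenerated Y (or W) no longer recruits reads to its ancestral region,
so the heterogametic sex shows ~50% pooled depth there. For 1 kb windows
with pooled male depth `d_M` and female depth `d_F` the scan computes

    score = log2( (d_M + ε) / (AC · (d_F + ε)) ),

where the adjustment coefficient `AC = median(d_M) / median(d_F)` (over
windows with positive depth in both pools) absorbs differences in sample
number and sequencing effort, so autosomal windows centre on 0 and a
hemizygous region in males sits at −1 (in females, +1). The pseudocount
ε (default 0.5) keeps zero-depth windows finite. Segments are maximal
runs of ≥ `min_run` (default 5) same-direction windows beyond a threshold
`t`, bridging single-window gaps — a deterministic stand-in for
changepoint segmentation that is adequate for block-shaped dosage
signals. `t` defaults to 1 (a two-fold change); for detecting a *halved*
dose, whose expected score is exactly −1, a threshold just inside the
signal (e.g. 0.9) is appropriate and the simulation studies use that.
The per-chromosome "sex-biased fraction" is simply the percentage of
windows with |score| ≥ t.

### SNP scan

Four statistics are computed per site or per 10 kb window (windows are
fixed, non-overlapping, anchored at coordinate 0):

* **Intersex F_ST** — the Weir–Cockerham (1984) two-group per-site
  estimator θ̂ = a/(a+b+c) from the among-sex (a), among-individual (b)
  and within-individual (c) variance components, sexes as groups.
  Monomorphic sites and sites with fewer than two called genotypes in
  either sex are *undefined*, not zero; negative θ̂ is retained (it ranks
  low). A fixed X–Y difference expressed as all-male heterozygosity gives
  θ̂ = 0.5; a fixed inter-sex difference gives θ̂ = 1.
* **Per-sex SNP density** — the number of sites polymorphic *within* each
  sex per window (a single heterozygote makes a site polymorphic). The
  statistic D = |density_M − density_F| is tested by permuting sex labels
  (group sizes preserved, the same permutation set shared across windows),
  with the add-one estimator p = (1 + #{D* ≥ D}) / (1 + N). For ≤ 12
  sexed samples an exhaustive mode enumerates every labelling and returns
  the exact p.
* **Per-sex nucleotide diversity** — site π = 2·(j/n)(1−j/n)·n/(n−1) over
  the n non-missing haplotypes of the sex, summed per window and divided
  by the window width.
* **Allelic association** — a 1-df Pearson χ² (no continuity correction)
  on the 2×2 allele × sex table, each genotype contributing two alleles.
  Degenerate tables get p = 1. A kinship-corrected mixed model is not
  used: the synthetic cohorts have no cryptic relatedness, and the
  ranking semantics are the same; under perfect separation this χ²
  equals the total allele count, which is exactly the arithmetic behind
  the headline k-mer p-values (below).

**Integration.** Windows are ranked per metric — by count of sites in the
global top-5% of θ̂, by count of sites in the top-5% smallest association
p, by permutation p ≤ 0.05 (then |density difference|), and by
|π_M − π_F| — and a window is a *candidate* only if it appears in the
top-K list of all four. Adjacent candidate windows merge into one region.
K defaults to 100, which against a ~92,000-window genome is ≈0.1% of
windows; on small simulated genomes the same selectivity is kept by
scaling K with the window count (`scaled_top_k`, K = 1 at a 20-window
desk scale). Using a fixed K = 100 on a 20-window genome would make every
window "top-K" and void the intersection.

**Falsification.** The randomisation control re-runs the entire
integration on cohorts with randomly reassigned sexes. Genuine sex-linked
candidates should essentially never recur; the report counts recurrence
and flags the original signal "validated" when the recurrence fraction is
below α. At desk scale a mildly sex-correlated random labelling can
occasionally keep the implanted window top-ranked (its fully sex-linked
sites are unusual under *any* split) while background noise hands it a
low density p — so a rare recurrence (~1 in 20 rounds for some seeds) is
expected behaviour of the control on a 20-window genome, not evidence of
a broken scan; at realistic genome sizes the coincidence probability is
negligible.

### K-mer scan

The reference-free channel detects sequence *present in one sex and
absent in the other* (Y- or W-limited DNA), which SNP calling against a
reference from the homogametic sex cannot see.

Canonical 31-mers (lexicographic minimum of k-mer and reverse complement;
k must be odd so no palindrome is its own reverse complement) are counted
per sample from 2-bit-packed sequence; windows are assembled into 64-bit
codes by a logarithmic rolling concatenation so genome-scale input
streams through numpy. The cohort matrix keeps k-mers that are present
(count ≥ 1) in ≥ 5 samples and "canonical" (count ≥ 2, i.e. not a
singleton artefact) in ≥ 20% of the samples carrying them — the
denominator is the carrier set, switchable to the full cohort. Carrier
status is then treated as a biallelic marker: minor-allele frequency
≥ 0.05 and count ≥ 5 are required, and association with sex uses the same
allelic χ² as the SNP scan with each sample contributing two carrier or
two non-carrier alleles. This two-allele coding is deliberately
calibrated: a fully sex-specific k-mer then has χ² equal to the total
allele count, giving p = 1.54 × 10⁻⁸ for 16 diploids (χ² = 32) and
p = 1.18 × 10⁻¹¹ for 23 informative diploids (χ² = 46) — the two headline
values this test must reproduce. The significant set defaults to all
k-mers tied at the minimum p; a quantile option widens it (e.g. top 1%).

Significant k-mers are assembled into unitigs of their de Bruijn graph
(maximal non-branching paths over (k−1)-overlaps, reverse complements
identified; extension stops at branches, used nodes and self-overlaps;
ties broken lexicographically so output is deterministic). Every input
k-mer lands in exactly one contig. Contigs are placed on a reference by
exact substring search of both strands (an optional seed-and-extend mode
tolerates mismatches); sex-limited sequence absent from the reference is
reported unplaced, exactly as W-derived contigs are when the reference
individual is male.

### Region validation and the verdict

Candidate regions (SNP candidates plus windows hit by placed contigs) are
validated two ways: (i) per-SNP genotype patterns — a SNP supports XY
when ≥ 50% of males are heterozygous *and* ≥ 50% of females homozygous
(hom-ref and hom-alt both count as homozygous; missing calls leave the
denominators), ZW under the mirror rule; (ii) classical (Torgerson)
multidimensional scaling of the allele-sharing distance matrix
d(i,j) = mean |g_i − g_j| / 2 over shared called sites, with
sex-concordance counted from the sign of axis 1 (per sex, the count on
that sex's majority side — invariant to axis sign, and a deterministic
replacement for judging cluster membership by eye).

The final call combines two votes: the SNP channel votes XY/ZW by the
majority genotype pattern; the k-mer channel votes by the sex-specific
share of significant k-mers, requiring at least 2/3 on one side. The
verdict is the common vote (or the only vote); any conflict or absence of
votes yields UNDETERMINED. The 2/3 margin is this package's own
construct — field practice weighs the same evidence narratively — and was
chosen so that the shares real cohorts of either system show (~0.84
male-specific under XY, ~0.91 female-specific under ZW) clear it
comfortably; it is a config parameter.

## Synthetic cohorts

The generator implants a known architecture so every stage can be tested
against ground truth:

* **Genome** — 2 chromosomes × 100 kb of uniform random sequence by
  default (a 200 kb desk-scale genome; all window arithmetic is identical
  at real scale).
* **Cohort** — 10 males + 10 females per population by default; one
  population unless population-specific sex regions are requested.
* **Background SNPs** — per-base rate 5 × 10⁻³ (≈ 50 SNPs per 10 kb
  window, the same order as ~10⁷ SNPs on a Gb-scale genome). Allele
  frequencies are drawn from Beta(0.5, 0.5) (U-shaped, SFS-like);
  between-population drift mixes in an independent Beta re-draw with
  weight `population_divergence`. Genotypes are binomial draws — sites
  are unlinked; no LD, demography or selection.
* **Sex-linked block** — 50 fully sex-linked SNPs in a 10 kb
  window-aligned region: heterozygous in the heterogametic sex,
  homozygous (ref or alt, chosen per site) in the other. Penetrance is
  per *individual*: with probability 1 − penetrance a whole individual
  expresses the opposite pattern, mimicking phenotyping errors or
  recombinants. Note the consequence: a single non-following female
  makes every implanted site polymorphic among females and zeroes the
  density statistic for the block, which is why system calls below full
  penetrance lean on the k-mer channel.
* **Hemizygous block** — optional region where the heterogametic pool's
  expected depth is halved. Pooled depths are Poisson per 1 kb window.
* **Sex-limited insert** — 300 bp of novel sequence spliced into one
  haplotype of every heterogametic individual (inside the sex region).
  The `reference_carries_sexlimited` flag controls whether the emitted
  reference contains it, modelling a reference individual of the
  heterogametic vs homogametic sex (contigs place in the first case and
  are unplaced in the second).
* **Reads** — error-free 150 bp fragments tiled at 50 bp steps over both
  haplotypes (3× per haplotype), so every interior k-mer occurs ≥ 2 times
  per sample and the ≥ 2-count canonicality filter behaves as with real
  reads. An optional per-base error rate (default 0) is available. No
  quality scores, no real error profile.

Identical seeds give bit-identical output (one `numpy` Generator drives
everything). What passing tests on these cohorts do **not** show: power
under LD and population structure, mapping bias, or calibration of the
χ² association under relatedness — the generator has none of these.

## Study sizes and numerical choices

* Simulation studies (test suite and `scripts/acceptance.py`) use the
  default 200 kb genome, 10+10 cohorts, 2,000 permutations, and 20 seeds
  per condition; the null-calibration study uses 10 chromosomes (200
  windows over two seeds). The library defaults remain the full-scale
  values (window 10 kb, top 5%, 100,000 permutations, top-100 windows,
  k = 31, support ≥ 5, canonical ≥ 20%, MAF ≥ 0.05, MAC ≥ 5, QUAL ≥ 30,
  depth 10–200, missingness ≤ 10%).
* Permutation p-values of the integer statistic D are discrete and
  therefore *super-uniform*: the measured null fraction of windows at
  p ≤ 0.05 is ≈ 2% rather than 5%, both at desk scale and at a 13v13
  cohort with ~100 SNPs per window. That is the correct, conservative
  behaviour of an exact test with ≥-tie handling; the calibration check
  asserts the fraction sits inside the binomial 99% band and, in
  particular, never exceeds it.
* The depth bound of the variant filter is applied per genotype
  (out-of-range calls become missing before the missingness test),
  matching common practice; a site-mean mode is available. Multiallelic
  sites are dropped with a logged count. Filtering is idempotent.
* Internal coordinates are 0-based half-open; VCF positions convert at
  the boundary. Windows print as multiples of the window width.
* MDS drops negative eigenvalues with a warning and orients each axis so
  the first nonzero coordinate is positive. Degenerate association
  tables (zero margins) get χ² = 0, p = 1 rather than NaN.
* All writers are deterministic; the pipeline manifest records SHA-256
  of every output so reruns can be verified bit-identical.

## Known limitations

* The desk-scale genome makes the top-K intersection much less selective
  than at real scale; `scaled_top_k` compensates but rare null
  coincidences (and rare randomisation-control recurrences) remain
  possible on 20-window genomes.
* The assembler is a plain unitig builder: repeats within the significant
  k-mer set fragment contigs; no bubble popping or scaffolding.
* Exact-match placement will miss diverged copies; the seed-and-extend
  mode is deliberately simple (Hamming, no gaps).
* The caller's 2/3 share threshold and channel-voting rule are package
  constructs; the verdict report labels them as such.
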