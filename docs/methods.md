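# Methods

## The tile model

WGBS of single oocytes and embryos yields sparse, noisy per-CpG counts, so
all quantities are computed on fixed 300-bp windows ("tiles") anchored at
coordinate 0 on every chromosome.  The processing order is: filter sites →
tile per sample → pool replicates → compare/profile.

* **Site filter** — a CpG needs ≥ 5 total reads (`min_site_coverage`,
  inclusive).  The filter is applied per sample, before tiling and before
  replicate pooling.
* **Tile filter** — a tile needs ≥ 4 surviving CpGs (`min_cpgs_per_tile`).
  The source convention "greater than three CpG sites" is read literally
  as ≥ 4; the common ≥ 3 variant is one flag away.
* **Tile level** — default `mean_of_sites`: the unweighted mean of per-site
  levels `n_meth/(n_meth+n_unmeth)`.  Sample-scale ("global") methylation
  is the unweighted mean of tile levels, so site-mean is the matching
  tile-scale convention.  `pooled_counts` (methylated reads over total
  reads) is kept alongside because the Fisher test is count-based.
* **Replicate pooling** — the stage tile universe is the union of replicate
  tile keys; read and CpG counts are summed and site-mean levels pooled
  weighted by CpG count (equivalent to averaging over all site
  observations).  Pooling is order-invariant and count-conserving.
* **CpG density** — for each covered CpG, the number of covered CpGs within
  a closed ±150-bp window, the focal site included (minimum 1); tile
  density is the mean over member sites.  Implemented as a vectorised
  binary-search window scan; an O(n²) all-pairs count serves as the test
  oracle.
* **Dyad merging** — the two strands of a CpG dyad are *not* merged by
  default (positions kept as the extractor reports them);
  `merge_cpg_dyads` sums counts onto the plus-strand position when asked.

Coordinates are 1-based for cytosines (Bismark convention) and 0-based
half-open for all intervals and tiles (BED convention); conversion happens
only at I/O boundaries.

## Differential methylation

For a stage pair, the comparison universe is the intersection of tile
keys.  Each shared tile gets a two-sided Fisher exact test on the 2×2
table of pooled methylated/unmethylated reads, defined by hypergeometric
enumeration: the sum of point probabilities of all tables with the
observed margins whose probability does not exceed the observed one
(relative tolerance 1e-12, guarding float ties).  The implementation
scores the whole margin support in one vectorised pass; tests check it to
1e-9 against exact integer-arithmetic enumeration for every table with
total ≤ 60, and against `scipy.stats.fisher_exact`.  A table with an
all-zero margin returns p = 1 by convention (it cannot arise from covered
tiles).

FDR is Benjamini–Hochberg, computed once per pairwise comparison over all
its common tiles (the FDR universe is per-comparison, not global across
comparisons), via `statsmodels`; the O(m²) step-up definition
`q_(i) = min_{j≥i} p_(j)·m/j` is the test oracle.

Classification, with thresholds as printed and boundary conventions
explicit:

* changing: |Δ| > 0.40 (strict) AND p ≤ 0.05 AND q ≤ 0.05; split into
  increasing/decreasing by sign of Δ = level_b − level_a; else stable.
* DMR: one side ≥ 0.75 and the other ≤ 0.25 (both inclusive) with the
  same significance gates; labelled by the high side.  Because
  0.75 − 0.25 = 0.5 > 0.4, DMRs are a subset of changing tiles on any
  shared universe.
* hyper/hypo: single-tile level ≥ 0.75 / ≤ 0.25, inclusive.

Both the raw-p and the q gate are applied even though the q gate usually
dominates.  Adjacent DMR tiles are not merged into larger regions.

## Annotation and profiles

Tiles get exactly one feature class by precedence (promoter > CGI > exon >
intron > SINE > LINE > LTR, configurable; no overlap → intergenic) so
class fractions partition any tile universe, matching pie-chart style
reporting.  Promoters are the 1,000 bp upstream of the TSS (strand-aware,
clipped at chromosome bounds).

Metagene profiles use per-site levels (finer resolution near the TSS than
tiles): 60 fixed 250-bp bins per 15,000-bp flank and 100 proportional
gene-body bins.  Minus-strand genes are reflected about the gene centre so
bin 0 is always the 5′-most upstream bin; the reflection makes a
minus-strand gene's profile exactly the mirror of its plus-strand image.
Empty bins are missing, not zero.  A constant methylation field yields a
flat profile to 1e-12.

Region summaries average tile levels over named intervals (site-level
variant flagged by column name).  CpH levels pool CHG+CHH site levels
after the same ≥ 5× filter; CpG records never contribute.  The
density–methylation relation buckets tiles by density (equal-count
quantiles by default) and reports Pearson r of bucket mean density versus
bucket mean level, with the raw tile-level r alongside.  Replicate
correlation is pairwise Pearson r over each sample pair's shared tiles.

Methylation–expression correlation is Spearman ρ between
log2(FPKM + 1) and per-gene region methylation; the +1 pseudocount only
admits zero FPKM — for positive FPKM the log and pseudocount are monotone
and leave ranks (hence ρ) unchanged.  Repeat-transcript annotation is
multi-label (a transcript overlapping both a SINE and a LINE counts in
both), unlike tile assignment.

## The simulator

The generator emulates the statistical structure of a gamete/early-embryo
WGBS study at desk scale, with truth tables for scoring:

* **Genome** — small multi-chromosome genome (defaults: chr1 500 kb, chr2
  400 kb, chrX 250 kb, chrM 16 kb) with geometric CpG spacing (mean 45 bp
  background, 12 bp inside CGIs), gene models with exon structure, CGIs at
  about half the TSSs, and LINE/SINE/LTR intervals.
* **Stage means** — defaults are the printed global levels of the bovine
  trajectory: sperm 72.5 %, GV 29.7 %, in-vivo MII 31.6 %, in-vitro MII
  29.0 %, 2-cell 25.0 %, 4-cell 26.7 %, 8-cell 15.3 % (the nadir), 16-cell
  32.1 % (the rebound).
* **Hierarchy** — each tile carries a true stage mean (stage mean, then
  promoter/CGI caps at 0.08/0.05, a mean-preserving density tilt in
  high-methylation stages, chrM pinned at 0.5 %, ICR-like loci at 50 % in
  embryo stages / hypo in sperm / hyper in oocytes, planted DMR tiles for
  one stage pair).  Each replicate draws a tile probability from a Beta
  with that mean and precision 30 (overdispersion, so the Fisher test
  faces a non-trivial null and within-stage replicates correlate more than
  between-stage samples); sites draw Poisson(10) depth and binomial
  methylated counts.  CpH sites are emitted sparsely (0.25 per CpG) at
  per-stage rates with the inverse developmental pattern (lowest in sperm,
  peak at 8-cell).
* **Plantable truth** — ICR-like loci and planted DMRs are placed only in
  tiles with ≥ 4 CpGs outside capped features and chrM, so the planted
  truth is observable under the default tile filter.
* **Expression** — a Gaussian copula couples per-gene promoter truth to
  lognormal FPKM at a target Spearman (default −0.30), using the exact
  inversion ρ_z = 2·sin(π·ρ_s/6); repeat transcripts draw low exponential
  FPKM (mean 12, i.e. the < 40 regime).
* **Determinism** — one integer seed feeds per-(stage, replicate) child
  generators; a config + seed pair fixes every output file byte-for-byte.

What the simulator does *not* model: read-level errors, bisulfite
conversion failure, mappability structure, strand asymmetries, copy-number
or allele-specific effects, and realistic chromosome-scale heterogeneity.
Passing recovery tests therefore demonstrates correctness of the
*analysis* under the stated generative assumptions, not robustness to
every artefact of real libraries.

## Validation choices and problem sizes

* Fisher: exhaustive check of all ~600k tables with total ≤ 60 at 1e-9;
  BH: 1,000 random vectors (m ≤ 500) with forced ties at 1e-12; density:
  1,000 random position sets (n ≤ 2,000) with exact equality.
* Stage-mean recovery runs a structure-free simulation (no caps, no tilt,
  no ICRs, no chrM) so the configured stage means are themselves the
  global truth: 6.6 Mb genome ≈ 20,000 emitted tiles, 10× depth, 3
  replicates, recovery within ±0.01 per stage, nadir at 8-cell and a
  ≥ 1.9× rebound to 16-cell.
* DMR recovery uses two groups at a common background mean of 0.5 with
  200 planted 0.85-vs-0.15 tiles at 20× depth (recall and precision
  ≥ 0.90) and a null run with nothing planted (call fraction ≤ 0.05).
  A null background is required for precision to be meaningful: under the
  real stage means, sperm-vs-oocyte background tiles differ by ~43 % and
  are genuinely differential.
* ICR recovery uses 40 loci × 3 replicates at 20× so the Monte-Carlo
  standard error of the pooled mean (~0.008 under precision-30 Beta noise)
  sits well inside the ±0.02 recovery band.
* All simulation sizes were chosen once for statistical adequacy at desk
  scale; the headline numbers of the original cluster-scale study (global
  levels, 14,939 common tiles, 6,211 gamete DMRs, r = −0.97) depend on
  the full bovine genome and raw reads and are reproduced qualitatively,
  not numerically.

## Known limitations

* No smoothing or HMM-based DMR detection; single-tile calls only.
* The beta-binomial dispersion is tile-level and shared across sites
  within a tile; real data show additional site-level heterogeneity.
* Whether the original analysis strand-merged CpG dyads, used site-mean or
  count-pooled tile levels, and which overlap-precedence rule produced its
  feature partitions is unstated at the source; each choice here is
  explicit and configurable, with the defaults documented above.
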