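# Methods

## The question and the estimands

In cyclical parthenogens, sex is widely believed to be environmentally
determined, but an X0 system can hide behind environmental sex induction
(it does in several aphids). With one female and one male pooled library
per clonal line, three signals distinguish the hypotheses:

* **Ploidy**: an X0 male carries one X, so his read depth on the X is half
  his autosomal depth; a ZW female mirrors this on the Z. The per-window
  standardized female/male ratio R = (c_F/C̄_F)/(c_M/C̄_M) is ~1 on
  autosomes, ~2 on an X, ~0.5 on a Z.
* **Zygosity**: a sex-linked SNP shows heterozygosity in one sex and
  homo-/hemizygosity in the other. Between groups of three samples per
  sex, the per-site Weir–Cockerham θ of that pattern is exactly 0.5.
* **Clonality**: a son is a clonal copy of his mother, so a genuine
  polymorphism cannot divide the sexes by zygosity at all, and a
  heterozygous male over homozygous females has no plausible clonal
  origin. Apparent sex-divided SNPs must therefore be artifacts, and their
  allele-depth signature (minor fraction ≈ 0.15 instead of ≈ 0.5)
  betrays them.

Absence of all three signals, consistently across clonal lines, is the
meaningful "no GSD" outcome; the merged verdict reports the three lines of
evidence separately and never collapses them into a single p-value.

## Coverage scan

Pipeline order: per-position mask → window means → standardize & ratio →
low-female filter → summarize/classify.

* **Repeat cap** (`cap`, default 200X, strictly greater-than): collapsed
  repeats attract mis-mapped reads in both sexes; positions above the cap
  are excluded per sample before any averaging.
* **Windows** (default 5 kb and 10 kb) tile each chromosome from
  position 1; the terminal short window is kept but flagged
  `PARTIAL_WINDOW` and excluded from classification. A window whose
  positions are all masked has a missing mean.
* **Standardization**: C̄ per sex is the mean of unmasked per-position
  depths over the whole genome — computed after masking and before any
  window-level exclusion, so the depth-weighted mean of z = depth/C̄ is
  exactly 1 by construction. Windows flagged by the low-female filter
  still contribute their positions to C̄ (the filter is a window-level
  exclusion from the ratio analysis, not from normalization).
* **Low-female filter** (`min_female`, default 5X, strictly lower-than):
  a near-zero female mean makes the ratio unstable. No male filter is
  applied — male coverage collapse is exactly the X0 signal — but windows
  with a male mean of 0 carry no finite ratio; they are flagged
  `MALE_ZERO`, excluded from summaries, and reported as run-length
  stretches, since a long run of them is itself X0 evidence.
* **Classification bands** (on the median window ratio per chromosome):
  AUTOSOMAL [0.8, 1.2], X_LINKED [1.6, 2.4], Z_LINKED [0.4, 0.6], else
  AMBIGUOUS. The bands are symmetric on the log scale around 1, 2 and 0.5
  and wide enough to absorb normalization shrinkage: a hemizygous
  chromosome that is a fraction f of the genome drags its sex's C̄ down by
  f/2, so with f = 0.1 an X lands at 1.9 and the autosomes at 0.95. The
  median, not the mean, drives the call so a handful of artifact windows
  cannot flip a chromosome. Outlier windows (unflagged, outside the
  autosomal band) are reported with coordinates regardless of the
  chromosome call, and `region_report` serves a priori focus regions
  (e.g. a peri-centromeric candidate interval) directly.

## Variant scan

Genotype-level filters (per-sample FORMAT DP between 10 and 100, GQ ≥ 30,
no missing calls, single-base biallelic REF/ALT) are applied before
estimation; boundary values pass. The per-site Weir–Cockerham (1984)
two-allele, two-population estimator is used, θ = a/(a+b+c) with the
standard n̄, n_c, p̄, s², h̄ intermediates. Negative components and thetas
are reported as computed, not clamped. Hemizygous calls arrive as diploid
homozygotes (the diploid-prior caller convention) and are treated as such.

Because all inputs are integer genotype counts, the components are
evaluated in exact rational arithmetic and converted to float at the end:
the candidate threshold (θ > 0.25, strict) then behaves exactly at the
boundary, and the fully sex-divided pattern yields θ = 0.5 to the last
bit. Ranking is by θ descending with positional tie-breaks; exhaustive
enumeration of all 3⁶ genotype configurations confirms that θ ≤ 1
whenever defined, that every one-sex-all-het / other-sex-one-allele-hom
configuration gives exactly 0.5, and that within the {hom_ref, het} space
spurious heterozygosity explores, no other pattern exceeds 0.25.

## Candidate review

For each sample at a candidate site, the allele balance is
(minor fraction, major:minor ratio) from AD. A heterozygous call is
**reliable** iff the ratio is ≤ `max_ratio` (default 1.5, i.e. minor
fraction ≥ 0.4). The site verdict is conservative: one unreliable het, or
one homozygote whose minor fraction exceeds `hom_minor_floor` (default
0.1 — chosen to separate the sequencing-error level of ~0.01 from the
~0.15 mis-mapping signature; configurable), makes the site
ARTIFACT_SUSPECT. Raising `max_ratio` is monotone: it can only move sites
toward SUPPORTED. The parthenogenesis flag marks all-males-het /
all-females-hom sites HET_MALE_IMPLAUSIBLE; the female-het/male-hom
pattern an X-linked SNP would genuinely show is CONSISTENT.

A known limitation: at modest depth the 1–1.5 band is strict. A genuine
heterozygote whose allele depths fluctuate binomially around 0.5 at
DP ≈ 25 falls outside the band with probability ≈ 0.23, so on real data
the review is best read as "no candidate survives even a lenient
authenticity screen", not as a calibrated classifier of individual calls.

## Simulator

The generator emulates the study design: 3 clonal lines × 2 sexes, one
pooled sample each, 10 chromosomes (default 1 Mb each), mean depth 25X.

* **Clonal pairing.** The female and male sample of one line share their
  true genotype. Consequently, under the null, genuine polymorphism never
  produces a sex-divided site — only the error channel can — which is the
  property the artifact-rejection screen is tested against.
* **Depth.** Poisson by default; negative binomial (size
  `depth_dispersion`) for per-position overdispersion. On top, each
  sample has a multiplicative local rate field: gamma multipliers with
  mean 1, constant within `rate_block_bp` blocks (default 1 kb), CV
  `rate_cv` (default 0.14), independent across blocks and samples. This
  stands in for library- and locus-specific coverage biases, which
  dominate window-scale variance in real short-read data: independent
  Poisson noise alone would give a window-ratio SD of ~0.003 at 25X/10 kb,
  two orders below what resequencing studies observe. The defaults
  reproduce window-ratio SDs of ≈ 0.063 (10 kb) and ≈ 0.088 (5 kb), the
  level reported for this study design; because the field is
  sample-specific it does not cancel in the female/male ratio, unlike
  shared mappability/GC structure, which is deliberately not modelled.
* **Hemizygosity.** Over the target (whole chromosome for X0/ZW, an
  interval for SEX_REGION) the hemizygous sex's depth expectation is
  halved and its genotype at a polymorphic site is one of its line's two
  alleles, emitted as a diploid homozygote with halved DP — how a
  diploid-prior caller reports haploid regions.
* **Artifact regions** multiply the depth expectation in both sexes
  (default use: exercise the > 200X mask).
* **Genotypes.** Background sites draw one Hardy–Weinberg genotype per
  line at reference-allele frequency `allele_freq` (default 0.5). With
  probability `false_het_rate` a site is error-prone instead: truly
  homozygous in every line, each sample independently miscalled
  heterozygous with probability 0.5; false-het AD is Binomial(DP,
  `error_minor_fraction`) (default 0.15), homozygotes at such sites carry
  stray minor reads at half that rate. Genuine heterozygote AD is
  balanced up to read parity (minor = ⌊DP/2⌋): the generator's job here
  is to present unambiguously clean heterozygotes so the review's
  discrimination (0.5 vs 0.15 balance) is what is tested, not binomial
  tail noise at 25X (see the review limitation above). Clean homozygotes
  carry Binomial(DP, 0.002) stray reads. GQ is a monotone function of DP
  capped at 99 (min(99, 3·DP)); only the ≥ 30 threshold matters
  downstream. Planted SEX_SNP sites are heterozygous in every sample of
  one sex (`sex_snp_pattern`, default female-het, i.e. the X-linked
  pattern) and hemizygous for a single shared allele in the other.
* **Determinism.** All randomness flows from `SimConfig.seed` through
  per-output seed streams (sex, genotype, stage), so identical inputs
  reproduce byte-identical files; samples within and across sexes are
  otherwise independent (no shared library-batch effects are modelled).

What passing simulation tests does **not** show about real data: no read
alignment, mappability, GC or batch structure is simulated, positions are
independent given the block field, and false heterozygotes are assigned
independently per sample rather than through a shared mis-mapping locus.
The simulator validates the pipeline's logic and calibration targets, not
the full error structure of a sequencing study.

## Numerical choices and degenerate inputs

* Exact rational arithmetic in the θ components (above); window/ratio
  arithmetic in float64, verified against a naive per-position reference
  to 12 significant digits.
* A sex whose unmasked genome-wide mean coverage is 0 is a degenerate
  input and raises; a chromosome with zero usable windows is called
  AMBIGUOUS with a warning; a fully masked window has a missing mean.
* Monomorphic sites have a + b + c = 0 and an undefined θ (excluded from
  ranking); ties in θ are broken by chromosome then position.
* Depth files may omit positions (treated as depth 0) and may be depth
  TSV (1-based) or bedGraph (0-based half-open); loaders name the file,
  line and chromosome on error.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the simulated study at
10 × 1 Mb chromosomes for coverage-level checks (20-seed detection runs
for X0/ZW recovery) and 10 × 100 kb with 2×10⁴ sites for the variant
screen; these sizes give per-window and per-site statistics
indistinguishable from larger genomes for the quantities checked, since
every estimator involved is local (per window or per site).
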