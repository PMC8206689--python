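# sexscan

Genome-wide tests for **genetic sex determination (GSD)** from male/female
whole-genome resequencing — built for cyclically parthenogenetic organisms
such as *Daphnia*, where males are produced asexually (a son is a clonal
copy of his mother) and the question is whether any genetic difference
between the sexes exists at all.

The package answers that question with three orthogonal screens, plus a
ground-truthed simulator to verify that each screen detects what it should
and rejects what it should not:

1. **Coverage-ratio scan** (`sexscan.coverage`). In an X0 system males
   carry one X, so male read depth on the X is half the autosomal depth
   (females ZW: the mirror). Per-position depths are masked above a repeat
   cap (default > 200X), averaged in non-overlapping windows (5 kb and
   10 kb by default), windows with female mean < 5X dropped, each sex
   standardized by its genome-wide mean coverage C̄, and the per-window
   ratio formed:

   R = (c_F / C̄_F) / (c_M / C̄_M)

   Autosomes sit at R ≈ 1, an X at R ≈ 2, a Z at R ≈ 0.5. Chromosomes are
   called from the median window R; a hemizygous chromosome occupying a
   fraction *f* of the genome lands at 2·(1 − f/2)⁻¹·… in practice 1.9
   rather than 2.0 for *f* = 0.1, which the classification bands absorb.

2. **Per-SNP F_st scan** (`sexscan.variants`). Biallelic SNPs passing
   genotype-level filters (10 ≤ DP ≤ 100, GQ ≥ 30, no missing calls) are
   ranked by the per-site Weir–Cockerham (1984) θ between females and
   males, θ = a/(a+b+c) from the among-population (a), among-individual
   (b) and within-individual (c) variance components. With three samples
   per sex, a SNP at which one sex is entirely heterozygous and the other
   homozygous attains θ = 0.5 exactly; candidates are sites with θ > 0.25.

3. **Candidate reliability review** (`sexscan.validate`). A genuine
   diploid heterozygote shows balanced allele depths; mis-mapped repeats
   produce "heterozygotes" with a minor-allele fraction around 0.15 and
   contaminate neighbouring homozygotes with stray reads. A heterozygous
   call is reliable only if its major:minor read ratio is ≤ 1.5; one
   unreliable het (or one contaminated homozygote) marks the site
   ARTIFACT_SUSPECT. A separate flag marks zygosity patterns impossible
   under clonal male production (all males het, all females hom).

`sexscan.simulate` generates depth tracks and VCF callsets under the
architectures being tested for (NULL_ESD, X0, ZW, SEX_REGION, SEX_SNP),
with repeat-like high-coverage artifact regions and error-driven false
heterozygotes, and writes ground truth alongside. `sexscan.report` runs
everything over multiple clonal lines and merges the evidence into a
single verdict.

## Worked example

Simulate an X0 genome (males hemizygous for chr1), scan it, and rank SNPs:

```bash
sexscan simulate --architecture X0 --hemizygous-chrom chr1 \
    --n-chromosomes 10 --chrom-length 100000 --n-sites 500 \
    --seed 11 --out sim/
sexscan coverage --female sim/G1_F.depth.tsv --male sim/G1_M.depth.tsv \
    --genome sim/genome.tsv --window 10000 --out cov/
```

which prints

```
genome-wide mean ratio 1.0449 (SD 0.2872); outputs in cov/
```

and `cov/chromosomes.tsv` calls chr1 `X_LINKED` with all other
chromosomes `AUTOSOMAL`:

```
chrom   n_windows  median_ratio  mean_ratio  sd_ratio   call
chr1    10         1.87444       1.87851     0.0903348  X_LINKED
chr2    10         0.913288      0.918959    0.0432636  AUTOSOMAL
...
```

— the hemizygous chromosome sits at the normalization-shrunk X
expectation (≈ 1.9, not 2.0) and the autosomes slightly below 1, because
the halved male X pulls the male genome-wide mean down. The genome-wide
mean sits above 1 since the X windows are included in it. On a
`NULL_ESD` simulation the same command reports a mean ratio ≈ 1.00 with
every chromosome `AUTOSOMAL`.

For the variant side:

```bash
sexscan fst --vcf sim/sites.vcf --sex-map sim/sex_map.tsv --out fst/
sexscan validate --vcf sim/sites.vcf --candidates fst/candidates.tsv \
    --sex-map sim/sex_map.tsv --out val/
```

`sexscan fst` prints `500 sites read, 474 passed filters, 2 candidates
with theta > 0.25`; the ranked table shows the genuinely X-linked sites
at the top:

```
chrom  pos    theta  ...  pattern                  sex_divided
chr1   41602  0.5    ...  F:all_het|M:all_hom_ref  True
chr1   54499  0.5    ...  F:all_het|M:all_hom_alt  True
```

These sites (heterozygous females over hemizygous males, with balanced
allele depths) are reported `SUPPORTED`/`CONSISTENT` by the review;
error-driven false heterozygotes reaching θ = 0.5 on a null simulation
end `ARTIFACT_SUSPECT` instead.

A full multi-line run is driven by YAML
(`sexscan run --config run.yaml`): pairs of depth files, the joint VCF and
sex map, window sizes, thresholds and optional focus regions; it writes
per-pair window/chromosome tables, outlier BEDs, the ranked F_st table,
candidate verdicts, a merged JSON summary and a plain-text verdict.

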