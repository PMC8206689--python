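"""Synthetic sequencing data with known sex-determination architecture.

The generator emulates the study design the scan is built for: three
isofemale (clonal) lines, one pooled female and one pooled male library
per line, ~25X mean coverage on a genome of 10 chromosomes.  Because males
in a cyclical parthenogen are produced asexually, a male is a clonal copy
of his mother; the simulator therefore gives the female and male sample of
one line identical true genotypes (minus a lost chromosome copy under the
hemizygous architectures).  Architectures:

* ``NULL_ESD``  -- purely environmental sex determination; no genetic
  difference between the sexes anywhere.
* ``X0``        -- males carry one copy of the target chromosome/region.
* ``ZW``        -- females carry one copy (mirror of X0).
* ``SEX_REGION``-- a sub-chromosomal hemizygous interval.
* ``SEX_SNP``   -- individual sex-linked SNPs with no coverage signature.

Depth is Poisson by default (negative binomial when ``depth_dispersion``
is set) around a locally varying rate: per-sample multiplicative rate
multipliers, constant within short blocks and gamma-distributed across
blocks, stand in for the library- and locus-specific coverage biases of
real short-read data, which dominate window-scale coverage variance.
Error-driven false heterozygotes (the ``false_het_rate`` channel) carry a
low minor-allele read fraction, reproducing the signature by which real
mis-mapped candidates are recognized and rejected.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .coverage import DepthTrack
from .genome import GenomeModel
from .io import write_bedgraph, write_depth_tsv, write_sex_map, write_vcf
from .variants import HET, HOM_ALT, HOM_REF, SiteRecord

# rng stream labels, mixed into the seed so each output has its own stream
_STREAM_DEPTH = 1
_STREAM_SITES = 2
_SEX_CODE = {"F": 0, "M": 1}

# probability that a sample at an error-prone (false-het) site is
# miscalled heterozygous; the remaining samples stay homozygous with
# stray minor-allele reads
FALSE_HET_SAMPLE_P = 0.5
# per-read sequencing error rate feeding stray reads at clean homozygotes
SEQ_ERROR = 0.002
_BASES = np.array(["A", "C", "G", "T"])


class Architecture(str, Enum):
    NULL_ESD = "NULL_ESD"
    X0 = "X0"
    ZW = "ZW"
    SEX_REGION = "SEX_REGION"
    SEX_SNP = "SEX_SNP"


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth sex-determination architecture driving the simulator.

    ``hemizygous_target`` is a chromosome name or a (chrom, start, end)
    1-based closed interval (required for X0/ZW/SEX_REGION).
    ``artifact_regions`` are (chrom, start, end, multiplier) tuples whose
    coverage is inflated in both sexes, mimicking collapsed repeats.
    ``sex_snp_pattern`` chooses which sex is heterozygous at planted SNPs:
    'female_het' (X-linked pattern) or 'male_het' (ZW mirror).
    """

    architecture: Architecture = Architecture.NULL_ESD
    hemizygous_target: str | tuple[str, int, int] | None = None
    sex_snp_sites: tuple[tuple[str, int], ...] = ()
    artifact_regions: tuple[tuple[str, int, int, float], ...] = ()
    false_het_rate: float = 0.0
    region_hemizygous_sex: str = "M"
    sex_snp_pattern: str = "female_het"

    def __post_init__(self) -> None:
        object.__setattr__(self, "architecture", Architecture(self.architecture))
        if not 0.0 <= self.false_het_rate <= 1.0:
            raise ValueError("false_het_rate must be in [0, 1]")
        arch = self.architecture
        if arch in (Architecture.NULL_ESD, Architecture.SEX_SNP):
            if self.hemizygous_target is not None:
                raise ValueError(f"{arch.value} takes no hemizygous_target")
        else:
            if self.hemizygous_target is None:
                raise ValueError(f"{arch.value} requires a hemizygous_target")
        if arch is not Architecture.SEX_SNP and self.sex_snp_sites:
            raise ValueError(f"{arch.value} takes no sex_snp_sites")
        if self.region_hemizygous_sex not in ("F", "M"):
            raise ValueError("region_hemizygous_sex must be 'F' or 'M'")
        if self.sex_snp_pattern not in ("female_het", "male_het"):
            raise ValueError("sex_snp_pattern must be 'female_het' or 'male_het'")

    @property
    def hemizygous_sex(self) -> str | None:
        """Which sex carries a single copy of the target (X0: males)."""
        if self.architecture is Architecture.X0:
            return "M"
        if self.architecture is Architecture.ZW:
            return "F"
        if self.architecture is Architecture.SEX_REGION:
            return self.region_hemizygous_sex
        return None

    def hemizygous_interval(self, genome: GenomeModel,
                            ) -> tuple[str, int, int] | None:
        if self.hemizygous_target is None:
            return None
        if isinstance(self.hemizygous_target, str):
            chrom = self.hemizygous_target
            if chrom not in genome:
                raise ValueError(f"hemizygous target chromosome {chrom!r} "
                                 f"not in genome")
            return (chrom, 1, genome.lengths[chrom])
        chrom, start, end = self.hemizygous_target
        genome.check_interval(chrom, start, end)
        return (chrom, start, end)

    def validate(self, genome: GenomeModel) -> None:
        self.hemizygous_interval(genome)
        for chrom, start, end, mult in self.artifact_regions:
            genome.check_interval(chrom, start, end)
            if mult <= 0:
                raise ValueError(f"artifact multiplier for {chrom}:{start}-{end} "
                                 f"must be positive")
        for chrom, pos in self.sex_snp_sites:
            genome.check_interval(chrom, pos, pos)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters shared by the depth and genotype simulators.

    mean_depth: expected per-position coverage per sample (the study design
    aimed for >= 25X).  depth_dispersion: negative-binomial size parameter;
    None gives the Poisson limit.  error_minor_fraction: expected
    minor-allele read fraction at spuriously heterozygous calls (~0.15 in
    real mis-mapped candidates).  rate_block_bp / rate_cv: length and
    coefficient of variation of the local coverage-rate multipliers
    (rate_cv = 0 switches the bias field off).  allele_freq: reference
    allele frequency for background polymorphisms.
    """

    n_genotypes: int = 3
    mean_depth: float = 25.0
    depth_dispersion: float | None = None
    error_minor_fraction: float = 0.15
    rate_block_bp: int = 1000
    rate_cv: float = 0.14
    allele_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be at least 1")
        if not 0.0 < self.error_minor_fraction < 0.5:
            raise ValueError("error_minor_fraction must be in (0, 0.5)")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive when set")
        if self.rate_block_bp < 1:
            raise ValueError("rate_block_bp must be at least 1")
        if self.rate_cv < 0:
            raise ValueError("rate_cv must be non-negative")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")


def _rng(config: SimConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, stream, *extra]))


def _expected_rate(genome: GenomeModel, scenario: ScenarioSpec,
                   config: SimConfig, sex: str) -> dict[str, np.ndarray]:
    """Expected depth per position for one sex, before sampling noise."""
    mu = {chrom: np.full(length, config.mean_depth, dtype=np.float64)
          for chrom, length in genome.chromosomes}
    interval = scenario.hemizygous_interval(genome)
    if interval is not None and sex == scenario.hemizygous_sex:
        chrom, start, end = interval
        mu[chrom][start - 1:end] *= 0.5
    for chrom, start, end, mult in scenario.artifact_regions:
        genome.check_interval(chrom, start, end)
        mu[chrom][start - 1:end] *= mult
    return mu


def simulate_depth(genome: GenomeModel, scenario: ScenarioSpec,
                   config: SimConfig, sex: str, genotype: int = 0,
                   ) -> DepthTrack:
    """Simulate one sample's per-position depth track.

    Expectation is ``mean_depth`` everywhere except the hemizygous target
    (halved, in the hemizygous sex only) and artifact regions (multiplied,
    in both sexes).  Identical (genome, scenario, config, sex, genotype)
    inputs reproduce the track bit for bit.
    """
    if sex not in _SEX_CODE:
        raise ValueError("sex must be 'F' or 'M'")
    scenario.validate(genome)
    rng = _rng(config, _STREAM_DEPTH, _SEX_CODE[sex], genotype)
    mu = _expected_rate(genome, scenario, config, sex)
    depth: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        lam = mu[chrom]
        if config.rate_cv > 0:
            n_blocks = -(-length // config.rate_block_bp)
            shape = 1.0 / config.rate_cv ** 2
            rates = rng.gamma(shape, 1.0 / shape, size=n_blocks)
            lam = lam * np.repeat(rates, config.rate_block_bp)[:length]
        if config.depth_dispersion is None:
            depth[chrom] = rng.poisson(lam).astype(np.int64)
        else:
            k = config.depth_dispersion
            depth[chrom] = rng.negative_binomial(k, k / (k + lam)).astype(np.int64)
    return DepthTrack(genome=genome, depth=depth,
                      sample=f"G{genotype + 1}_{sex}", sex=sex)


def sample_layout(config: SimConfig) -> tuple[tuple[str, ...], tuple[str, ...],
                                              tuple[str, ...]]:
    """Sample names, sexes and genotype labels in fixed order (F then M
    within each genotype line)."""
    samples, sexes, genotypes = [], [], []
    for g in range(config.n_genotypes):
        for sex in ("F", "M"):
            samples.append(f"G{g + 1}_{sex}")
            sexes.append(sex)
            genotypes.append(f"G{g + 1}")
    return tuple(samples), tuple(sexes), tuple(genotypes)


def _draw_positions(genome: GenomeModel, rng: np.random.Generator, n: int,
                    exclude: set[tuple[str, int]]) -> list[tuple[str, int]]:
    """n distinct random (chrom, 1-based pos) sites, avoiding ``exclude``."""
    lengths = np.array([length for _, length in genome.chromosomes],
                       dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    chosen: list[tuple[str, int]] = []
    seen = set(exclude)
    while len(chosen) < n:
        draws = rng.integers(0, total, size=max(16, 2 * (n - len(chosen))))
        for lin in draws:
            ci = int(np.searchsorted(offsets, lin, side="right") - 1)
            site = (genome.names[ci], int(lin - offsets[ci]) + 1)
            if site not in seen:
                seen.add(site)
                chosen.append(site)
                if len(chosen) == n:
                    break
    return chosen


def _gq(dp: int) -> int:
    # monotone in depth, capped at the conventional 99; only the >= 30
    # pass/fail matters downstream
    return min(99, 3 * dp)


def _dp_draw(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def _het_ad(rng: np.random.Generator, dp: int) -> tuple[int, int]:
    """Allele depths of a genuine heterozygote: balanced up to read parity."""
    alt = dp // 2 + (int(rng.integers(0, 2)) if dp % 2 else 0)
    return dp - alt, alt


def _hom_ad(rng: np.random.Generator, dp: int, hom_alt: bool,
            minor_p: float = SEQ_ERROR) -> tuple[int, int]:
    minor = int(rng.binomial(dp, minor_p))
    return (minor, dp - minor) if hom_alt else (dp - minor, minor)


def simulate_genotypes(genome: GenomeModel, scenario: ScenarioSpec,
                       config: SimConfig, n_sites: int) -> list[SiteRecord]:
    """Simulate a biallelic SNP callset for all samples.

    ``n_sites`` counts all sites including any planted sex-linked SNPs.
    Background sites draw one Hardy-Weinberg genotype per clonal line
    (shared by that line's female and male sample); with probability
    ``false_het_rate`` a site is instead error-prone: truly homozygous in
    every line, but each sample is independently miscalled heterozygous
    with low allele balance.  Inside a hemizygous target the single-copy
    sex receives one of its line's two alleles, called as a homozygote
    with halved depth.  Planted SEX_SNP sites are heterozygous in every
    sample of one sex and hemizygous for a single shared allele in the
    other.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    scenario.validate(genome)
    planted = list(scenario.sex_snp_sites)
    if len(planted) > n_sites:
        raise ValueError(f"n_sites={n_sites} is smaller than the "
                         f"{len(planted)} planted sex-linked sites")
    rng = _rng(config, _STREAM_SITES)
    samples, sexes, _ = sample_layout(config)
    n_samples = len(samples)
    interval = scenario.hemizygous_interval(genome)
    hemi_sex = scenario.hemizygous_sex

    background = _draw_positions(genome, rng, n_sites - len(planted),
                                 exclude=set(planted))
    p = config.allele_freq
    order = {chrom: i for i, chrom in enumerate(genome.names)}
    sites: list[SiteRecord] = []

    def alleles(local_rng):
        ref, alt = local_rng.choice(4, size=2, replace=False)
        return str(_BASES[ref]), str(_BASES[alt])

    for chrom, pos in background:
        ref, alt = alleles(rng)
        in_hemi = (interval is not None and chrom == interval[0]
                   and interval[1] <= pos <= interval[2])
        error_prone = rng.random() < scenario.false_het_rate
        if error_prone:
            line_gt = np.full(config.n_genotypes, HOM_REF)
        else:
            u = rng.random(config.n_genotypes)
            line_gt = np.where(u < p * p, HOM_REF,
                               np.where(u < p * p + 2 * p * (1 - p),
                                        HET, HOM_ALT))
        gt = np.empty(n_samples, dtype=np.int64)
        dp = np.empty(n_samples, dtype=np.int64)
        gq = np.empty(n_samples, dtype=np.int64)
        ad = np.empty((n_samples, 2), dtype=np.int64)
        for i in range(n_samples):
            g = int(line_gt[i // 2])
            hemi = in_hemi and sexes[i] == hemi_sex
            if hemi and g == HET:
                g = HOM_REF if rng.random() < 0.5 else HOM_ALT
            mean = config.mean_depth / 2 if hemi else config.mean_depth
            d = _dp_draw(rng, mean)
            if error_prone and rng.random() < FALSE_HET_SAMPLE_P:
                g = HET
                alt_reads = int(rng.binomial(d, config.error_minor_fraction))
                pair = (d - alt_reads, alt_reads)
            elif g == HET:
                pair = _het_ad(rng, d)
            else:
                minor_p = (config.error_minor_fraction / 2 if error_prone
                           else SEQ_ERROR)
                pair = _hom_ad(rng, d, hom_alt=(g == HOM_ALT), minor_p=minor_p)
            gt[i], dp[i], gq[i], ad[i] = g, d, _gq(d), pair
        sites.append(SiteRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                samples=samples, sexes=sexes,
                                gt=gt, dp=dp, gq=gq, ad=ad))

    het_sex = "F" if scenario.sex_snp_pattern == "female_het" else "M"
    for chrom, pos in planted:
        ref, alt = alleles(rng)
        hemi_allele = HOM_REF if rng.random() < 0.5 else HOM_ALT
        gt = np.empty(n_samples, dtype=np.int64)
        dp = np.empty(n_samples, dtype=np.int64)
        gq = np.empty(n_samples, dtype=np.int64)
        ad = np.empty((n_samples, 2), dtype=np.int64)
        for i in range(n_samples):
            if sexes[i] == het_sex:
                d = _dp_draw(rng, config.mean_depth)
                g = HET
                pair = _het_ad(rng, d)
            else:
                d = _dp_draw(rng, config.mean_depth / 2)
                g = hemi_allele
                pair = _hom_ad(rng, d, hom_alt=(g == HOM_ALT))
            gt[i], dp[i], gq[i], ad[i] = g, d, _gq(d), pair
        sites.append(SiteRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                samples=samples, sexes=sexes,
                                gt=gt, dp=dp, gq=gq, ad=ad))

    sites.sort(key=lambda s: (order[s.chrom], s.pos))
    return sites


def simulate_pair_tracks(genome: GenomeModel, scenario: ScenarioSpec,
                         config: SimConfig, genotype: int = 0,
                         ) -> tuple[DepthTrack, DepthTrack]:
    """Female and male depth tracks for one genotype line."""
    return (simulate_depth(genome, scenario, config, "F", genotype),
            simulate_depth(genome, scenario, config, "M", genotype))


def write_outputs(tracks: list[DepthTrack], sites: list[SiteRecord],
                  directory: str | os.PathLike, genome: GenomeModel,
                  scenario: ScenarioSpec | None = None,
                  config: SimConfig | None = None,
                  bedgraph: bool = False) -> dict[str, str]:
    """Write simulator outputs in the formats the analysis consumes.

    Emits one depth TSV (or bedGraph) per track, a VCF with the genotype
    matrix, the sex-map TSV, the genome table and a ground-truth JSON
    echoing the scenario and configuration for test harnesses.  Returns a
    name -> path mapping.
    """
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for track in tracks:
        name = track.sample or f"track{len(paths)}"
        ext = "bedgraph" if bedgraph else "depth.tsv"
        path = os.path.join(directory, f"{name}.{ext}")
        (write_bedgraph if bedgraph else write_depth_tsv)(track, path)
        paths[f"depth:{name}"] = path

    genome_path = os.path.join(directory, "genome.tsv")
    genome.to_file(genome_path)
    paths["genome"] = genome_path

    if sites:
        vcf_path = os.path.join(directory, "sites.vcf")
        write_vcf(sites, genome, vcf_path)
        paths["vcf"] = vcf_path
        samples = sites[0].samples
        sexes = sites[0].sexes
        genotypes = [s.rsplit("_", 1)[0] for s in samples]
        sex_map_path = os.path.join(directory, "sex_map.tsv")
        write_sex_map(list(samples), list(sexes), genotypes, sex_map_path)
        paths["sex_map"] = sex_map_path

    truth = {
        "scenario": _scenario_dict(scenario) if scenario else None,
        "config": dataclasses.asdict(config) if config else None,
        "planted_sites": ([[c, p] for c, p in scenario.sex_snp_sites]
                          if scenario else []),
        "n_sites": len(sites),
        "tracks": [t.sample for t in tracks],
    }
    truth_path = os.path.join(directory, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    paths["truth"] = truth_path
    return paths


def _scenario_dict(scenario: ScenarioSpec) -> dict:
    d = dataclasses.asdict(scenario)
    d["architecture"] = scenario.architecture.value
    return d
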