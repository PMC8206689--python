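"""Per-site male-female differentiation scan on filtered biallelic SNPs.

Sites are screened with genotype-level quality rules (per-sample depth
between 10 and 100, genotype quality at least 30, no missing calls), then
the Weir & Cockerham (1984) per-site fixation index theta is estimated
between the female and male sample groups.  A SNP that perfectly separates
the sexes by zygosity -- all of one sex heterozygous, all of the other
homozygous for one allele -- attains theta = 0.5 with three samples per
sex, the maximum the screen is expected to surface for a sex-linked
polymorphism under this design.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_BASES = ("A", "C", "G", "T")


@dataclass
class SiteRecord:
    """One candidate variant site with per-sample calls.

    ``gt`` uses integer codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing);
    ``ad`` is an (n_samples, 2) array of (ref reads, alt reads).  Sample
    order is fixed and shared across sites; ``sexes`` holds 'F'/'M' labels
    aligned with ``samples``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    samples: tuple[str, ...]
    sexes: tuple[str, ...]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        if len(self.sexes) != n:
            raise ValueError("sexes and samples have different lengths")
        self.gt = np.asarray(self.gt, dtype=np.int64)
        self.dp = np.asarray(self.dp, dtype=np.int64)
        self.gq = np.asarray(self.gq, dtype=np.int64)
        self.ad = np.asarray(self.ad, dtype=np.int64)
        if self.gt.shape != (n,) or self.dp.shape != (n,) or self.gq.shape != (n,):
            raise ValueError("per-sample arrays must have one entry per sample")
        if self.ad.shape != (n, 2):
            raise ValueError("ad must be an (n_samples, 2) array")

    @property
    def is_biallelic_snp(self) -> bool:
        return (len(self.ref) == 1 and len(self.alt) == 1
                and self.ref in _BASES and self.alt in _BASES
                and self.ref != self.alt)

    def sex_indices(self, sex: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sexes) if s == sex])

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def site_passes(site: SiteRecord, min_dp: int = 10, max_dp: int = 100,
                min_gq: int = 30) -> bool:
    """Quality rule for one site: biallelic SNP, every sample called,
    min_dp <= DP <= max_dp and GQ >= min_gq for every sample."""
    if not site.is_biallelic_snp:
        return False
    if np.any(site.gt == MISSING):
        return False
    if np.any(site.dp < min_dp) or np.any(site.dp > max_dp):
        return False
    if np.any(site.gq < min_gq):
        return False
    return True


def filter_sites(sites: list[SiteRecord], min_dp: int = 10, max_dp: int = 100,
                 min_gq: int = 30) -> list[SiteRecord]:
    """Keep sites passing all genotype-level quality rules (see site_passes)."""
    if min_dp <= 0 or max_dp <= 0 or min_gq <= 0:
        raise ValueError("thresholds must be positive")
    if min_dp > max_dp:
        raise ValueError("min_dp must not exceed max_dp")
    return [s for s in sites if site_passes(s, min_dp, max_dp, min_gq)]


@dataclass
class FstRecord:
    """Per-site Weir-Cockerham variance components between two groups.

    a: among-group, b: among-individual-within-group, c: within-individual;
    theta = a / (a + b + c), undefined (NaN) when the site is monomorphic
    across both groups so that a + b + c = 0.
    """

    chrom: str
    pos: int
    n_f: int
    n_m: int
    p_f: float
    p_m: float
    h_f: float
    h_m: float
    counts_f: tuple[int, int, int]  # (hom_ref, het, hom_alt)
    counts_m: tuple[int, int, int]
    a: float
    b: float
    c: float
    theta: float
    defined: bool

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _group_stats(gt: np.ndarray) -> tuple[int, float, float, tuple[int, int, int]]:
    called = gt[gt != MISSING]
    n = len(called)
    if n == 0:
        raise ValueError("empty group after removing missing genotypes")
    n_rr = int(np.sum(called == HOM_REF))
    n_ra = int(np.sum(called == HET))
    n_aa = int(np.sum(called == HOM_ALT))
    p = (2 * n_rr + n_ra) / (2 * n)  # reference-allele frequency
    h = n_ra / n                     # observed heterozygote proportion
    return n, p, h, (n_rr, n_ra, n_aa)


def wc_fst(site: SiteRecord) -> FstRecord:
    """Weir & Cockerham (1984) per-site theta between females and males.

    Two-allele, two-population form with the a/b/c variance components;
    negative components (and thetas) are reported as computed, matching the
    convention of the standard VCF tooling.  Hemizygous calls arrive as
    diploid homozygotes and are treated as such, which is exactly how a
    diploid-prior caller presents them.

    Genotype counts are integers, so every component is a rational number;
    the components are evaluated in exact rational arithmetic and converted
    to float at the end.  This keeps boundary comparisons (a candidate
    threshold applied strictly) and the worked values (0.5 for a fully
    sex-divided site) free of rounding drift.
    """
    f_idx = site.sex_indices("F")
    m_idx = site.sex_indices("M")
    if len(f_idx) == 0 or len(m_idx) == 0:
        raise ValueError("both sex groups must be non-empty")
    n1, p1f, h1f, counts_f = _group_stats(site.gt[f_idx])
    n2, p2f, h2f, counts_m = _group_stats(site.gt[m_idx])

    p1 = Fraction(2 * counts_f[0] + counts_f[1], 2 * n1)
    p2 = Fraction(2 * counts_m[0] + counts_m[1], 2 * n2)
    h1 = Fraction(counts_f[1], n1)
    h2 = Fraction(counts_m[1], n2)

    r = 2
    nbar = Fraction(n1 + n2, r)
    nc = (r * nbar - Fraction(n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * Fraction(r - 1, r)
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * Fraction(r - 1, r)
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2

    denom = a + b + c
    defined = denom != 0
    theta = float(a / denom) if defined else float("nan")
    return FstRecord(chrom=site.chrom, pos=site.pos, n_f=n1, n_m=n2,
                     p_f=p1f, p_m=p2f, h_f=h1f, h_m=h2f,
                     counts_f=counts_f, counts_m=counts_m,
                     a=float(a), b=float(b), c=float(c), theta=theta,
                     defined=defined)


def zygosity_pattern(record: FstRecord) -> str:
    """Compact per-sex zygosity annotation, e.g. 'F:all_het|M:all_hom_alt'."""
    def describe(counts: tuple[int, int, int], n: int) -> str:
        labels = ("hom_ref", "het", "hom_alt")
        present = [(label, k) for label, k in zip(labels, counts) if k > 0]
        if len(present) == 1 and present[0][1] == n:
            return f"all_{present[0][0]}"
        return "+".join(f"{k}x{label}" for label, k in present) or "none"
    return (f"F:{describe(record.counts_f, sum(record.counts_f))}"
            f"|M:{describe(record.counts_m, sum(record.counts_m))}")


def is_sex_divided(record: FstRecord) -> bool:
    """True when one sex is entirely heterozygous and the other entirely
    homozygous -- the zygosity signature a sex-linked SNP would show."""
    f_hom = record.counts_f[0] + record.counts_f[2]
    m_hom = record.counts_m[0] + record.counts_m[2]
    n_f, n_m = sum(record.counts_f), sum(record.counts_m)
    f_all_het = record.counts_f[1] == n_f
    m_all_het = record.counts_m[1] == n_m
    return (f_all_het and m_hom == n_m) or (m_all_het and f_hom == n_f)


def rank_and_extract(records: list[FstRecord],
                     candidate_threshold: float = 0.25,
                     ) -> tuple[pd.DataFrame, list[FstRecord]]:
    """Rank sites by theta (descending) and extract candidates above threshold.

    Candidates are defined records with theta strictly greater than the
    threshold; ties in theta are broken by chromosome then position so the
    ranking is reproducible.  Each row carries the per-sex zygosity pattern.
    """
    ordered = sorted(
        records,
        key=lambda rec: (-(rec.theta if rec.defined and np.isfinite(rec.theta)
                           else -np.inf), rec.chrom, rec.pos))
    table = pd.DataFrame([{
        "chrom": rec.chrom,
        "pos": rec.pos,
        "theta": rec.theta,
        "defined": rec.defined,
        "n_F": rec.n_f,
        "n_M": rec.n_m,
        "p_F": rec.p_f,
        "p_M": rec.p_m,
        "pattern": zygosity_pattern(rec),
        "sex_divided": is_sex_divided(rec),
    } for rec in ordered])
    candidates = [rec for rec in ordered
                  if rec.defined and np.isfinite(rec.theta)
                  and rec.theta > candidate_threshold]
    return table, candidates
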