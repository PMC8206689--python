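"""Reliability review of candidate sex-associated SNPs from allele depths.

Short-read heterozygote calls in repetitive or mis-mapped regions tend to
show grossly unbalanced allele depths (a minor-allele fraction around 0.15
instead of the ~0.5 a genuine diploid heterozygote produces), while the
paired homozygote calls carry stray minor-allele reads.  This module turns
that manual review into rules: a heterozygous call is reliable only if the
ratio of the two allele read counts is at most 1.5 (minor fraction >= 0.4),
and any homozygote whose minor fraction exceeds a noise floor marks the
site as contaminated.  A separate flag notes when the zygosity pattern is
implausible under cyclic parthenogenesis, where a son is a clonal copy of
his mother: heterozygous males with homozygous females cannot arise that
way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, HOM_REF, MISSING, SiteRecord

VERDICT_SUPPORTED = "SUPPORTED"
VERDICT_ARTIFACT = "ARTIFACT_SUSPECT"

PLAUSIBLE = "CONSISTENT"
IMPLAUSIBLE = "HET_MALE_IMPLAUSIBLE"


def allele_balance(ad: tuple[int, int] | np.ndarray) -> tuple[float, float]:
    """Minor-allele fraction and major:minor read ratio for one AD pair.

    Returns (min/sum, max/min); the ratio is infinite when the minor count
    is zero.  Symmetric in the two counts.
    """
    a, b = int(ad[0]), int(ad[1])
    if a < 0 or b < 0:
        raise ValueError(f"negative read counts in AD ({a}, {b})")
    total = a + b
    if total == 0:
        raise ValueError("no reads: AD sums to zero")
    minor = min(a, b)
    major = max(a, b)
    fraction = minor / total
    ratio = np.inf if minor == 0 else major / minor
    return fraction, ratio


@dataclass
class BalanceReport:
    """Per-sample allele-balance table plus the site-level verdicts."""

    chrom: str
    pos: int
    rows: pd.DataFrame  # sample, sex, gt, ad_ref, ad_alt, minor_fraction, major_minor_ratio, reliable_het
    verdict: str
    plausibility: str


def plausibility_flag(site: SiteRecord) -> str:
    """Parthenogenesis plausibility of the zygosity pattern.

    Sons produced asexually are clonal copies of their mothers, so a SNP at
    which every male is heterozygous while every female is homozygous has no
    plausible clonal origin and is flagged; every other pattern (including
    the female-het/male-hom pattern an X-linked SNP would actually show) is
    CONSISTENT.
    """
    f_gt = [g for g, s in zip(site.gt, site.sexes) if s == "F" and g != MISSING]
    m_gt = [g for g, s in zip(site.gt, site.sexes) if s == "M" and g != MISSING]
    if not f_gt or not m_gt:
        return PLAUSIBLE
    males_all_het = all(g == HET for g in m_gt)
    females_all_hom = all(g in (HOM_REF, HOM_ALT) for g in f_gt)
    if males_all_het and females_all_hom:
        return IMPLAUSIBLE
    return PLAUSIBLE


def review_candidate(site: SiteRecord, max_ratio: float = 1.5,
                     hom_minor_floor: float = 0.1) -> BalanceReport:
    """Review one candidate site for allele-balance reliability.

    Each heterozygous call is reliable iff its major:minor read ratio is at
    most ``max_ratio``.  The site verdict is conservative: one unreliable
    heterozygote, or one homozygote whose minor-allele fraction exceeds
    ``hom_minor_floor`` (stray reads well above the sequencing-error rate),
    makes the whole site ARTIFACT_SUSPECT; otherwise it is SUPPORTED.
    """
    if max_ratio < 1:
        raise ValueError("max_ratio must be at least 1")
    rows = []
    artifact = False
    gt_names = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt",
                MISSING: "missing"}
    for i, sample in enumerate(site.samples):
        gt = int(site.gt[i])
        ad = site.ad[i]
        if gt == MISSING:
            rows.append({"sample": sample, "sex": site.sexes[i],
                         "gt": gt_names[gt], "ad_ref": int(ad[0]),
                         "ad_alt": int(ad[1]), "minor_fraction": np.nan,
                         "major_minor_ratio": np.nan, "reliable_het": None})
            continue
        try:
            fraction, ratio = allele_balance(ad)
        except ValueError as exc:
            raise ValueError(
                f"sample {sample!r} at {site.chrom}:{site.pos} has no usable "
                f"allele depths (AD={tuple(int(x) for x in ad)})") from exc
        reliable: bool | None = None
        if gt == HET:
            reliable = bool(ratio <= max_ratio)
            if not reliable:
                artifact = True
        else:
            if fraction > hom_minor_floor:
                artifact = True
        rows.append({"sample": sample, "sex": site.sexes[i],
                     "gt": gt_names[gt], "ad_ref": int(ad[0]),
                     "ad_alt": int(ad[1]), "minor_fraction": fraction,
                     "major_minor_ratio": ratio, "reliable_het": reliable})
    return BalanceReport(
        chrom=site.chrom, pos=site.pos,
        rows=pd.DataFrame(rows),
        verdict=VERDICT_ARTIFACT if artifact else VERDICT_SUPPORTED,
        plausibility=plausibility_flag(site),
    )
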