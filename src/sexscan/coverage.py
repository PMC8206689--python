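"""Windowed female/male coverage-ratio scan for hemizygous chromosomes.

In an X0 system males carry a single X, so the male read depth on the X is
half the autosomal depth; in a ZW system the female Z depth is halved.
The scan exploits this: per-position depths are masked above a repeat
cap, averaged in non-overlapping windows, standardized by each sex's
genome-wide mean coverage, and the per-window female/male ratio R is
formed.  Autosomes sit near R = 1, an X near 2, a Z near 0.5 (after the
normalization shrinkage a hemizygous chromosome occupying a fraction f of
the genome lands at 1 / (1 - f/2) x 2 x ... e.g. 1.9 rather than 2.0 for
f = 0.1).

Pipeline order: mask -> window means -> standardize & ratio -> low-female
filter -> summarize & classify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel

FLAG_LOW_FEMALE = "LOW_FEMALE"
FLAG_MALE_ZERO = "MALE_ZERO"
FLAG_PARTIAL_WINDOW = "PARTIAL_WINDOW"

CALL_AUTOSOMAL = "AUTOSOMAL"
CALL_X_LINKED = "X_LINKED"
CALL_Z_LINKED = "Z_LINKED"
CALL_AMBIGUOUS = "AMBIGUOUS"


@dataclass
class DepthTrack:
    """Per-position read depth for one sample, with an exclusion mask.

    ``depth[chrom]`` is an integer vector of length equal to the chromosome;
    ``mask[chrom]`` is boolean, True meaning the position is excluded from
    every mean.
    """

    genome: GenomeModel
    depth: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    sample: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        lengths = self.genome.lengths
        for chrom in self.depth:
            if chrom not in lengths:
                raise ValueError(f"unknown chromosome {chrom!r} in depth track")
            if len(self.depth[chrom]) != lengths[chrom]:
                raise ValueError(
                    f"depth vector for {chrom} has length {len(self.depth[chrom])}, "
                    f"expected {lengths[chrom]}")
        for chrom in self.genome.names:
            if chrom not in self.depth:
                raise ValueError(f"depth track missing chromosome {chrom!r}")
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(lengths[chrom], dtype=bool)

    def unmasked_mean(self) -> float:
        """Genome-wide mean depth over unmasked positions (C-bar)."""
        total = 0.0
        count = 0
        for chrom in self.genome.names:
            keep = ~self.mask[chrom]
            total += float(self.depth[chrom][keep].sum())
            count += int(keep.sum())
        if count == 0:
            raise ValueError("every position is masked; genome-wide mean undefined")
        return total / count


def mask_high_coverage(track: DepthTrack, cap: float = 200.0) -> DepthTrack:
    """Mask positions with depth strictly greater than ``cap``.

    The cap removes collapsed repeats and other mis-mapping hotspots whose
    depth is far above the genome average; masking is per sample, so a
    region can be usable in one sex and masked in the other.
    """
    if cap < 0:
        raise ValueError("cap must be non-negative")
    new_mask = {chrom: track.mask[chrom] | (track.depth[chrom] > cap)
                for chrom in track.genome.names}
    return replace(track, mask=new_mask)


@dataclass
class WindowMeans:
    """Per-window mean coverages for one sample plus its genome-wide mean."""

    genome: GenomeModel
    window: int
    windows: pd.DataFrame  # chrom, start, end, mean, n_unmasked, partial
    cbar: float
    sex: str = ""
    sample: str = ""


def window_means(track: DepthTrack, window: int) -> WindowMeans:
    """Mean unmasked depth in non-overlapping windows tiled from position 1.

    The terminal window of a chromosome may be shorter than ``window``; it is
    kept but flagged partial.  A window whose positions are all masked gets a
    missing (NaN) mean.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in track.genome.chromosomes:
        depth = track.depth[chrom].astype(np.float64)
        keep = ~track.mask[chrom]
        idx = np.arange(0, length, window)
        sums = np.add.reduceat(np.where(keep, depth, 0.0), idx)
        counts = np.add.reduceat(keep.astype(np.int64), idx)
        starts = idx + 1
        ends = np.minimum(idx + window, length)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "mean": means,
            "n_unmasked": counts,
            "partial": (ends - starts + 1) < window,
        }))
    df = pd.concat(rows, ignore_index=True)
    return WindowMeans(genome=track.genome, window=window, windows=df,
                       cbar=track.unmasked_mean(), sex=track.sex,
                       sample=track.sample)


@dataclass
class WindowTable:
    """Joint female/male window table with standardized ratios and flags.

    Columns: chrom, start, end, c_F, c_M (raw window means), z_F, z_M
    (window mean / sex genome-wide mean), ratio (z_F / z_M), and boolean
    flag columns ``partial``, ``low_female``, ``male_zero``.
    """

    genome: GenomeModel
    window: int
    df: pd.DataFrame
    cbar_f: float
    cbar_m: float

    def flags_string(self) -> pd.Series:
        """Human-readable flag column (semicolon-joined, '.' when clean)."""
        def join(row):
            flags = []
            if row["low_female"]:
                flags.append(FLAG_LOW_FEMALE)
            if row["male_zero"]:
                flags.append(FLAG_MALE_ZERO)
            if row["partial"]:
                flags.append(FLAG_PARTIAL_WINDOW)
            return ";".join(flags) if flags else "."
        return self.df.apply(join, axis=1)

    def unflagged(self) -> pd.DataFrame:
        df = self.df
        keep = ~(df["partial"] | df["low_female"] | df["male_zero"])
        keep &= np.isfinite(df["ratio"])
        return df[keep]


def standardize_and_ratio(female: WindowMeans, male: WindowMeans) -> WindowTable:
    """Standardize window means by sex genome-wide coverage and form F/M ratios.

    The genome-wide mean is computed from unmasked per-position depth (not
    from window means), so the depth-weighted mean of z over unmasked
    positions is exactly 1 in each sex.  Windows with a male mean of 0 are
    flagged MALE_ZERO and carry no finite ratio -- runs of them are X0
    evidence in their own right and are reported separately downstream.
    """
    if female.genome != male.genome:
        raise ValueError("female and male tracks use different genomes")
    if female.window != male.window:
        raise ValueError(f"window sizes differ: {female.window} vs {male.window}")
    if female.cbar == 0 or male.cbar == 0:
        raise ValueError("genome-wide mean coverage is zero; degenerate input")
    f = female.windows
    m = male.windows
    if not (f["chrom"].equals(m["chrom"]) and f["start"].equals(m["start"])):
        raise ValueError("window grids differ between sexes")
    z_f = f["mean"] / female.cbar
    z_m = m["mean"] / male.cbar
    male_zero = m["mean"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(male_zero, np.nan, z_f / z_m)
    df = pd.DataFrame({
        "chrom": f["chrom"],
        "start": f["start"],
        "end": f["end"],
        "c_F": f["mean"],
        "c_M": m["mean"],
        "z_F": z_f,
        "z_M": z_m,
        "ratio": ratio,
        "partial": f["partial"] | m["partial"],
        "low_female": False,
        "male_zero": male_zero.fillna(False).astype(bool),
    })
    return WindowTable(genome=female.genome, window=female.window, df=df,
                       cbar_f=female.cbar, cbar_m=male.cbar)


def filter_low_female(table: WindowTable, min_female: float = 5.0) -> WindowTable:
    """Flag windows whose female mean coverage is strictly below ``min_female``.

    Low female coverage makes the ratio denominator-style unstable, so such
    windows are dropped from ratios and summaries.  No male-side filter is
    applied: low male coverage is exactly the X0 signal being tested for.
    """
    df = table.df.copy()
    low = df["c_F"] < min_female
    low |= df["c_F"].isna()
    df["low_female"] = low
    df.loc[low, "ratio"] = np.nan
    return replace(table, df=df)


@dataclass(frozen=True)
class ClassificationBands:
    """Median-ratio bands mapping chromosomes to calls.

    Bands are roughly symmetric on the log scale around the ploidy
    expectations (1, 2 and 0.5) and wide enough to absorb the shrinkage a
    hemizygous chromosome induces in the genome-wide normalization.
    """

    autosomal: tuple[float, float] = (0.8, 1.2)
    x_linked: tuple[float, float] = (1.6, 2.4)
    z_linked: tuple[float, float] = (0.4, 0.6)

    def call(self, median_ratio: float) -> str:
        if not np.isfinite(median_ratio):
            return CALL_AMBIGUOUS
        lo, hi = self.autosomal
        if lo <= median_ratio <= hi:
            return CALL_AUTOSOMAL
        lo, hi = self.x_linked
        if lo <= median_ratio <= hi:
            return CALL_X_LINKED
        lo, hi = self.z_linked
        if lo <= median_ratio <= hi:
            return CALL_Z_LINKED
        return CALL_AMBIGUOUS


DEFAULT_BANDS = ClassificationBands()


@dataclass
class CoverageSummary:
    """Per-chromosome calls plus genome-wide ratio statistics."""

    per_chromosome: pd.DataFrame  # chrom, n_windows, median_ratio, mean_ratio, sd_ratio, call
    genome_mean: float
    genome_sd: float
    outliers: pd.DataFrame
    male_zero_runs: pd.DataFrame
    window: int = 0


def _male_zero_runs(df: pd.DataFrame) -> pd.DataFrame:
    """Run-length report of consecutive MALE_ZERO windows per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        flags = sub["male_zero"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                rows.append({"chrom": chrom, "start": int(starts[i]),
                             "end": int(ends[j]), "n_windows": j - i + 1})
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


def summarize_and_classify(table: WindowTable,
                           bands: ClassificationBands = DEFAULT_BANDS,
                           ) -> CoverageSummary:
    """Classify chromosomes from the median window ratio and list outliers.

    The median drives the call so that a handful of artifact windows cannot
    flip a chromosome; flagged windows (partial, low-female, male-zero)
    never enter the medians or the genome-wide statistics.  Outliers are
    unflagged windows whose ratio falls outside the autosomal band.
    """
    good = table.unflagged()
    per_chrom = []
    for chrom in table.genome.names:
        sub = good[good["chrom"] == chrom]
        n = len(sub)
        if n == 0:
            warnings.warn(f"chromosome {chrom} has no usable windows; "
                          f"call is {CALL_AMBIGUOUS}", stacklevel=2)
            per_chrom.append({"chrom": chrom, "n_windows": 0,
                              "median_ratio": np.nan, "mean_ratio": np.nan,
                              "sd_ratio": np.nan, "call": CALL_AMBIGUOUS})
            continue
        med = float(sub["ratio"].median())
        per_chrom.append({
            "chrom": chrom,
            "n_windows": n,
            "median_ratio": med,
            "mean_ratio": float(sub["ratio"].mean()),
            "sd_ratio": float(sub["ratio"].std(ddof=1)) if n > 1 else 0.0,
            "call": bands.call(med),
        })
    lo, hi = bands.autosomal
    outliers = good[(good["ratio"] < lo) | (good["ratio"] > hi)].copy()
    genome_mean = float(good["ratio"].mean()) if len(good) else np.nan
    genome_sd = (float(good["ratio"].std(ddof=1)) if len(good) > 1 else 0.0)
    return CoverageSummary(
        per_chromosome=pd.DataFrame(per_chrom),
        genome_mean=genome_mean,
        genome_sd=genome_sd,
        outliers=outliers,
        male_zero_runs=_male_zero_runs(table.df),
        window=table.window,
    )


def region_report(table: WindowTable, chrom: str, start: int, end: int) -> pd.DataFrame:
    """All windows overlapping a 1-based closed interval, with ratios and flags.

    Used to interrogate a priori candidate regions (e.g. a peri-centromeric
    interval carrying an incipient W in other populations) regardless of the
    chromosome-level call.
    """
    table.genome.check_interval(chrom, start, end)
    df = table.df
    hit = (df["chrom"] == chrom) & (df["start"] <= end) & (df["end"] >= start)
    return df[hit].copy()


def coverage_pipeline(female: DepthTrack, male: DepthTrack, window: int,
                      cap: float = 200.0, min_female: float = 5.0,
                      bands: ClassificationBands = DEFAULT_BANDS,
                      ) -> tuple[WindowTable, CoverageSummary]:
    """Full scan for one female/male pair at one window size."""
    fem = mask_high_coverage(female, cap)
    mal = mask_high_coverage(male, cap)
    table = standardize_and_ratio(window_means(fem, window),
                                  window_means(mal, window))
    table = filter_low_female(table, min_female)
    return table, summarize_and_classify(table, bands)
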