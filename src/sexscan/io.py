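"""Readers and writers for the pipeline's on-disk formats.

Depth tracks travel as headerless 3-column TSV (chrom, 1-based position,
depth) -- the layout per-position depth tools emit -- or as standard
bedGraph (0-based half-open intervals).  Positions absent from a depth
file are depth 0, matching tools that skip uncovered sites.  Variants
travel as VCF 4.2 with GT:DP:GQ:AD FORMAT fields, read through cyvcf2;
sample sexes come from a 3-column sex-map TSV (sample, sex, genotype).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .genome import GenomeModel
from .variants import HET, HOM_ALT, HOM_REF, MISSING, SiteRecord

load_genome = GenomeModel.from_file


def _sniff_depth_format(path: str | os.PathLike) -> str:
    """'tsv' for 3 columns, 'bedgraph' for 4 (or a track-line header)."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("track"):
                return "bedgraph"
            ncols = len(line.split("\t"))
            if ncols == 3:
                return "tsv"
            if ncols == 4:
                return "bedgraph"
            raise ValueError(f"{path}: cannot infer depth format from a "
                             f"{ncols}-column line")
    return "tsv"  # empty file: all-zero track


def _numeric_column(raw: pd.Series, path, colname: str) -> np.ndarray:
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: line {lineno}: malformed {colname} "
                         f"value {raw.iloc[int(bad.idxmax())]!r}")
    return values.to_numpy()


def load_depth(path: str | os.PathLike, genome: GenomeModel,
               fmt: str | None = None, sample: str = "", sex: str = "",
               ) -> DepthTrack:
    """Load a per-position depth file into an all-positions DepthTrack.

    ``fmt`` is 'tsv', 'bedgraph' or None (sniffed from the first data
    line).  Unknown chromosomes and malformed lines raise with the file
    location; positions not listed get depth 0.
    """
    fmt = fmt or _sniff_depth_format(path)
    if fmt not in ("tsv", "bedgraph"):
        raise ValueError(f"unknown depth format {fmt!r}")
    names = (["chrom", "pos", "depth"] if fmt == "tsv"
             else ["chrom", "start", "end", "depth"])
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str,
                         comment=None, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    df = df[~df["chrom"].fillna("").str.startswith(("#", "track"))]
    df = df[df["chrom"].notna()]

    lengths = genome.lengths
    depth = {chrom: np.zeros(length, dtype=np.int64)
             for chrom, length in genome.chromosomes}
    if len(df):
        unknown = set(df["chrom"]) - set(lengths)
        if unknown:
            raise ValueError(f"{path}: unknown chromosome "
                             f"{sorted(unknown)[0]!r} not in genome")
        value = _numeric_column(df["depth"], path, "depth")
        if np.any(value < 0):
            raise ValueError(f"{path}: negative depth values")
        value = value.astype(np.int64)
        if fmt == "tsv":
            pos = _numeric_column(df["pos"], path, "position").astype(np.int64)
            for chrom, idx in df.groupby("chrom", sort=False).indices.items():
                p = pos[idx]
                if np.any(p < 1) or np.any(p > lengths[chrom]):
                    raise ValueError(f"{path}: position outside {chrom} "
                                     f"(length {lengths[chrom]})")
                depth[chrom][p - 1] = value[idx]
        else:
            start = _numeric_column(df["start"], path, "start").astype(np.int64)
            end = _numeric_column(df["end"], path, "end").astype(np.int64)
            for chrom, idx in df.groupby("chrom", sort=False).indices.items():
                s, e = start[idx], end[idx]
                if np.any(s < 0) or np.any(e > lengths[chrom]) or np.any(s >= e):
                    raise ValueError(f"{path}: interval outside {chrom} "
                                     f"(length {lengths[chrom]})")
                for j in range(len(idx)):
                    depth[chrom][s[j]:e[j]] = value[idx[j]]
    return DepthTrack(genome=genome, depth=depth, sample=sample, sex=sex)


def write_depth_tsv(track: DepthTrack, path: str | os.PathLike,
                    skip_zero: bool = False) -> None:
    """Write a 3-column depth TSV (chrom, 1-based pos, depth)."""
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            d = track.depth[chrom]
            pos = np.arange(1, len(d) + 1)
            if skip_zero:
                keep = d > 0
                d, pos = d[keep], pos[keep]
            np.savetxt(fh, np.column_stack([pos, d]), fmt=f"{chrom}\t%d\t%d")


def write_bedgraph(track: DepthTrack, path: str | os.PathLike) -> None:
    """Write the track run-length-encoded as standard 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            d = track.depth[chrom]
            boundaries = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(d)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{d[s]}\n")


def read_sex_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample/sex/genotype map; sexes must be 'F' or 'M'."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["sample", "sex", "genotype"], dtype=str)
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        raise ValueError(f"{path}: sex must be 'F' or 'M', got "
                         f"{df.loc[bad, 'sex'].iloc[0]!r}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample names")
    return df


def write_sex_map(samples: list[str], sexes: list[str], genotypes: list[str],
                  path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, x, g in zip(samples, sexes, genotypes):
            fh.write(f"{s}\t{x}\t{g}\n")


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(sites: list[SiteRecord], genome: GenomeModel,
              path: str | os.PathLike) -> None:
    """Write sites as minimal VCF 4.2 with GT:DP:GQ:AD per sample.

    Hemizygous calls are emitted as diploid homozygotes, the way a
    diploid-prior caller reports haploid regions.
    """
    if not sites:
        raise ValueError("no sites to write")
    samples = sites[0].samples
    order = {chrom: i for i, chrom in enumerate(genome.names)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sexscan-simulator\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
                 '"Allele read depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sorted(sites, key=lambda s: (order.get(s.chrom, 1 << 30), s.pos)):
            fields = [site.chrom, str(site.pos), ".", site.ref, site.alt,
                      ".", "PASS", ".", "GT:DP:GQ:AD"]
            for i in range(len(samples)):
                gt = _GT_STRING[int(site.gt[i])]
                fields.append(f"{gt}:{site.dp[i]}:{site.gq[i]}:"
                              f"{site.ad[i][0]},{site.ad[i][1]}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike, sex_map: pd.DataFrame,
             ) -> list[SiteRecord]:
    """Read a (possibly gzipped) VCF into SiteRecords using cyvcf2.

    Every sample in the VCF must appear in the sex map.  Multi-allelic
    records are kept (with a comma-joined ALT) so the downstream biallelic
    filter can reject them explicitly; missing FORMAT values become
    missing genotypes / zero depths.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    sex_of = dict(zip(sex_map["sample"], sex_map["sex"]))
    missing_samples = [s for s in samples if s not in sex_of]
    if missing_samples:
        raise ValueError(f"sample {missing_samples[0]!r} absent from sex map")
    sexes = tuple(sex_of[s] for s in samples)
    n = len(samples)

    gt_map = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}
    sites: list[SiteRecord] = []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        gt = np.array([gt_map.get(int(t), MISSING) for t in var.gt_types],
                      dtype=np.int64)
        dp = var.format("DP")
        dp = (np.zeros(n, dtype=np.int64) if dp is None
              else np.maximum(dp.reshape(n), 0).astype(np.int64))
        gq = var.format("GQ")
        gq = (np.zeros(n, dtype=np.int64) if gq is None
              else np.maximum(np.nan_to_num(gq.reshape(n).astype(np.float64)),
                              0).astype(np.int64))
        ad = var.format("AD")
        if ad is None:
            ad = np.zeros((n, 2), dtype=np.int64)
        else:
            ad = np.maximum(ad[:, :2], 0).astype(np.int64)
            if ad.shape[1] < 2:
                ad = np.column_stack([ad, np.zeros(n, dtype=np.int64)])
        sites.append(SiteRecord(chrom=var.CHROM, pos=var.POS, ref=var.REF,
                                alt=alt, samples=samples, sexes=sexes,
                                gt=gt, dp=dp, gq=gq, ad=ad))
    return sites
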