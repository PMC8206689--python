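"""Multi-genotype orchestration and the combined GSD verdict.

The study design asks one question -- is there any genetic difference
between the sexes? -- through three orthogonal lines of evidence: a
chromosome (or region) with a non-autosomal coverage ratio consistently
across clonal lines, outlier coverage windows shared by every line, and a
sex-divided SNP that survives the reliability review.  The merged verdict
reports each line separately and calls a GSD signal only when at least one
of them is positive; absence of signal is itself the scientifically
meaningful outcome.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .coverage import (CALL_AUTOSOMAL, ClassificationBands, CoverageSummary,
                       WindowTable, coverage_pipeline, region_report)
from .genome import GenomeModel
from .io import load_depth, load_genome, read_sex_map, read_vcf
from .validate import VERDICT_SUPPORTED, BalanceReport, review_candidate
from .variants import filter_sites, rank_and_extract, wc_fst


@dataclass
class PairFiles:
    """Input files for one genotype line (one female + one male library)."""

    label: str
    female: str
    male: str


@dataclass
class RunConfig:
    """Full-run configuration; YAML-loadable, flags override fields."""

    pairs: list[PairFiles]
    genome: str = ""
    vcf: str | None = None
    sex_map: str | None = None
    window_sizes: tuple[int, ...] = (5000, 10000)
    cap: float = 200.0
    min_female: float = 5.0
    min_dp: int = 10
    max_dp: int = 100
    min_gq: int = 30
    fst_threshold: float = 0.25
    max_ratio: float = 1.5
    hom_minor_floor: float = 0.1
    focus_regions: list[tuple[str, int, int]] = field(default_factory=list)
    out_dir: str = "sexscan_out"
    seed: int = 0
    bands: ClassificationBands = field(default_factory=ClassificationBands)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("config must list at least one female/male pair")
        if any(w <= 0 for w in self.window_sizes):
            raise ValueError("window sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pairs = [PairFiles(**p) for p in raw.pop("pairs")]
        focus = [tuple(r) for r in raw.pop("focus_regions", [])]
        window_sizes = tuple(raw.pop("window_sizes", (5000, 10000)))
        return cls(pairs=pairs, focus_regions=focus,
                   window_sizes=window_sizes, **raw)


@dataclass
class PairResult:
    label: str
    tables: dict[int, WindowTable]
    summaries: dict[int, CoverageSummary]


@dataclass
class ReportBundle:
    config: RunConfig
    genome: GenomeModel
    pairs: list[PairResult]
    fst_table: pd.DataFrame | None
    candidates: list
    validations: list[BalanceReport]
    shared_outliers: dict[int, pd.DataFrame]
    focus_reports: dict[str, pd.DataFrame]
    verdict: dict


def cross_pair_overlap(tables: list[WindowTable],
                       bands: ClassificationBands = ClassificationBands(),
                       ) -> pd.DataFrame:
    """Outlier windows shared by every pair (same window grid required).

    A window counts if it is an unflagged non-autosomal outlier in every
    table; an empty result is evidence against a shared genetic signal.
    """
    if len(tables) < 2:
        raise ValueError("cross-pair overlap needs at least two pairs")
    windows = {t.window for t in tables}
    if len(windows) != 1:
        raise ValueError(f"mismatched window sizes across pairs: {sorted(windows)}")
    lo, hi = bands.autosomal
    keys: list[set[tuple[str, int]]] = []
    for t in tables:
        good = t.unflagged()
        out = good[(good["ratio"] < lo) | (good["ratio"] > hi)]
        keys.append(set(zip(out["chrom"], out["start"])))
    shared = set.intersection(*keys)
    first = tables[0].df
    hit = [(c, s) in shared for c, s in zip(first["chrom"], first["start"])]
    return first[hit][["chrom", "start", "end"]].reset_index(drop=True)


def _stage(label: str):
    """Decorator-free helper: wrap stage errors with stage + pair context."""
    class _Ctx:
        def __init__(self, name): self.name = name
        def __enter__(self): return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
    return _Ctx(label)


def run_all(config: RunConfig) -> ReportBundle:
    """Run the coverage scan per pair and window size, then the variant scan
    and candidate review on the joint VCF, and merge the evidence."""
    genome = (config.genome if isinstance(config.genome, GenomeModel)
              else load_genome(config.genome))

    pair_results: list[PairResult] = []
    for pair in config.pairs:
        with _stage(f"coverage:{pair.label}"):
            female = load_depth(pair.female, genome, sex="F",
                                sample=f"{pair.label}_F")
            male = load_depth(pair.male, genome, sex="M",
                              sample=f"{pair.label}_M")
            tables, summaries = {}, {}
            for w in config.window_sizes:
                table, summary = coverage_pipeline(
                    female, male, w, cap=config.cap,
                    min_female=config.min_female, bands=config.bands)
                tables[w] = table
                summaries[w] = summary
        pair_results.append(PairResult(pair.label, tables, summaries))

    fst_table = None
    candidates: list = []
    validations: list[BalanceReport] = []
    if config.vcf:
        with _stage("variant_scan"):
            sex_map = read_sex_map(config.sex_map)
            sites = read_vcf(config.vcf, sex_map)
            passing = filter_sites(sites, config.min_dp, config.max_dp,
                                   config.min_gq)
            records = [wc_fst(s) for s in passing]
            fst_table, candidates = rank_and_extract(records,
                                                     config.fst_threshold)
        with _stage("snp_validation"):
            by_key = {s.key(): s for s in passing}
            validations = [review_candidate(by_key[rec.key()],
                                            config.max_ratio,
                                            config.hom_minor_floor)
                           for rec in candidates]

    shared: dict[int, pd.DataFrame] = {}
    if len(pair_results) >= 2:
        for w in config.window_sizes:
            shared[w] = cross_pair_overlap(
                [p.tables[w] for p in pair_results], config.bands)

    focus: dict[str, pd.DataFrame] = {}
    for chrom, start, end in config.focus_regions:
        for p in pair_results:
            for w in config.window_sizes:
                focus[f"{p.label}:{chrom}:{start}-{end}:w{w}"] = region_report(
                    p.tables[w], chrom, start, end)

    verdict = _merged_verdict(pair_results, shared, candidates, validations,
                              config)
    return ReportBundle(config=config, genome=genome, pairs=pair_results,
                        fst_table=fst_table, candidates=candidates,
                        validations=validations, shared_outliers=shared,
                        focus_reports=focus, verdict=verdict)


def _merged_verdict(pairs: list[PairResult], shared: dict[int, pd.DataFrame],
                    candidates: list, validations: list[BalanceReport],
                    config: RunConfig) -> dict:
    """Three lines of evidence; 'GSD signal' only if at least one fires."""
    consistent: list[dict] = []
    for w in config.window_sizes:
        calls_by_chrom: dict[str, set[str]] = {}
        for p in pairs:
            for _, row in p.summaries[w].per_chromosome.iterrows():
                calls_by_chrom.setdefault(row["chrom"], set()).add(row["call"])
        for chrom, calls in calls_by_chrom.items():
            if len(calls) == 1 and (call := next(iter(calls))) != CALL_AUTOSOMAL:
                if call != "AMBIGUOUS":
                    consistent.append({"chrom": chrom, "call": call,
                                       "window": w})
    shared_nonempty = {w: len(df) for w, df in shared.items() if len(df)}
    from .variants import is_sex_divided
    supported = []
    verdict_by_key = {(v.chrom, v.pos): v.verdict for v in validations}
    for rec in candidates:
        if (is_sex_divided(rec)
                and verdict_by_key.get(rec.key()) == VERDICT_SUPPORTED):
            supported.append({"chrom": rec.chrom, "pos": rec.pos,
                              "theta": rec.theta})
    signal = bool(consistent or shared_nonempty or supported)
    return {
        "gsd_signal": signal,
        "consistent_nonautosomal_chromosomes": consistent,
        "shared_outlier_windows": {str(w): int(n)
                                   for w, n in shared_nonempty.items()},
        "supported_sex_divided_snps": supported,
        "summary": ("GSD signal detected" if signal
                    else "no GSD signal: no shared non-autosomal coverage "
                         "pattern and no supported sex-divided SNP"),
    }


def write_report(bundle: ReportBundle, out_dir: str | None = None) -> dict[str, str]:
    """Write per-pair tables, merged JSON, text summary and a run log."""
    out_dir = out_dir or bundle.config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    pair_dir = os.path.join(out_dir, "pairs")
    os.makedirs(pair_dir, exist_ok=True)
    paths: dict[str, str] = {}

    summary_json: dict = {
        "version": __version__,
        "seed": bundle.config.seed,
        "thresholds": {
            "cap": bundle.config.cap,
            "min_female": bundle.config.min_female,
            "min_dp": bundle.config.min_dp,
            "max_dp": bundle.config.max_dp,
            "min_gq": bundle.config.min_gq,
            "fst_threshold": bundle.config.fst_threshold,
            "max_ratio": bundle.config.max_ratio,
            "hom_minor_floor": bundle.config.hom_minor_floor,
        },
        "window_sizes": list(bundle.config.window_sizes),
        "pairs": {},
        "verdict": bundle.verdict,
    }

    for pair in bundle.pairs:
        pair_json: dict = {}
        for w, table in pair.tables.items():
            base = os.path.join(pair_dir, f"{pair.label}.w{w}")
            df = table.df.copy()
            df["flags"] = table.flags_string()
            df.drop(columns=["partial", "low_female", "male_zero"]).to_csv(
                f"{base}.windows.tsv", sep="\t", index=False,
                float_format="%.6g")
            summary = pair.summaries[w]
            summary.per_chromosome.to_csv(f"{base}.chromosomes.tsv",
                                          sep="\t", index=False,
                                          float_format="%.6g")
            with open(f"{base}.outliers.bed", "w") as fh:
                for _, row in summary.outliers.iterrows():
                    fh.write(f"{row['chrom']}\t{row['start'] - 1}"
                             f"\t{row['end']}\tratio={row['ratio']:.4g}\n")
            paths[f"{pair.label}:w{w}:windows"] = f"{base}.windows.tsv"
            pair_json[str(w)] = {
                "genome_mean_ratio": summary.genome_mean,
                "genome_sd_ratio": summary.genome_sd,
                "calls": dict(zip(summary.per_chromosome["chrom"],
                                  summary.per_chromosome["call"])),
                "n_outlier_windows": int(len(summary.outliers)),
                "male_zero_runs": int(len(summary.male_zero_runs)),
            }
        summary_json["pairs"][pair.label] = pair_json

    if bundle.fst_table is not None:
        fst_path = os.path.join(out_dir, "fst.tsv")
        bundle.fst_table.to_csv(fst_path, sep="\t", index=False,
                                float_format="%.6g")
        paths["fst"] = fst_path
        cand_rows = []
        verdicts = {(v.chrom, v.pos): v for v in bundle.validations}
        for rec in bundle.candidates:
            v = verdicts.get(rec.key())
            cand_rows.append({
                "chrom": rec.chrom, "pos": rec.pos, "theta": rec.theta,
                "pattern": next(iter(bundle.fst_table[
                    (bundle.fst_table["chrom"] == rec.chrom)
                    & (bundle.fst_table["pos"] == rec.pos)]["pattern"]), ""),
                "verdict": v.verdict if v else "",
                "plausibility": v.plausibility if v else "",
            })
        cand_path = os.path.join(out_dir, "candidates.tsv")
        pd.DataFrame(cand_rows, columns=["chrom", "pos", "theta", "pattern",
                                         "verdict", "plausibility"]).to_csv(
            cand_path, sep="\t", index=False, float_format="%.6g")
        paths["candidates"] = cand_path
        if bundle.validations:
            balance = pd.concat(
                [v.rows.assign(chrom=v.chrom, pos=v.pos)
                 for v in bundle.validations], ignore_index=True)
            bal_path = os.path.join(out_dir, "balance_report.tsv")
            balance.to_csv(bal_path, sep="\t", index=False,
                           float_format="%.6g")
            paths["balance"] = bal_path
        summary_json["n_sites_ranked"] = int(len(bundle.fst_table))
        summary_json["n_candidates"] = len(bundle.candidates)

    for name, df in bundle.focus_reports.items():
        safe = name.replace(":", "_").replace("-", "_")
        path = os.path.join(out_dir, f"focus.{safe}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[f"focus:{name}"] = path

    json_path = os.path.join(out_dir, "summary.json")
    with open(json_path, "w") as fh:
        json.dump(summary_json, fh, indent=2, sort_keys=True)
    paths["json"] = json_path

    txt_path = os.path.join(out_dir, "summary.txt")
    with open(txt_path, "w") as fh:
        fh.write(_text_summary(bundle, summary_json))
    paths["text"] = txt_path

    log_path = os.path.join(out_dir, "run.log")
    with open(log_path, "w") as fh:
        fh.write(f"sexscan {__version__} (python {sys.version.split()[0]})\n")
        fh.write(f"seed: {bundle.config.seed}\n")
        for key, value in summary_json["thresholds"].items():
            fh.write(f"threshold {key}: {value}\n")
        fh.write(f"window_sizes: {list(bundle.config.window_sizes)}\n")
        for pair in bundle.config.pairs:
            fh.write(f"pair {pair.label}: F={pair.female} M={pair.male}\n")
        if bundle.config.vcf:
            fh.write(f"vcf: {bundle.config.vcf}\n")
    paths["log"] = log_path
    return paths


def _text_summary(bundle: ReportBundle, summary_json: dict) -> str:
    lines = ["sexscan combined report", "======================", ""]
    for label, per_window in summary_json["pairs"].items():
        for w, stats in per_window.items():
            lines.append(
                f"pair {label}, {int(w)} bp windows: genome-wide mean "
                f"coverage ratio {stats['genome_mean_ratio']:.3f} "
                f"(standard deviation {stats['genome_sd_ratio']:.3f}), "
                f"{stats['n_outlier_windows']} outlier windows")
            non_auto = {c: call for c, call in stats["calls"].items()
                        if call != CALL_AUTOSOMAL}
            if non_auto:
                lines.append(f"  non-autosomal calls: {non_auto}")
    if "n_candidates" in summary_json:
        lines.append("")
        lines.append(f"variant scan: {summary_json['n_sites_ranked']} sites "
                     f"ranked, {summary_json['n_candidates']} candidates "
                     f"above the Fst threshold")
        for v in bundle.validations:
            lines.append(f"  candidate {v.chrom}:{v.pos}: {v.verdict}, "
                         f"{v.plausibility}")
    lines.append("")
    lines.append(f"VERDICT: {bundle.verdict['summary']}")
    lines.append("")
    return "\n".join(lines)


def plot_ratios(table: WindowTable, path: str) -> None:
    """Optional per-chromosome scatter of window ratios (one panel row)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = table.genome.names
    fig, axes = plt.subplots(1, len(names), figsize=(2.2 * len(names), 2.8),
                             sharey=True)
    if len(names) == 1:
        axes = [axes]
    good = table.unflagged()
    for ax, chrom in zip(axes, names):
        sub = good[good["chrom"] == chrom]
        ax.scatter(sub["start"] / 1e6, sub["ratio"], s=4, alpha=0.5)
        ax.axhline(1.0, color="grey", lw=0.5)
        ax.axhline(2.0, color="red", lw=0.5, ls="--")
        ax.set_title(chrom, fontsize=8)
        ax.set_xlabel("Mb", fontsize=7)
    axes[0].set_ylabel("female/male ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
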