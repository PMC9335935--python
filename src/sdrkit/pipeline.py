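"""End-to-end orchestration: filter → window statistics → SDR scan → tree share.

Every output TSV starts with a provenance comment naming the package version
and a hash of the run configuration; per-stage site counts go to the run log.
Outputs are deterministic for a fixed configuration and input bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, sdr_snp, tree_share, window_stats
from .errors import ConfigurationError, SdrkitError
from .variant_io import FilterConfig, SampleSheet, apply_site_filters, config_hash, read_vcf

log = logging.getLogger("sdrkit")


@dataclass
class RunConfig:
    """Inputs, thresholds and window widths for a full run."""

    vcf: str
    sheet: str
    out_dir: str
    depth: str | None = None
    sex_chrom: str = "chr12"
    autosomes: list = field(default_factory=list)
    filters: FilterConfig = field(default_factory=FilterConfig)
    stat_window: int = 100_000  # F_ST, density ratios, per-window densities
    min_per_sex: int = 2
    focal: tuple = ("picta", "wingei")
    outgroups: tuple = ("latipinna", "holbrooki")
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.filters, dict):
            self.filters = FilterConfig(**self.filters)
        self.focal = tuple(self.focal)
        self.outgroups = tuple(self.outgroups)
        if self.sex_chrom in set(self.autosomes):
            raise ConfigurationError("sex chromosome label also listed as an autosome")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_tsv(frame: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sdrkit {__version__} config={tag}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_full(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of output paths and the
    hypothesis verdict (when the tree-share stage could run)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash analysis parameters only, so reruns into another directory compare equal
    params = {k: v for k, v in dataclasses.asdict(cfg).items() if k not in ("vcf", "sheet", "depth", "out_dir")}
    tag = config_hash(sorted(params.items()))
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    bundle: dict = {"out_dir": str(out)}
    try:
        stage = "read_inputs"
        sheet = SampleSheet.read_tsv(cfg.sheet)
        gt = read_vcf(cfg.vcf, sheet)
        log.info("input sites: %d, samples: %d", gt.n_sites, gt.n_samples)

        stage = "filter"
        gt, report = apply_site_filters(gt, cfg.filters)
        for name, removed in report.stages:
            log.info("filter %s removed %d sites", name, removed)
        log.info("filtered sites: %d (genotypes masked: %d)", gt.n_sites, report.genotypes_masked)
        _write_tsv(report.to_frame(), out / "filter_report.tsv", tag)
        bundle["filter_report"] = str(out / "filter_report.tsv")

        chrom_lengths = {
            chrom: int(grp["pos"].max()) for chrom, grp in gt.sites.groupby("chrom", sort=False)
        }
        autosomes = cfg.autosomes or [c for c in chrom_lengths if c != cfg.sex_chrom]
        windows = window_stats.make_windows(chrom_lengths, cfg.stat_window)

        stage = "window_stats"
        species_with_sexes = [
            sp
            for sp in dict.fromkeys(sheet.table["species"])
            if sheet.males(sp) and sheet.females(sp)
        ]
        n_undefined = 0
        for sp in species_with_sexes:
            table = window_stats.build_window_table(
                gt, sheet, windows, species=sp, min_per_sex=cfg.min_per_sex
            )
            auto_mask = table["chrom"].isin(autosomes).to_numpy()
            env_rows = []
            for stat in ("fst", "snp_density_ratio", "sdr_like_density", "female_specific_density"):
                try:
                    env = window_stats.autosomal_envelope(table.loc[auto_mask, stat])
                    env_rows.append((stat, env.lower, env.upper))
                except ConfigurationError as exc:
                    log.warning("envelope for %s/%s skipped: %s", sp, stat, exc)
            n_undefined += int(table["fst"].isna().sum())
            _write_tsv(table, out / f"window_stats_{sp}.tsv", tag)
            _write_tsv(
                pd.DataFrame(env_rows, columns=["statistic", "lower", "upper"]),
                out / f"envelopes_{sp}.tsv",
                tag,
            )
            bundle[f"window_stats_{sp}"] = str(out / f"window_stats_{sp}.tsv")
            if cfg.depth is not None:
                depth = window_stats.read_depth_tsv(cfg.depth)
                ratio = window_stats.depth_ratio_windows(depth, sheet, autosomes, species=sp)
                _write_tsv(ratio, out / f"depth_ratio_{sp}.tsv", tag)
                bundle[f"depth_ratio_{sp}"] = str(out / f"depth_ratio_{sp}.tsv")
        log.info("undefined fst windows across species tables: %d", n_undefined)

        stage = "sdr_snp"
        for sp in species_with_sexes:
            calls = sdr_snp.classify_sites(gt, sheet, species=sp, min_per_sex=cfg.min_per_sex)
            frame = gt.sites[["chrom", "pos"]].copy()
            frame["status"] = calls["status"].to_numpy()
            frame["y_like_allele"] = calls["y_like_allele"].to_numpy()
            _write_tsv(frame, out / f"sdr_calls_{sp}.tsv", tag)
            fp = sdr_snp.autosomal_fp_rate(
                gt, sheet, autosomes, species=sp, min_per_sex=cfg.min_per_sex
            )
            log.info("autosomal SDR-like rate for %s: %.6f", sp, fp)
            bundle[f"sdr_calls_{sp}"] = str(out / f"sdr_calls_{sp}.tsv")

        stage = "tree_share"
        summary_payload: dict = {"sdrkit": __version__, "config": tag}
        focal_ok = all(
            len(sheet.males(sp)) >= cfg.min_per_sex and len(sheet.females(sp)) >= cfg.min_per_sex
            for sp in cfg.focal
        ) and all(sheet.ids(species=sp) for sp in cfg.outgroups)
        if focal_ok:
            sex_mask = (gt.sites["chrom"] == cfg.sex_chrom).to_numpy()
            tc = tree_share.run_treeshare(
                gt.subset_sites(sex_mask),
                sheet,
                min_per_sex=cfg.min_per_sex,
                focal=cfg.focal,
                outgroups=cfg.outgroups,
            )
            summary = tree_share.summarize_hypotheses(tc)
            _write_tsv(tc.per_site, out / "treeshare_sites.tsv", tag)
            _write_tsv(tc.counts_frame(), out / "tree_counts.tsv", tag)
            log.info(
                "tree share: %d sites, %d informative, verdict %s",
                tc.n_sites,
                tc.n_informative,
                summary.verdict,
            )
            summary_payload.update(summary.to_dict())
            summary_payload["uninformative"] = dict(sorted(tc.uninformative.items()))
            bundle["verdict"] = summary.verdict
        else:
            log.warning("tree-share stage skipped: focal/outgroup sample minima not met")
            summary_payload["verdict"] = "not_run"
        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary_payload, fh, sort_keys=True)
        bundle["summary"] = str(out / "summary.yaml")
        return bundle
    except SdrkitError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
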