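"""Scenario simulator: genotypes, depths and per-site truth under explicit
sex-chromosome histories.

The generator draws per-site mutations as Poisson events on the branches of a
fixed four-tip gametolog tree (Xp, Yp, Xw, Yw — the X and Y of *M. picta*
and *P. wingei*), so every SDR site carries a derived allele on exactly the
chromosomes below its mutated branch(es).  Y-labelled branches carry a
male-bias rate multiplier α.  Sites outside the SDR (pseudoautosomal region
and autosomes) are exchangeable between X and Y: a shared allele frequency
drawn from a symmetric Beta with Hardy–Weinberg genotypes and no sex
linkage.  Females are assembled as X/X, males as X/Y; outgroup individuals
carry the ancestral allele.

Artifact layer, mirroring how diploid variant callers behave on degenerate
Y chromosomes: with probability ``d_p`` an SDR site is deleted on Yp — every
*M. picta* male is then recorded as the homozygote for his X allele (the
hemizygote-imputation artifact) and his per-site depth halves; a
mapping-failure rate further thins male window depth inside the SDR.  A
per-genotype error rate flips single allele copies.  Per-window read depth
is Poisson with mean λ × window × copies/2.

Randomness is counter-based: each site and window derives its own Philox
substream from the master seed, so enlarging a simulation never perturbs
sites already generated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .variant_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable, SampleSheet
from .tree_share import TREE_OF_PATTERN, pattern_str
from . import window_stats

SCENARIOS = ("homologous", "independent", "turnover_wingei", "autosome")
_BASES = np.array(list("ACGT"))

# Philox stream labels
_STREAM_POSITIONS = 0
_STREAM_SITES = 1
_STREAM_WINDOWS = 2


@dataclass
class Branch:
    name: str
    tips: frozenset
    length: float
    is_y: bool

    def rate(self, mu: float, alpha: float) -> float:
        return mu * self.length * (alpha if self.is_y else 1.0)


@dataclass
class ScenarioConfig:
    """Generative parameters for one sex-chromosome history scenario.

    Times are in arbitrary coalescent-style units (the analysis only ever
    sees their ratios through relative branch lengths); ``mu`` is the
    expected number of mutations per site per unit time on a branch.
    Default cohort sizes follow the resequencing design the analysis targets:
    3 males and 3 females per focal species plus one individual per outgroup
    species.
    """

    scenario: str
    t_s: float = 1.0  # focal species split
    t_sdr: float = 2.0  # ancestral SDR origin (homologous / turnover)
    t_p: float = 0.5  # M. picta SDR origin (independent)
    t_w: float = 0.5  # P. wingei SDR origin (independent)
    t_to: float = 0.5  # turnover time (turnover_wingei)
    root_stem: float = 0.0  # shared stem above the focal root (size-4 patterns)
    mu: float = 0.05
    alpha: float = 1.0  # Y-branch mutation multiplier (male-biased mutation)
    homoplasy: bool = False  # allow multiple mutated branches at one site
    d_p: float = 0.0  # Yp deletion fraction
    d_w: float = 0.0  # Yw deletion fraction
    mapping_failure: float = 0.0  # extra male depth thinning in SDR windows
    genotype_error: float = 0.0  # per-genotype single-allele flip rate
    mean_depth: float = 30.0  # λ, reads per bp per diploid genome
    samples: dict = field(default_factory=lambda: {"picta": (3, 3), "wingei": (3, 3)})
    outgroup_samples: dict = field(default_factory=lambda: {"latipinna": 1, "holbrooki": 1})
    sex_chrom: str = "chr12"
    chrom_length: int = 2_000_000
    sdr_start: int = 500_000  # 0-based inclusive
    sdr_end: int = 1_500_000  # exclusive
    autosomes: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    snp_density: float = 0.013  # segregating sites per bp
    par_beta: float = 0.5  # symmetric Beta shape for exchangeable-site frequencies
    window_width: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        for name in ("d_p", "d_w", "mapping_failure", "genotype_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.scenario != "autosome":
            if not (0 <= self.sdr_start < self.sdr_end <= self.chrom_length):
                raise ConfigurationError("SDR interval must lie inside the sex chromosome")
        self.samples = {k: tuple(v) for k, v in self.samples.items()}

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["samples"] = {k: list(v) for k, v in data["samples"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _require_times(cfg: ScenarioConfig, **conds) -> None:
    for desc, ok in conds.items():
        if not ok:
            raise ConfigurationError(f"scenario {cfg.scenario!r} requires {desc}")


def scenario_tree(cfg: ScenarioConfig) -> list[Branch]:
    """Branches of the rooted four-tip gametolog tree for the scenario.

    * homologous: ((Yp,Yw),(Xp,Xw)) — X–Y split at t_sdr in the common
      ancestor, species splits at t_s on both stems.
    * independent: ((Xp,Yp),(Xw,Yw)) — species split at t_s, each species'
      X–Y split at its own t_p / t_w.
    * turnover_wingei: (((Xw,Yw),Xp),Yp) — ancestral SDR at t_sdr whose old Y
      survives only in *M. picta*; the wingei Y derives from an X at t_to.
    """
    if cfg.scenario == "autosome":
        raise ConfigurationError("the autosome scenario has no gametolog tree")
    t_s, t_sdr = cfg.t_s, cfg.t_sdr
    if cfg.scenario == "homologous":
        _require_times(cfg, **{"t_sdr > t_s > 0": t_sdr > t_s > 0})
        branches = [
            Branch("Ystem", frozenset({"Yp", "Yw"}), t_sdr - t_s, True),
            Branch("Xstem", frozenset({"Xp", "Xw"}), t_sdr - t_s, False),
            Branch("Yp", frozenset({"Yp"}), t_s, True),
            Branch("Yw", frozenset({"Yw"}), t_s, True),
            Branch("Xp", frozenset({"Xp"}), t_s, False),
            Branch("Xw", frozenset({"Xw"}), t_s, False),
        ]
    elif cfg.scenario == "independent":
        _require_times(
            cfg, **{"0 < t_p < t_s": 0 < cfg.t_p < t_s, "0 < t_w < t_s": 0 < cfg.t_w < t_s}
        )
        branches = [
            Branch("picta_stem", frozenset({"Xp", "Yp"}), t_s - cfg.t_p, False),
            Branch("wingei_stem", frozenset({"Xw", "Yw"}), t_s - cfg.t_w, False),
            Branch("Xp", frozenset({"Xp"}), cfg.t_p, False),
            Branch("Yp", frozenset({"Yp"}), cfg.t_p, True),
            Branch("Xw", frozenset({"Xw"}), cfg.t_w, False),
            Branch("Yw", frozenset({"Yw"}), cfg.t_w, True),
        ]
    else:  # turnover_wingei
        _require_times(cfg, **{"0 < t_to < t_s < t_sdr": 0 < cfg.t_to < t_s < t_sdr})
        branches = [
            Branch("wingei_stem", frozenset({"Xw", "Yw"}), t_s - cfg.t_to, False),
            Branch("XpXwYw_stem", frozenset({"Xp", "Xw", "Yw"}), t_sdr - t_s, False),
            Branch("Yp", frozenset({"Yp"}), t_sdr, True),
            Branch("Xp", frozenset({"Xp"}), t_s, False),
            Branch("Xw", frozenset({"Xw"}), cfg.t_to, False),
            Branch("Yw", frozenset({"Yw"}), cfg.t_to, True),
        ]
    if cfg.root_stem > 0:
        branches.append(Branch("root_stem", frozenset({"Xp", "Yp", "Xw", "Yw"}), cfg.root_stem, False))
    return branches


def expected_internal_fractions(cfg: ScenarioConfig) -> dict[int, float]:
    """Expected fraction of informative sites per tree id: internal-branch
    mutation rates (μ × length, ×α on Y branches) normalised over internal
    branches."""
    branches = scenario_tree(cfg)
    internal = [b for b in branches if len(b.tips) in (2, 3)]
    total = sum(b.rate(cfg.mu, cfg.alpha) for b in internal)
    if total == 0:
        return {}
    return {TREE_OF_PATTERN[b.tips]: b.rate(cfg.mu, cfg.alpha) / total for b in internal}


def _site_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed, counter=((stream << 44) | index) << 128))


@dataclass
class SimulationResult:
    config: ScenarioConfig
    genotype_table: GenotypeTable
    sample_sheet: SampleSheet
    depth_table: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> dict:
        from pathlib import Path
        from .variant_io import write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "sim.vcf",
            "sheet": outdir / "samples.tsv",
            "depth": outdir / "depth.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "scenario.yaml",
        }
        write_vcf(self.genotype_table, self.sample_sheet, paths["vcf"])
        self.sample_sheet.to_tsv(paths["sheet"])
        self.depth_table.to_csv(paths["depth"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.config.to_yaml(paths["config"])
        return {k: str(v) for k, v in paths.items()}


def _build_sheet(cfg: ScenarioConfig) -> SampleSheet:
    records = []
    for sp, (nm, nf) in cfg.samples.items():
        records += [(f"{sp}_M{i+1}", sp, "M") for i in range(nm)]
        records += [(f"{sp}_F{i+1}", sp, "F") for i in range(nf)]
    for sp, n in cfg.outgroup_samples.items():
        records += [(f"{sp}_{i+1}", sp, "unknown") for i in range(n)]
    return SampleSheet.from_records(records)


def _positions(cfg: ScenarioConfig, chrom_index: int, length: int) -> np.ndarray:
    n = int(round(cfg.snp_density * length))
    rng = _site_rng(cfg.seed, _STREAM_POSITIONS, chrom_index)
    pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + 1
    return pos.astype(np.int64)


def _genotype_codes(n_derived: np.ndarray, derived_is_ref: bool) -> np.ndarray:
    """Diploid genotype class from per-individual derived-allele dosage."""
    alt_dosage = (2 - n_derived) if derived_is_ref else n_derived
    return alt_dosage.astype(np.int8)  # 0/1/2 == HOM_REF/HET/HOM_ALT


def simulate_scenario(cfg: ScenarioConfig) -> SimulationResult:
    """Generate (genotypes, sample sheet, window depths, truth) for a scenario.

    Deterministic under ``cfg.seed``: identical configs produce byte-identical
    outputs.  Every emitted site has exactly one truth row recording the
    generating branches, the true presence pattern, the expected tree id (or
    why the site is uninformative) and artifact flags.
    """
    sheet = _build_sheet(cfg)
    sample_ids = sheet.sample_ids
    n_samples = len(sample_ids)
    species = sheet.table["species"].to_numpy()
    sex = sheet.table["sex"].to_numpy()
    is_male = sex == "M"
    picta_male = (species == "picta") & is_male
    wingei_male = (species == "wingei") & is_male
    outgroup = np.isin(species, list(cfg.outgroup_samples))

    # Chromosome layout: sex chromosome first (unless pure-autosome scenario).
    chroms: list[tuple[str, int, bool]] = []
    if cfg.scenario != "autosome":
        chroms.append((cfg.sex_chrom, cfg.chrom_length, True))
        branches = scenario_tree(cfg)
        branch_rates = np.array([b.rate(cfg.mu, cfg.alpha) for b in branches])
    for name, length in cfg.autosomes.items():
        chroms.append((name, int(length), False))

    site_rows = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    truth_rows = []

    for chrom_index, (chrom, length, is_sex) in enumerate(chroms):
        for ordinal, pos in enumerate(_positions(cfg, chrom_index, length)):
            idx = (chrom_index << 32) | ordinal
            rng = _site_rng(cfg.seed, _STREAM_SITES, idx)
            in_sdr = is_sex and cfg.sdr_start <= pos - 1 < cfg.sdr_end

            if in_sdr:
                hits = rng.poisson(branch_rates)
                hit_idx = np.flatnonzero(hits > 0)
                if len(hit_idx) == 0:
                    continue
                if not cfg.homoplasy and len(hit_idx) > 1:
                    continue
                tips: frozenset = frozenset().union(*(branches[j].tips for j in hit_idx))
                derived_is_ref = bool(rng.random() < 0.5)
                base_idx = rng.choice(4, size=2, replace=False)

                # Per-chromosome derived indicator.
                der = {c: (c in tips) for c in ("Xp", "Yp", "Xw", "Yw")}
                n_derived = np.zeros(n_samples, dtype=np.int8)
                for sp, xc, yc in (("picta", "Xp", "Yp"), ("wingei", "Xw", "Yw")):
                    sp_mask = species == sp
                    n_derived[sp_mask & ~is_male] = 2 * der[xc]
                    n_derived[sp_mask & is_male] = der[xc] + der[yc]
                # outgroups and any other species carry the ancestral allele
                g = _genotype_codes(n_derived, derived_is_ref)

                deleted_p = bool(rng.random() < cfg.d_p)
                deleted_w = bool(cfg.d_w > 0 and rng.random() < cfg.d_w)
                if deleted_p:
                    g[picta_male] = _genotype_codes(
                        np.full(int(picta_male.sum()), 2 * der["Xp"], dtype=np.int8), derived_is_ref
                    )
                if deleted_w:
                    g[wingei_male] = _genotype_codes(
                        np.full(int(wingei_male.sum()), 2 * der["Xw"], dtype=np.int8), derived_is_ref
                    )

                lam = np.full(n_samples, cfg.mean_depth)
                if deleted_p:
                    lam[picta_male] *= 0.5
                if deleted_w:
                    lam[wingei_male] *= 0.5
            else:
                # Exchangeable site: shared frequency, Hardy-Weinberg, no linkage.
                p = rng.beta(cfg.par_beta, cfg.par_beta)
                n_derived = (rng.random((n_samples, 2)) < p).sum(axis=1).astype(np.int8)
                derived_is_ref = bool(rng.random() < 0.5)
                base_idx = rng.choice(4, size=2, replace=False)
                g = _genotype_codes(n_derived, derived_is_ref)
                tips = frozenset()
                hit_idx = np.array([], dtype=int)
                deleted_p = deleted_w = False
                lam = np.full(n_samples, cfg.mean_depth)

            err = np.zeros(n_samples, dtype=bool)
            if cfg.genotype_error > 0:
                err = rng.random(n_samples) < cfg.genotype_error
                if err.any():
                    flip_up = rng.random(n_samples) < 0.5
                    g = g.copy()
                    orig_het = g == HET
                    g[err & ~orig_het] = HET  # one allele of a homozygote flips
                    g[err & orig_het & flip_up] = HOM_ALT
                    g[err & orig_het & ~flip_up] = HOM_REF

            dp = rng.poisson(lam).astype(np.int32)
            g = np.where(dp == 0, MISSING, g).astype(np.int8)

            if not np.any((g == HET) | (g == HOM_ALT)):
                continue  # monomorphic in the reference allele: never called

            if in_sdr:
                size = len(tips)
                if size in (2, 3):
                    truth_label = str(TREE_OF_PATTERN[tips])
                else:
                    truth_label = {0: "no_derived", 1: "derived_singleton", 4: "derived_on_all"}[size]
                branch_names = "|".join(branches[j].name for j in hit_idx)
                region = "sdr"
            else:
                truth_label = "not_sdr"
                branch_names = "."
                region = "par" if is_sex else "autosome"

            site_rows.append(
                (
                    chrom,
                    int(pos),
                    _BASES[base_idx[0]],
                    _BASES[base_idx[1]],
                    60.0,
                    True,
                    True,
                    False,
                )
            )
            gts.append(g)
            dps.append(dp)
            truth_rows.append(
                (
                    chrom,
                    int(pos),
                    region,
                    branch_names,
                    pattern_str(tips) if tips else ".",
                    truth_label,
                    deleted_p,
                    deleted_w,
                    deleted_p or deleted_w,
                    bool(err.any()),
                )
            )

    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "is_snp", "is_biallelic", "is_indel"],
    )
    g_mat = np.vstack(gts) if gts else np.zeros((0, n_samples), dtype=np.int8)
    d_mat = np.vstack(dps) if dps else np.zeros((0, n_samples), dtype=np.int32)
    gt = GenotypeTable(sample_ids, sites, g_mat, d_mat)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "region",
            "branches",
            "pattern",
            "expected",
            "deleted_on_Yp",
            "deleted_on_Yw",
            "imputed",
            "error",
        ],
    )

    depth_table = _simulate_depth(cfg, sheet, chroms)
    return SimulationResult(cfg, gt, sheet, depth_table, truth)


def _simulate_depth(cfg: ScenarioConfig, sheet: SampleSheet, chroms) -> pd.DataFrame:
    """Per-window mean depth per sample: Poisson(λ × window × copies/2)/window."""
    windows = window_stats.make_windows({name: length for name, length, _ in chroms}, cfg.window_width)
    species = sheet.table["species"].to_numpy()
    is_male = (sheet.table["sex"] == "M").to_numpy()
    n_samples = len(sheet.sample_ids)
    copies_base = np.full(n_samples, 2.0)

    values = np.zeros((len(windows), n_samples))
    is_sex_chrom = {name: flag for name, _, flag in chroms}
    for w, row in enumerate(windows.itertuples(index=False)):
        copies = copies_base.copy()
        if is_sex_chrom[row.chrom] and cfg.scenario != "autosome":
            overlap = max(0, min(row.end, cfg.sdr_end) - max(row.start, cfg.sdr_start))
            f = overlap / (row.end - row.start)
            if f > 0:
                for sp, d_sp in (("picta", cfg.d_p), ("wingei", cfg.d_w)):
                    sel = (species == sp) & is_male
                    loss = d_sp + (1.0 - d_sp) * cfg.mapping_failure
                    copies[sel] = 2.0 - f * loss
        rng = _site_rng(cfg.seed, _STREAM_WINDOWS, w)
        length = row.end - row.start
        values[w] = rng.poisson(cfg.mean_depth * length * copies / 2.0) / length

    out = windows.copy()
    for j, s in enumerate(sheet.sample_ids):
        out[s] = values[:, j]
    return out
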