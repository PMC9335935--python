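"""Sliding-window male/female divergence statistics and autosomal envelopes.

Five statistics summarise X–Y differentiation using males vs. females as a
proxy for Y vs. X:

1. read-depth ratio (M:F, per-sample depths normalised by autosome-wide mean),
2. Weir & Cockerham (1984) F_ST between the sexes (ratio-of-sums over sites),
3. SNP density ratio (sites polymorphic within males : within females),
4. SDR-like SNP density (putatively Y-linked heterozygosity patterns),
5. female-specific SNP density.

Windows tile each chromosome without overlap (the last window may be short);
coordinates are BED-style 0-based half-open.  Undefined windows are reported
as NaN, never dropped.  Envelopes are the empirical 2.5%/97.5% quantiles of
a statistic over autosomal windows, with linear interpolation between order
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, DataFormatError
from .variant_io import HET, HOM_ALT, MISSING, GenotypeTable, SampleSheet
from . import sdr_snp

WINDOW_COLUMNS = ["chrom", "start", "end"]


def make_windows(chrom_lengths: Mapping[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows of ``width`` bp."""
    if width <= 0:
        raise ConfigurationError("window width must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + width, length))))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def assign_windows(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Window index for each site (−1 when a site falls in no window)."""
    out = np.full(len(sites), -1, dtype=np.int64)
    widx = windows.reset_index(drop=True)
    for chrom, grp in widx.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sel = sites["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        pos0 = sites.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        idx = grp.index.to_numpy()[np.clip(j, 0, len(ends) - 1)]
        out[np.flatnonzero(sel)] = np.where(ok, idx, -1)
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST between the sexes
# ---------------------------------------------------------------------------


class FstComponents(NamedTuple):
    a: float
    b: float
    c: float
    informative: bool
    defined: bool

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return np.nan if denom == 0 else self.a / denom


def _group_freqs(genotypes: np.ndarray):
    """Sample size, alt-allele frequency and observed het frequency per site."""
    called = genotypes >= 0
    n = called.sum(axis=1).astype(float)
    het = (genotypes == HET).sum(axis=1)
    alt = het + 2 * (genotypes == HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h, alt


def weir_cockerham_components(male_g: np.ndarray, female_g: np.ndarray):
    """Vectorised per-site Weir & Cockerham variance components for two groups.

    ``male_g`` and ``female_g`` are sites × samples genotype matrices.
    Returns arrays ``(a, b, c, informative, defined)``.  A site is *defined*
    when both groups have a called genotype and the pooled sample size
    supports the estimator (mean group size > 1); it is *informative* when
    additionally polymorphic across the pooled groups.  Monomorphic sites
    return (0, 0, 0).
    """
    male_g = np.atleast_2d(male_g)
    female_g = np.atleast_2d(female_g)
    n1, p1, h1, alt1 = _group_freqs(male_g)
    n2, p2, h2, alt2 = _group_freqs(female_g)

    defined = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    total_alt = alt1 + alt2
    total_alleles = 2 * (n1 + n2)
    poly = (total_alt > 0) & (total_alt < total_alleles)
    informative = defined & poly

    # r = 2 specialisation of the 1984 per-locus components.
    n_bar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = 2.0 * n_bar - (n1**2 + n2**2) / (2.0 * n_bar)
        p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / (2.0 * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 / 2.0 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - s2 / 2.0 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    return a, b, c, informative, defined


def site_fst_components(male_genotypes: Sequence[int], female_genotypes: Sequence[int]) -> FstComponents:
    """Single-site wrapper around :func:`weir_cockerham_components`."""
    a, b, c, informative, defined = weir_cockerham_components(
        np.asarray(male_genotypes, dtype=np.int8).reshape(1, -1),
        np.asarray(female_genotypes, dtype=np.int8).reshape(1, -1),
    )
    return FstComponents(float(a[0]), float(b[0]), float(c[0]), bool(informative[0]), bool(defined[0]))


def window_fst(
    gt: GenotypeTable,
    sheet: SampleSheet,
    windows: pd.DataFrame,
    species: str | None = None,
) -> np.ndarray:
    """Ratio-of-sums F_ST per window: Σa / Σ(a+b+c) over informative sites."""
    males = sheet.males(species)
    females = sheet.females(species)
    if not males or not females:
        raise ConfigurationError("window_fst requires at least one sample of each sex")
    a, b, c, informative, defined = weir_cockerham_components(
        gt.genotypes[:, gt.sample_index(males)], gt.genotypes[:, gt.sample_index(females)]
    )
    use = informative & defined
    widx = assign_windows(gt.sites, windows)
    num = np.zeros(len(windows))
    den = np.zeros(len(windows))
    cnt = np.zeros(len(windows))
    sel = use & (widx >= 0)
    np.add.at(num, widx[sel], a[sel])
    np.add.at(den, widx[sel], (a + b + c)[sel])
    np.add.at(cnt, widx[sel], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((cnt > 0) & (den != 0), num / np.where(den == 0, 1, den), np.nan)
    return out


# ---------------------------------------------------------------------------
# Read-depth ratio
# ---------------------------------------------------------------------------


def read_depth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_depth_tsv(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)


def depth_ratio_windows(
    depth: pd.DataFrame,
    sheet: SampleSheet,
    autosomes: Sequence[str],
    species: str | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-window M:F mean depth ratio.

    ``depth`` holds one row per window (``chrom``, ``start``, ``end``) and one
    column per sample (mean reads/bp).  With ``normalize`` each sample is
    first divided by its own autosome-wide mean depth so that library-size
    differences cancel; the raw mode is available for parity with fold
    coverage as produced by coverage tools.  Windows with zero female mean
    are NaN.
    """
    males = sheet.males(species)
    females = sheet.females(species)
    if not males or not females:
        raise ConfigurationError("depth ratio requires at least one sample of each sex")
    missing = [s for s in males + females if s not in depth.columns]
    if missing:
        raise DataFormatError(f"depth table lacks samples: {missing}")
    vals = depth[males + females].to_numpy(float)
    if normalize:
        auto = depth["chrom"].isin(autosomes).to_numpy()
        if not auto.any():
            raise ConfigurationError("normalisation needs at least one autosomal window")
        means = vals[auto].mean(axis=0)
        if np.any(means == 0):
            raise DataFormatError("a sample has zero autosome-wide mean depth")
        vals = vals / means
    m = vals[:, : len(males)].mean(axis=1)
    f = vals[:, len(males) :].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(f > 0, m / np.where(f == 0, 1, f), np.nan)
    out = depth[WINDOW_COLUMNS].copy()
    out["depth_ratio"] = ratio
    return out


# ---------------------------------------------------------------------------
# SNP density ratio and per-window densities
# ---------------------------------------------------------------------------


def _polymorphic_within(genotypes: np.ndarray) -> np.ndarray:
    """Sites where both alleles segregate among the given samples' calls."""
    called = genotypes >= 0
    alt = (genotypes == HET).sum(axis=1) + 2 * (genotypes == HOM_ALT).sum(axis=1)
    ref = 2 * called.sum(axis=1) - alt
    return (alt > 0) & (ref > 0)


def snp_density_ratio_windows(
    gt: GenotypeTable,
    sheet: SampleSheet,
    windows: pd.DataFrame,
    species: str | None = None,
) -> np.ndarray:
    """Per window: sites polymorphic within males / polymorphic within females."""
    males = sheet.males(species)
    females = sheet.females(species)
    if not males or not females:
        raise ConfigurationError("snp density ratio requires both sexes")
    poly_m = _polymorphic_within(gt.genotypes[:, gt.sample_index(males)])
    poly_f = _polymorphic_within(gt.genotypes[:, gt.sample_index(females)])
    widx = assign_windows(gt.sites, windows)
    num = np.zeros(len(windows))
    den = np.zeros(len(windows))
    ok = widx >= 0
    np.add.at(num, widx[ok & poly_m], 1)
    np.add.at(den, widx[ok & poly_f], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den == 0, 1, den), np.nan)


def counts_per_window(sites: pd.DataFrame, windows: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Number of masked sites falling in each window."""
    widx = assign_windows(sites, windows)
    out = np.zeros(len(windows))
    sel = (widx >= 0) & np.asarray(mask, bool)
    np.add.at(out, widx[sel], 1)
    return out


# ---------------------------------------------------------------------------
# Envelopes and smoothing
# ---------------------------------------------------------------------------


@dataclass
class Envelope:
    """2.5%/97.5% quantile band of a statistic over autosomal windows."""

    lower: float
    upper: float

    def outside(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, float)
        return (v < self.lower) | (v > self.upper)


def autosomal_envelope(values: Sequence[float], min_windows: int = 40) -> Envelope:
    """Empirical (2.5%, 97.5%) quantiles with linear interpolation.

    Undefined (NaN) windows are excluded; fewer than ``min_windows`` defined
    windows is an error — simulate or tile more autosome.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) < min_windows:
        raise ConfigurationError(
            f"only {len(v)} defined autosomal windows (< {min_windows}); enlarge the autosomal set"
        )
    lo, hi = np.quantile(v, [0.025, 0.975], method="linear")
    return Envelope(float(lo), float(hi))


def smooth_series(x: Sequence[float], y: Sequence[float], span: float = 0.3) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at the input points.

    Reporting-only smoother (the classification stages never consume it).
    With fewer than 10 defined points the series is passed through unchanged
    with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 10:
        warnings.warn("fewer than 10 defined points; smoothing skipped", stacklevel=2)
        return y.copy()
    out = np.full_like(y, np.nan)
    sm = lowess(y[ok], x[ok], frac=span, it=0, return_sorted=False)
    out[ok] = sm
    return out


# ---------------------------------------------------------------------------
# Assembled per-window table
# ---------------------------------------------------------------------------


def build_window_table(
    gt: GenotypeTable,
    sheet: SampleSheet,
    windows: pd.DataFrame,
    species: str | None = None,
    min_per_sex: int = 2,
) -> pd.DataFrame:
    """WindowStatTable: F_ST, SNP density ratio, SDR-like and female-specific
    densities and site counts per window (depth ratio joins from the depth
    table, which lives on its own window grid)."""
    out = windows[WINDOW_COLUMNS].copy()
    out["fst"] = window_fst(gt, sheet, windows, species=species)
    out["snp_density_ratio"] = snp_density_ratio_windows(gt, sheet, windows, species=species)
    calls = sdr_snp.classify_sites(gt, sheet, species=species, min_per_sex=min_per_sex)
    out["sdr_like_density"] = counts_per_window(gt.sites, windows, (calls["status"] == "sdr_like").to_numpy())
    out["female_specific_density"] = counts_per_window(
        gt.sites, windows, (calls["status"] == "female_specific").to_numpy()
    )
    out["n_sites"] = counts_per_window(gt.sites, windows, np.ones(gt.n_sites, bool))
    return out
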