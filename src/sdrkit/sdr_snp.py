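"""Per-site sex-linked SNP classification from heterozygosity patterns.

A site is *SDR-like* (putatively Y-linked) when one allele appears in males
only within heterozygous genotypes — every called male heterozygous for it —
and is absent from all called females.  That allele is recorded as "Y-like";
the alternate allele at the site is "X-like".  A site is *female-specific*
when one allele is carried by at least one female and by no male.  Both
classifications require a minimum number of called individuals per sex
(default 2); with small samples such patterns arise by chance on autosomes,
which is why the autosomal rate is tracked as an internal control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import HET, HOM_ALT, HOM_REF, GenotypeTable, SampleSheet

STATUSES = ("sdr_like", "female_specific", "neither", "insufficient_data")


@dataclass
class SdrSnpCall:
    site_index: int
    status: str
    y_like_allele: str  # "ref", "alt", or "none"

    def __post_init__(self) -> None:
        assert (self.y_like_allele != "none") == (self.status == "sdr_like")


def _counts(genotypes: np.ndarray):
    called = genotypes >= 0
    n = called.sum(axis=1)
    het = (genotypes == HET).sum(axis=1)
    hom_alt = (genotypes == HOM_ALT).sum(axis=1)
    hom_ref = (genotypes == HOM_REF).sum(axis=1)
    alt = het + 2 * hom_alt
    ref = het + 2 * hom_ref
    return n, het, hom_ref, hom_alt, ref, alt


def classify_sites(
    gt: GenotypeTable,
    sheet: SampleSheet,
    species: str | None = None,
    min_per_sex: int = 2,
    min_females_carrying: int = 1,
) -> pd.DataFrame:
    """Vectorised SDR-like / female-specific status for every site.

    Returns a DataFrame with columns ``status`` and ``y_like_allele`` aligned
    with ``gt.sites``.  The two statuses are mutually exclusive: a Y-like
    allele is present in every male (so it cannot be male-absent) and its
    X-like partner is present in every male too.
    """
    males = gt.genotypes[:, gt.sample_index(sheet.males(species))]
    females = gt.genotypes[:, gt.sample_index(sheet.females(species))]
    nm, het_m, homref_m, homalt_m, ref_m, alt_m = _counts(males)
    nf, het_f, homref_f, homalt_f, ref_f, alt_f = _counts(females)

    insufficient = (nm < min_per_sex) | (nf < min_per_sex)
    all_males_het = (nm > 0) & (het_m == nm)
    sdr_alt = all_males_het & (alt_f == 0)  # females all hom_ref
    sdr_ref = all_males_het & (ref_f == 0)  # females all hom_alt
    carriers_f_alt = het_f + homalt_f
    carriers_f_ref = het_f + homref_f
    fs_alt = (alt_m == 0) & (carriers_f_alt >= min_females_carrying)
    fs_ref = (ref_m == 0) & (carriers_f_ref >= min_females_carrying)

    status = np.full(gt.n_sites, "neither", dtype=object)
    y_allele = np.full(gt.n_sites, "none", dtype=object)
    fs = fs_alt | fs_ref
    status[fs] = "female_specific"
    sdr = sdr_alt | sdr_ref
    status[sdr] = "sdr_like"
    y_allele[sdr_alt] = "alt"
    y_allele[sdr_ref & ~sdr_alt] = "ref"
    status[insufficient] = "insufficient_data"
    y_allele[insufficient] = "none"
    return pd.DataFrame({"status": status, "y_like_allele": y_allele})


def _single_site_table(male_genotypes, female_genotypes) -> tuple[GenotypeTable, SampleSheet]:
    male_genotypes = list(male_genotypes)
    female_genotypes = list(female_genotypes)
    ids = [f"m{i}" for i in range(len(male_genotypes))] + [f"f{i}" for i in range(len(female_genotypes))]
    sheet = SampleSheet.from_records(
        [(s, "other", "M") for s in ids[: len(male_genotypes)]]
        + [(s, "other", "F") for s in ids[len(male_genotypes) :]]
    )
    sites = pd.DataFrame(
        {
            "chrom": ["chr0"],
            "pos": [1],
            "ref": ["A"],
            "alt": ["T"],
            "qual": [60.0],
            "is_snp": [True],
            "is_biallelic": [True],
            "is_indel": [False],
        }
    )
    g = np.array([male_genotypes + female_genotypes], dtype=np.int8)
    d = np.full_like(g, 30, dtype=np.int32)
    return GenotypeTable(ids, sites, g, d), sheet


def classify_sdr_like(
    male_genotypes: Sequence[int], female_genotypes: Sequence[int], min_per_sex: int = 2
) -> SdrSnpCall:
    """Single-site SDR-like call (Y-like allele recorded when present)."""
    gt, sheet = _single_site_table(male_genotypes, female_genotypes)
    row = classify_sites(gt, sheet, min_per_sex=min_per_sex).iloc[0]
    status = row["status"]
    if status == "female_specific":
        status = "neither"
    return SdrSnpCall(0, status, row["y_like_allele"] if status == "sdr_like" else "none")


def classify_female_specific(
    male_genotypes: Sequence[int], female_genotypes: Sequence[int], min_per_sex: int = 2
) -> SdrSnpCall:
    """Single-site female-specific call."""
    gt, sheet = _single_site_table(male_genotypes, female_genotypes)
    row = classify_sites(gt, sheet, min_per_sex=min_per_sex).iloc[0]
    status = row["status"]
    if status == "sdr_like":
        status = "neither"
    return SdrSnpCall(0, status, "none")


def autosomal_fp_rate(
    gt: GenotypeTable,
    sheet: SampleSheet,
    autosomes: Sequence[str],
    species: str | None = None,
    min_per_sex: int = 2,
) -> float:
    """Fraction of autosomal sites called SDR-like: the empirical false-positive
    control for apparent sex linkage under small sample sizes."""
    mask = gt.sites["chrom"].isin(autosomes).to_numpy()
    if not mask.any():
        warnings.warn("no autosomal sites; false-positive rate reported as 0", stacklevel=2)
        return 0.0
    calls = classify_sites(gt.subset_sites(mask), sheet, species=species, min_per_sex=min_per_sex)
    return float((calls["status"] == "sdr_like").mean())


def calls_to_tsv(gt: GenotypeTable, calls: pd.DataFrame, path) -> None:
    out = gt.sites[["chrom", "pos"]].copy()
    out["status"] = calls["status"].to_numpy()
    out["y_like_allele"] = calls["y_like_allele"].to_numpy()
    out.to_csv(path, sep="\t", index=False)
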