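"""VCF ingestion, sample metadata, and the site-filter cascade.

Genotypes are held as a sites × samples integer matrix with codes
``HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1`` alongside a parallel matrix of
per-genotype read depths.  All positions are 1-based, matching VCF.  All
genotypes are treated as diploid calls: hemizygosity never appears directly —
variant callers impute a homozygote at sites deleted from the Y, and that
imputation artifact is modelled downstream, not here.

Filtering applies a fixed cascade (quality → indel → biallelic SNP →
per-genotype depth masking → singleton → missingness → minor allele
frequency) and returns an accounting report whose per-stage removals always
reconcile the input and output site counts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .errors import ConfigurationError, DataFormatError

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

SPECIES = ("reticulata", "wingei", "picta", "latipinna", "holbrooki", "other")
SEXES = ("M", "F", "unknown")

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "is_snp", "is_biallelic", "is_indel"]


@dataclass
class SampleSheet:
    """Assignment of species and sex to each sample.

    ``table`` has columns ``sample_id``, ``species``, ``sex``; sample ids are
    unique and species/sex are restricted to the recognised vocabularies.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "sex"}
        if not required.issubset(self.table.columns):
            raise ConfigurationError(f"sample sheet needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            raise ConfigurationError(f"duplicate sample ids: {ids[ids.duplicated()].tolist()}")
        bad_sp = set(self.table["species"]) - set(SPECIES)
        if bad_sp:
            raise ConfigurationError(f"unknown species {sorted(bad_sp)}; allowed: {SPECIES}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise ConfigurationError(f"unknown sex {sorted(bad_sex)}; allowed: {SEXES}")

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "SampleSheet":
        return cls(pd.DataFrame(records, columns=["sample_id", "species", "sex"]))

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str, comment="#"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def ids(self, species: str | None = None, sex: str | None = None) -> list[str]:
        t = self.table
        if species is not None:
            t = t[t["species"] == species]
        if sex is not None:
            t = t[t["sex"] == sex]
        return t["sample_id"].tolist()

    def males(self, species: str | None = None) -> list[str]:
        return self.ids(species=species, sex="M")

    def females(self, species: str | None = None) -> list[str]:
        return self.ids(species=species, sex="F")

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        t = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleSheet(t)


@dataclass
class GenotypeTable:
    """Sites × samples genotype and depth matrices with site metadata.

    ``sites`` is a DataFrame with columns :data:`SITE_COLUMNS`; positions are
    strictly increasing within each chromosome.  ``genotypes`` and ``depths``
    are 2-D arrays of shape (n_sites, n_samples).
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.genotypes.shape != (n_sites, n_samples):
            raise DataFormatError(
                f"genotype matrix {self.genotypes.shape} != sites × samples ({n_sites}, {n_samples})"
            )
        if self.depths.shape != (n_sites, n_samples):
            raise DataFormatError("depth matrix shape inconsistent with site list / sample sheet")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataFormatError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ConfigurationError(f"sample {exc} not in genotype table") from exc

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.samples,
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            self.depths[mask],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeTable":
        idx = self.sample_index(sample_ids)
        return GenotypeTable(list(sample_ids), self.sites.copy(), self.genotypes[:, idx], self.depths[:, idx])


@dataclass
class FilterConfig:
    """Thresholds of the site-filter cascade.

    ``min_depth`` masks individual genotypes below the threshold to missing
    (the site is then exposed to the missingness rule) rather than dropping
    the whole site.  ``max_missing_fraction`` is the maximum tolerated
    fraction of missing genotypes per site (0.0 reproduces vcftools
    ``--max-missing 1.0``).
    """

    min_qual: float = 20.0
    biallelic_snps_only: bool = True
    drop_indels: bool = True
    drop_singletons: bool = True
    min_depth: int = 0
    max_missing_fraction: float = 1.0
    min_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ConfigurationError("max_missing_fraction must lie in [0, 1]")
        if not (0.0 <= self.min_maf <= 1.0):
            raise ConfigurationError("min_maf must lie in [0, 1]")


@dataclass
class FilterReport:
    """Per-stage site-removal accounting, in application order."""

    n_input: int
    stages: list[tuple[str, int]] = field(default_factory=list)
    genotypes_masked: int = 0

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.stages)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)] + list(self.stages) + [("output", self.n_output)]
        return pd.DataFrame(rows, columns=["stage", "sites"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_vcf(path, sheet: SampleSheet) -> GenotypeTable:
    """Load a VCF 4.x into a :class:`GenotypeTable` restricted to sheet samples.

    Genotypes are mapped by unphased allele content; multi-allelic and
    non-SNP records are retained but flagged so the filter cascade can drop
    them.  Raises :class:`DataFormatError` if GT is absent and
    :class:`ConfigurationError` if a sheet sample is missing from the header.
    """
    vcf = VCF(str(path), gts012=True)
    missing = [s for s in sheet.sample_ids if s not in vcf.samples]
    if missing:
        raise ConfigurationError(f"sheet samples absent from VCF header: {missing}")
    order = np.array([vcf.samples.index(s) for s in sheet.sample_ids], dtype=int)

    chroms, poss, refs, alts, quals = [], [], [], [], []
    snp_flags, biall_flags, indel_flags = [], [], []
    gts, dps = [], []
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise DataFormatError(f"record {v.CHROM}:{v.POS} lacks a GT FORMAT field")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
        snp_flags.append(bool(v.is_snp))
        biall_flags.append(len(v.ALT) == 1)
        indel_flags.append(bool(v.is_indel))
        g = np.asarray(v.gt_types, dtype=np.int8)[order]
        g[g == 3] = MISSING
        gts.append(g)
        dp = v.format("DP")
        if dp is None:
            d = np.zeros(len(order), dtype=np.int32)
        else:
            d = np.asarray(dp, dtype=np.int64).reshape(-1)[order].astype(np.int32)
            d[d < 0] = 0
        dps.append(d)

    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.array(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "qual": np.array(quals, dtype=float),
            "is_snp": snp_flags,
            "is_biallelic": biall_flags,
            "is_indel": indel_flags,
        }
    )
    n = len(sites)
    g = np.vstack(gts) if n else np.zeros((0, len(order)), dtype=np.int8)
    d = np.vstack(dps) if n else np.zeros((0, len(order)), dtype=np.int32)
    return GenotypeTable(sheet.sample_ids, sites, g, d)


_GT_TUPLES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def write_vcf(gt: GenotypeTable, sheet: SampleSheet, path) -> None:
    """Write a minimal VCF 4.2 with GT:DP; inverse of :func:`read_vcf`."""
    if list(sheet.sample_ids) != list(gt.samples):
        gt = gt.subset_samples(sheet.sample_ids)
    header = pysam.VariantHeader()
    for chrom in gt.sites["chrom"].unique():
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth supporting the genotype")
    for s in gt.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in enumerate(gt.sites.itertuples(index=False)):
            alleles = (row.ref,) + tuple(str(row.alt).split(","))
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=alleles,
                qual=None if pd.isna(row.qual) else float(row.qual),
            )
            for j, s in enumerate(gt.samples):
                rec.samples[s]["GT"] = _GT_TUPLES[int(gt.genotypes[i, j])]
                rec.samples[s]["DP"] = int(gt.depths[i, j])
            out.write(rec)


def _allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) allele counts over non-missing diploid genotypes."""
    called = genotypes >= 0
    alt = (genotypes == HET).sum(axis=1) + 2 * (genotypes == HOM_ALT).sum(axis=1)
    ref = 2 * called.sum(axis=1) - alt
    return ref, alt


def apply_site_filters(gt: GenotypeTable, cfg: FilterConfig) -> tuple[GenotypeTable, FilterReport]:
    """Apply the filter cascade in fixed order and account for every removal.

    Order: quality → indel → biallelic SNP → per-genotype depth masking →
    singleton → missingness → minor allele frequency.  A singleton site is
    one where the minor allele occurs exactly once over all called alleles
    (a single heterozygote carrying the only copy).  MAF is computed over
    called alleles only.
    """
    report = FilterReport(n_input=gt.n_sites)
    cur = gt

    def drop(name: str, remove_mask: np.ndarray) -> None:
        nonlocal cur
        n = int(remove_mask.sum())
        report.stages.append((name, n))
        if n:
            cur = cur.subset_sites(~remove_mask)

    qual = cur.sites["qual"].to_numpy()
    drop("quality", (~np.isnan(qual)) & (qual < cfg.min_qual))

    if cfg.drop_indels:
        drop("indel", cur.sites["is_indel"].to_numpy(bool))
    else:
        report.stages.append(("indel", 0))

    if cfg.biallelic_snps_only:
        ok = cur.sites["is_snp"].to_numpy(bool) & cur.sites["is_biallelic"].to_numpy(bool)
        drop("biallelic_snp", ~ok)
    else:
        report.stages.append(("biallelic_snp", 0))

    if cfg.min_depth > 0 and cur.n_sites:
        mask_cells = (cur.depths < cfg.min_depth) & (cur.genotypes != MISSING)
        report.genotypes_masked = int(mask_cells.sum())
        if report.genotypes_masked:
            g = cur.genotypes.copy()
            g[mask_cells] = MISSING
            cur = GenotypeTable(cur.samples, cur.sites, g, cur.depths)

    ref, alt = _allele_counts(cur.genotypes)
    if cfg.drop_singletons:
        drop("singleton", np.minimum(ref, alt) == 1)
    else:
        report.stages.append(("singleton", 0))

    miss_frac = (cur.genotypes == MISSING).mean(axis=1) if cur.n_sites else np.zeros(0)
    drop("max_missing", miss_frac > cfg.max_missing_fraction + 1e-12)

    if cfg.min_maf > 0:
        ref, alt = _allele_counts(cur.genotypes)
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(total > 0, np.minimum(ref, alt) / np.maximum(total, 1), 0.0)
        drop("maf", maf < cfg.min_maf - 1e-12)
    else:
        report.stages.append(("maf", 0))

    assert report.n_input - report.n_removed == cur.n_sites
    return cur, report


def config_hash(obj) -> str:
    """Short stable hash of a configuration object, for output provenance lines."""
    payload = repr(obj).encode()
    return hashlib.md5(payload).hexdigest()[:10]
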