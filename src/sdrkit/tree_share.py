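"""Gametolog allele-sharing: topologically informative SNPs and the 10 trees.

The question: do the sex-determining regions (SDRs) of *M. picta* and
*P. wingei* descend from one ancestral SDR, or did they arise independently
(possibly via a turnover in which a new Y was derived from an X)?  Because a
nonrecombining SDR fixes one allele on the X and one on the Y of each
species, the joint presence/absence pattern of a derived allele across the
four gametologs (Xp, Yp, Xw, Yw) identifies one of ten rooted gene trees.

A SNP is *topologically informative* when

1. at least ``min_per_sex`` called individuals exist per focal species and
   sex, and at least one called individual per outgroup species;
2. alleles are fixed on the X and on the Y within each focal species: all
   females homozygous for one allele, and all males either all heterozygous
   or all homozygous for the females' allele;
3. every outgroup individual is homozygous for the same (ancestral) allele;
4. the derived allele is fixed on exactly 2 or 3 of {Xp, Yp, Xw, Yw}.

Shared derived alleles on both Ys (or both Xs) support a homologous SDR
(trees 1–2); species-private X–Y sharing supports independent SDRs (trees
3–4); trees 5–8 arise under turnover histories or homoplasy; trees 9–10 are
biologically implausible cross-pairings that calibrate the homoplasy rate.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .variant_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable, SampleSheet

CHROMOSOMES = ("Xp", "Yp", "Xw", "Yw")

#: Subset of {Xp, Yp, Xw, Yw} carrying the derived allele → tree id.
#: One editable table so the numbering can be realigned with published
#: artwork without touching code.
TREE_OF_PATTERN: dict[frozenset, int] = {
    frozenset({"Yp", "Yw"}): 1,
    frozenset({"Xp", "Xw"}): 2,
    frozenset({"Xp", "Yp"}): 3,
    frozenset({"Xw", "Yw"}): 4,
    frozenset({"Xp", "Xw", "Yw"}): 5,
    frozenset({"Xp", "Yp", "Xw"}): 6,
    frozenset({"Yp", "Xw", "Yw"}): 7,
    frozenset({"Xp", "Yp", "Yw"}): 8,
    frozenset({"Xp", "Yw"}): 9,
    frozenset({"Yp", "Xw"}): 10,
}

TREE_INTERPRETATION = {
    1: "homologous-SDR",
    2: "homologous-SDR",
    3: "independent-SDR",
    4: "independent-SDR",
    5: "turnover",
    6: "turnover",
    7: "turnover",
    8: "turnover",
    9: "implausible",
    10: "implausible",
}

REJECTION_REASONS = (
    "female_polymorphic",
    "males_mixed",
    "males_opposite_homozygote",
    "insufficient_samples",
)


@dataclass
class GametologCall:
    """Inferred fixed X and Y alleles for one species at one site."""

    species: str
    x_allele: str | None  # "ref" / "alt"
    y_allele: str | None
    rejected: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        assert (self.x_allele is not None and self.y_allele is not None) != self.rejected


def infer_gametolog_alleles(
    male_genotypes: Sequence[int],
    female_genotypes: Sequence[int],
    min_per_sex: int = 2,
    species: str = "other",
) -> GametologCall:
    """Fixed-allele call for one species at one biallelic site.

    Females must all be homozygous for the same allele (the X allele); males
    all heterozygous puts the other allele on the Y, males all homozygous for
    the females' allele puts the same allele on the Y.  Anything else is a
    rejection, returned as a value.
    """
    m = np.asarray(male_genotypes, dtype=np.int8)
    f = np.asarray(female_genotypes, dtype=np.int8)
    m = m[m != MISSING]
    f = f[f != MISSING]
    if len(m) < min_per_sex or len(f) < min_per_sex:
        return GametologCall(species, None, None, True, "insufficient_samples")
    if not (np.all(f == HOM_REF) or np.all(f == HOM_ALT)):
        return GametologCall(species, None, None, True, "female_polymorphic")
    x = "ref" if f[0] == HOM_REF else "alt"
    if np.all(m == HET):
        return GametologCall(species, x, "alt" if x == "ref" else "ref")
    if np.all(m == f[0]):
        return GametologCall(species, x, x)
    other_hom = HOM_ALT if f[0] == HOM_REF else HOM_REF
    if np.all(m == other_hom):
        return GametologCall(species, None, None, True, "males_opposite_homozygote")
    return GametologCall(species, None, None, True, "males_mixed")


def _gametolog_calls_vec(males: np.ndarray, females: np.ndarray, min_per_sex: int):
    """Vectorised gametolog calls.

    Returns (x, y, reason): ``x``/``y`` are int8 arrays (0=ref, 1=alt, −1
    undefined), ``reason`` an object array (None when accepted).
    """
    n_sites = males.shape[0]
    called_m = males != MISSING
    called_f = females != MISSING
    nm = called_m.sum(axis=1)
    nf = called_f.sum(axis=1)

    f_homref = np.all((females == HOM_REF) | ~called_f, axis=1) & (nf > 0)
    f_homalt = np.all((females == HOM_ALT) | ~called_f, axis=1) & (nf > 0)
    f_fixed = f_homref | f_homalt
    x = np.where(f_homalt, 1, 0).astype(np.int8)

    m_het = np.all((males == HET) | ~called_m, axis=1) & (nm > 0)
    m_homref = np.all((males == HOM_REF) | ~called_m, axis=1) & (nm > 0)
    m_homalt = np.all((males == HOM_ALT) | ~called_m, axis=1) & (nm > 0)
    m_same = (f_homref & m_homref) | (f_homalt & m_homalt)
    m_opposite = (f_homref & m_homalt) | (f_homalt & m_homref)

    reason = np.full(n_sites, None, dtype=object)
    insufficient = (nm < min_per_sex) | (nf < min_per_sex)
    accepted = ~insufficient & f_fixed & (m_het | m_same)
    reason[~f_fixed] = "female_polymorphic"
    reason[f_fixed & ~(m_het | m_same) & ~m_opposite] = "males_mixed"
    reason[f_fixed & m_opposite] = "males_opposite_homozygote"
    reason[insufficient] = "insufficient_samples"

    y = np.where(m_het, 1 - x, x).astype(np.int8)
    x = np.where(accepted, x, -1).astype(np.int8)
    y = np.where(accepted, y, -1).astype(np.int8)
    return x, y, reason


def polarize(outgroup_genotypes: Mapping[str, Sequence[int]]) -> tuple[str | None, str | None]:
    """Ancestral allele from outgroup species, or (None, reason).

    Every called outgroup individual, across all outgroup species, must be
    homozygous for the same allele; a heterozygote or disagreement rejects
    the site, and each species needs at least one called individual.
    """
    seen = set()
    for species, g in outgroup_genotypes.items():
        g = np.asarray(g, dtype=np.int8)
        g = g[g != MISSING]
        if len(g) == 0:
            return None, "insufficient_outgroup"
        if np.any(g == HET):
            return None, "outgroup_het"
        seen.update("ref" if v == HOM_REF else "alt" for v in g)
    if len(seen) != 1:
        return None, "outgroup_disagree"
    return seen.pop(), None


def _polarize_vec(genotypes_by_species: Sequence[np.ndarray]):
    """Vectorised polarisation: (ancestral int8 0/1/−1, reason object array)."""
    n_sites = genotypes_by_species[0].shape[0]
    reason = np.full(n_sites, None, dtype=object)
    any_het = np.zeros(n_sites, bool)
    any_ref = np.zeros(n_sites, bool)
    any_alt = np.zeros(n_sites, bool)
    insufficient = np.zeros(n_sites, bool)
    for g in genotypes_by_species:
        called = g != MISSING
        insufficient |= called.sum(axis=1) == 0
        any_het |= np.any((g == HET) & called, axis=1)
        any_ref |= np.any(g == HOM_REF, axis=1)
        any_alt |= np.any(g == HOM_ALT, axis=1)
    disagree = any_ref & any_alt
    ok = ~insufficient & ~any_het & ~disagree
    reason[disagree] = "outgroup_disagree"
    reason[any_het] = "outgroup_het"
    reason[insufficient] = "insufficient_outgroup"
    anc = np.where(any_alt, 1, 0).astype(np.int8)
    anc = np.where(ok, anc, -1).astype(np.int8)
    return anc, reason


def informative_filter(
    picta_call: GametologCall, wingei_call: GametologCall, ancestral: str
) -> tuple[frozenset | None, str | None]:
    """Derived-allele presence pattern over {Xp, Yp, Xw, Yw}, or a reason.

    Informative iff the derived allele is fixed on 2 or 3 of the four
    chromosomes; upstream rejections propagate.
    """
    if picta_call.rejected:
        return None, f"picta:{picta_call.reason}"
    if wingei_call.rejected:
        return None, f"wingei:{wingei_call.reason}"
    derived = "alt" if ancestral == "ref" else "ref"
    alleles = {
        "Xp": picta_call.x_allele,
        "Yp": picta_call.y_allele,
        "Xw": wingei_call.x_allele,
        "Yw": wingei_call.y_allele,
    }
    pattern = frozenset(c for c in CHROMOSOMES if alleles[c] == derived)
    size = len(pattern)
    if size in (2, 3):
        return pattern, None
    return None, {0: "no_derived", 1: "derived_singleton", 4: "derived_on_all"}[size]


def classify_tree(pattern: frozenset, table: Mapping[frozenset, int] | None = None) -> int:
    """Tree id (1–10) for an informative presence pattern."""
    table = TREE_OF_PATTERN if table is None else table
    if pattern not in table:
        raise ValueError(f"pattern {set(pattern)} is not topologically informative")
    return table[pattern]


def pattern_str(pattern: frozenset | None) -> str:
    if not pattern:
        return "."
    return "|".join(c for c in CHROMOSOMES if c in pattern)


@dataclass
class TreeClassification:
    """Per-site tree assignment plus genome-wide counts."""

    per_site: pd.DataFrame  # chrom, pos, pattern, tree_id (0 = uninformative), reason
    counts: dict[int, int]
    uninformative: Counter
    n_sites: int

    @property
    def n_informative(self) -> int:
        return sum(self.counts.values())

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            (t, self.counts.get(t, 0), TREE_INTERPRETATION[t], pattern_str(p))
            for p, t in sorted(TREE_OF_PATTERN.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows, columns=["tree_id", "n_snps", "interpretation", "pattern"])


def run_treeshare(
    gt: GenotypeTable,
    sheet: SampleSheet,
    min_per_sex: int = 2,
    focal: tuple[str, str] = ("picta", "wingei"),
    outgroups: tuple[str, ...] = ("latipinna", "holbrooki"),
    pattern_table: Mapping[frozenset, int] | None = None,
) -> TreeClassification:
    """Classify every site: fixation per species → polarisation → presence
    pattern → tree id, with uninformative tallies by reason.

    Only biallelic SNP sites may reach this stage (asserted); run the filter
    cascade first.
    """
    sp_p, sp_w = focal
    for sp in focal:
        if len(sheet.males(sp)) < min_per_sex or len(sheet.females(sp)) < min_per_sex:
            raise ConfigurationError(
                f"need at least {min_per_sex} males and {min_per_sex} females of {sp}"
            )
    for sp in outgroups:
        if not sheet.ids(species=sp):
            raise ConfigurationError(f"need at least one outgroup individual of {sp}")
    if gt.n_sites:
        ok = gt.sites["is_snp"].to_numpy(bool) & gt.sites["is_biallelic"].to_numpy(bool)
        assert ok.all(), "non-biallelic sites reached tree classification; filter first"

    gp = gt.genotypes
    xp, yp, reason_p = _gametolog_calls_vec(
        gp[:, gt.sample_index(sheet.males(sp_p))], gp[:, gt.sample_index(sheet.females(sp_p))], min_per_sex
    )
    xw, yw, reason_w = _gametolog_calls_vec(
        gp[:, gt.sample_index(sheet.males(sp_w))], gp[:, gt.sample_index(sheet.females(sp_w))], min_per_sex
    )
    anc, reason_o = _polarize_vec([gp[:, gt.sample_index(sheet.ids(species=sp))] for sp in outgroups])

    table = TREE_OF_PATTERN if pattern_table is None else pattern_table
    n = gt.n_sites
    tree_id = np.zeros(n, dtype=np.int32)
    reasons = np.full(n, None, dtype=object)
    patterns = np.full(n, ".", dtype=object)
    counts: Counter = Counter()
    uninformative: Counter = Counter()
    alleles = np.stack([xp, yp, xw, yw], axis=1)  # order = CHROMOSOMES
    for i in range(n):
        if reason_p[i] is not None:
            r = f"{sp_p}:{reason_p[i]}"
        elif reason_w[i] is not None:
            r = f"{sp_w}:{reason_w[i]}"
        elif reason_o[i] is not None:
            r = f"outgroup:{reason_o[i]}"
        else:
            derived = 1 - anc[i]
            pat = frozenset(c for c, a in zip(CHROMOSOMES, alleles[i]) if a == derived)
            size = len(pat)
            if size in (2, 3):
                t = table[pat]
                tree_id[i] = t
                patterns[i] = pattern_str(pat)
                counts[t] += 1
                continue
            r = {0: "no_derived", 1: "derived_singleton", 4: "derived_on_all"}[size]
            patterns[i] = pattern_str(pat)
        reasons[i] = r
        uninformative[r] += 1

    per_site = pd.DataFrame(
        {
            "chrom": gt.sites["chrom"].to_numpy(),
            "pos": gt.sites["pos"].to_numpy(),
            "pattern": patterns,
            "tree_id": tree_id,
            "reason": reasons,
        }
    )
    return TreeClassification(per_site, dict(counts), uninformative, n)


@dataclass
class HypothesisSummary:
    """Counts and fractions mapped onto the four SDR-history hypotheses."""

    counts: dict[int, int]
    n_informative: int
    n_sites: int
    fractions: dict[int, float] = field(default_factory=dict)
    fractions_of_all_sites: dict[int, float] = field(default_factory=dict)
    verdict: str = "ambiguous"
    rule: str = ""

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "rule": self.rule,
            "n_informative": self.n_informative,
            "n_sites": self.n_sites,
            "counts": {f"n{t}": self.counts.get(t, 0) for t in range(1, 11)},
            "fractions_of_informative": {f"n{t}": self.fractions.get(t, 0.0) for t in range(1, 11)},
            "fractions_of_all_sites": {
                f"n{t}": self.fractions_of_all_sites.get(t, 0.0) for t in range(1, 11)
            },
        }


RULE_TEXT = (
    "homologous if (n1+n2)/N >= 0.5; otherwise turnover_wingei if n5 exceeds the "
    "homoplasy expectation (n9+n10)/2 by more than 3*sqrt(expectation+1); otherwise "
    "independent if (n3+n4)/N >= 0.5; otherwise ambiguous. Reporting heuristic only: "
    "all fractions are emitted regardless of the verdict."
)


def summarize_hypotheses(tc: TreeClassification) -> HypothesisSummary:
    """Map tree counts onto the four history hypotheses with a stated rule."""
    counts = {t: tc.counts.get(t, 0) for t in range(1, 11)}
    N = sum(counts.values())
    summary = HypothesisSummary(counts=counts, n_informative=N, n_sites=tc.n_sites, rule=RULE_TEXT)
    if N == 0:
        warnings.warn("no topologically informative sites; verdict is ambiguous", stacklevel=2)
        return summary
    summary.fractions = {t: counts[t] / N for t in counts}
    if tc.n_sites:
        summary.fractions_of_all_sites = {t: counts[t] / tc.n_sites for t in counts}
    homoplasy_expect = (counts[9] + counts[10]) / 2.0
    turnover_flag = counts[5] > homoplasy_expect + 3.0 * sqrt(homoplasy_expect + 1.0)
    if (counts[1] + counts[2]) / N >= 0.5:
        summary.verdict = "homologous"
    elif turnover_flag:
        summary.verdict = "turnover_wingei"
    elif (counts[3] + counts[4]) / N >= 0.5:
        summary.verdict = "independent"
    else:
        summary.verdict = "ambiguous"
    return summary
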