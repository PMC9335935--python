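"""Independent oracles used by the test suite.

These are deliberately naive transcriptions (loops, enumeration, closed
forms) kept separate from the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


def wc_components_oracle(groups: list[list[int]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) per-locus variance components for r groups.

    Literal transcription of the published equations: sample sizes n_i,
    alt-allele frequencies p_i and observed heterozygote frequencies h_i per
    group; returns (a, b, c).
    """
    r = len(groups)
    n, p, h = [], [], []
    for g in groups:
        g = [x for x in g if x != MISSING]
        ni = len(g)
        het = sum(1 for x in g if x == HET)
        alt = het + 2 * sum(1 for x in g if x == HOM_ALT)
        n.append(ni)
        p.append(alt / (2 * ni))
        h.append(het / ni)
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def quantile_oracle(values, q: float) -> float:
    """Linear interpolation between order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 >= len(v):
        return v[-1]
    return v[lo] * (1 - frac) + v[lo + 1] * frac


def loess_oracle(x, y, frac: float) -> np.ndarray:
    """Tricube-weighted local linear regression at the input points, using
    the k = int(frac * n) nearest neighbours of each point as the window."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = int(frac * n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h > 0:
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        else:
            w = (d == 0).astype(float)
        sw = np.sum(w)
        sx = np.sum(w * x)
        sy = np.sum(w * y)
        sxx = np.sum(w * x * x)
        sxy = np.sum(w * x * y)
        denom = sw * sxx - sx * sx
        if abs(denom) < 1e-12 * max(sxx, 1.0):
            out[i] = sy / sw
        else:
            b = (sw * sxy - sx * sy) / denom
            a = (sy - b * sx) / sw
            out[i] = a + b * x[i]
    return out


def hardy_weinberg_probs(p: float) -> dict[int, float]:
    q = 1 - p
    return {HOM_REF: q * q, HET: 2 * p * q, HOM_ALT: p * p}


def sdr_like_prob_exact(n_males: int, n_females: int, p: float) -> float:
    """Exact probability that an autosomal Hardy–Weinberg site looks SDR-like:
    enumeration over all genotype combinations."""
    probs = hardy_weinberg_probs(p)
    total = 0.0
    for males in itertools.product(probs, repeat=n_males):
        for females in itertools.product(probs, repeat=n_females):
            w = math.prod(probs[g] for g in males) * math.prod(probs[g] for g in females)
            all_het = all(g == HET for g in males)
            f_homref = all(g == HOM_REF for g in females)
            f_homalt = all(g == HOM_ALT for g in females)
            if all_het and (f_homref or f_homalt):
                total += w
    return total


def filter_rule_checks(site: dict, genotypes: list[int], cfg) -> dict[str, bool]:
    """Brute-force per-rule verdicts for one site (True = rule removes it)."""
    called = [g for g in genotypes if g != MISSING]
    alt = sum(1 for g in called if g == HET) + 2 * sum(1 for g in called if g == HOM_ALT)
    ref = 2 * len(called) - alt
    miss_frac = 1 - len(called) / len(genotypes) if genotypes else 0.0
    maf = min(ref, alt) / (ref + alt) if (ref + alt) else 0.0
    qual = site["qual"]
    return {
        "quality": (qual == qual) and qual < cfg.min_qual,
        "indel": cfg.drop_indels and site["is_indel"],
        "biallelic_snp": cfg.biallelic_snps_only and not (site["is_snp"] and site["is_biallelic"]),
        "singleton": cfg.drop_singletons and min(ref, alt) == 1,
        "max_missing": miss_frac > cfg.max_missing_fraction + 1e-12,
        "maf": cfg.min_maf > 0 and maf < cfg.min_maf - 1e-12,
    }
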