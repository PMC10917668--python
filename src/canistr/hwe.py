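"""Hardy-Weinberg exact testing and null-allele screening.

The HWE test is the classical conditional exact test for multi-allelic loci,
evaluated by Monte Carlo: the 2n observed alleles are repeatedly shuffled
into n diploid genotypes, and the p-value is the proportion of shuffled
genotype arrays whose conditional probability (given the allele counts) is
at most that of the observed array, with the +1/+1 small-sample correction.

Null-allele screening combines two moment estimators of the null-allele
frequency driven by the heterozygote deficit (Chakraborty et al. 1992,
Brookfield 1996) with a homozygote-excess scan across allele size classes -
a deliberately simplified surrogate for a full stutter/dropout diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .locus_stats import allele_frequencies
from .model import GenotypeTable

__all__ = [
    "HWEResult",
    "NullAlleleEstimates",
    "SizeClassReport",
    "hwe_exact_test",
    "bonferroni_adjust",
    "null_allele_estimates",
    "homozygote_excess_scan",
]


@dataclass(frozen=True)
class HWEResult:
    locus: str
    population: str
    p_value: Optional[float]  # None when undefined (n_typed < 5)
    n_shuffles: int
    n_typed: int
    alpha: float = 0.05
    significant_raw: bool = False
    significant_bonferroni: bool = False

    @property
    def defined(self) -> bool:
        return self.p_value is not None


@dataclass(frozen=True)
class NullAlleleEstimates:
    r_chakraborty: float
    r_brookfield: float
    flagged: bool


@dataclass(frozen=True)
class SizeClassReport:
    """Homozygote-excess scan result for one locus x population."""
    locus: str
    population: str
    classes: tuple  # per-class dicts
    flagged: bool
    p_total: float = 1.0  # one-sided p for the overall homozygote excess


def _encoded_genotypes(table: GenotypeTable, locus: str, population: str):
    """Typed genotypes as integer allele codes; returns (codes (n,2), alleles)."""
    alleles = sorted({al for s in table.samples_in(population)
                      if s.is_typed(locus) for al in s.genotypes[locus]},
                     key=lambda al: al.sort_key)
    index = {al: i for i, al in enumerate(alleles)}
    rows = [(index[g[0]], index[g[1]])
            for s in table.samples_in(population)
            if (g := s.genotypes.get(locus)) is not None and s.is_typed(locus)]
    return np.array(rows, dtype=np.int64).reshape(-1, 2), alleles


def _array_log_stat(pairs: np.ndarray, k: int, logfact: np.ndarray) -> np.ndarray:
    """Non-constant part of the log conditional probability of genotype arrays.

    For fixed allele counts, log P(array) = const + H*ln2 - sum log(n_gt!),
    where H is the heterozygote count and n_gt the per-genotype-cell counts.
    ``pairs`` has shape (B, n, 2) with allele codes.
    """
    lo = pairs.min(axis=2)
    hi = pairs.max(axis=2)
    het = (lo != hi).sum(axis=1)
    codes = lo * k + hi
    B, n = codes.shape
    offset = np.arange(B, dtype=np.int64)[:, None] * (k * k)
    counts = np.bincount((codes + offset).ravel(), minlength=B * k * k)
    counts = counts.reshape(B, k * k)
    return het * np.log(2.0) - logfact[counts].sum(axis=1)


def hwe_exact_test(table: GenotypeTable, locus: str, population: str,
                   n_shuffles: int = 5000, seed: int = 0,
                   alpha: float = 0.05) -> HWEResult:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    Two-sided by probability ordering: arrays less probable than the observed
    one (conditional on allele counts) count against the null whichever way
    they deviate.  Deterministic for a fixed seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be positive")
    pairs, alleles = _encoded_genotypes(table, locus, population)
    n = len(pairs)
    if n < 5:
        return HWEResult(locus, population, None, n_shuffles, n, alpha)
    k = len(alleles)
    if k == 1:  # a monomorphic locus admits a single genotype array
        return HWEResult(locus, population, 1.0, n_shuffles, n, alpha)
    pool = pairs.ravel()
    logfact = gammaln(np.arange(n + 1, dtype=np.float64) + 1.0)  # log(c!)
    obs_stat = _array_log_stat(pairs[None, :, :], k, logfact)[0]
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(pool, (n_shuffles, 1)), axis=1)
    stats = _array_log_stat(shuffled.reshape(n_shuffles, n, 2), k, logfact)
    hits = int((stats <= obs_stat + 1e-9).sum())
    p = (1 + hits) / (1 + n_shuffles)
    return HWEResult(locus, population, p, n_shuffles, n, alpha,
                     significant_raw=p <= alpha)


def bonferroni_adjust(results: Sequence[HWEResult],
                      alpha: float = 0.05) -> list:
    """Apply a Bonferroni correction across one family of HWE tests.

    The family is whatever list the caller groups together (typically all
    loci within one population); m counts the defined tests in it.
    """
    if not results:
        raise ValueError("empty result family")
    m = sum(1 for r in results if r.defined)
    out = []
    for r in results:
        if not r.defined:
            out.append(replace(r, alpha=alpha))
            continue
        out.append(replace(
            r, alpha=alpha,
            significant_raw=r.p_value <= alpha,
            significant_bonferroni=m > 0 and r.p_value <= alpha / m))
    return out


def null_allele_estimates(HO: float, HE: float,
                          threshold: float = 0.05) -> NullAlleleEstimates:
    """Moment estimators of the null-allele frequency from HO and HE.

    Chakraborty: r = (HE-HO)/(HE+HO); Brookfield: r = (HE-HO)/(1+HE).
    Negative values (observed heterozygote excess) are reported as-is; the
    flag fires only when both estimates exceed ``threshold``.
    """
    if not (0 <= HO <= 1 and 0 <= HE <= 1):
        raise ValueError("HO and HE must be in [0, 1]")
    denom = HE + HO
    r_c = (HE - HO) / denom if denom > 0 else 0.0
    r_b = (HE - HO) / (1.0 + HE)
    return NullAlleleEstimates(r_chakraborty=r_c, r_brookfield=r_b,
                               flagged=min(r_c, r_b) > threshold)


def homozygote_excess_scan(table: GenotypeTable, locus: str, population: str,
                           n_size_classes: int = 4, n_mc: int = 2000,
                           seed: int = 0, alpha: float = 0.05) -> SizeClassReport:
    """Scan allele size classes for homozygote excess relative to HWE.

    Alleles are binned by parsed size into ``n_size_classes`` equal-width
    classes; for each occupied class the observed homozygote count is
    compared with its Monte-Carlo HWE expectation (genotypes resampled from
    the allele spectrum).  The locus-level flag is raised when the one-sided
    excess is significant in a strict majority of occupied classes, or when
    the total homozygote count across classes is itself in significant
    excess (stutter miscalls concentrate the excess in the larger allele of
    each adjacent pair, so a per-class majority alone would miss them;
    null alleles inflate every class at once).
    """
    pairs, alleles = _encoded_genotypes(table, locus, population)
    n = len(pairs)
    if n < 10:
        raise ValueError(f"need >= 10 typed individuals, got {n}")
    sizes = np.array([al.parsed_size if al.parsed_size is not None else -1
                      for al in alleles], dtype=float)
    lo_s, hi_s = sizes.min(), sizes.max()
    if hi_s == lo_s:
        cls = np.zeros(len(alleles), dtype=np.int64)
        n_classes = 1
    else:
        n_classes = n_size_classes
        edges = np.linspace(lo_s, hi_s, n_classes + 1)
        cls = np.clip(np.searchsorted(edges, sizes, side="right") - 1,
                      0, n_classes - 1)
    counts = np.bincount(pairs.ravel(), minlength=len(alleles))
    freqs = counts / counts.sum()
    hom_mask = pairs[:, 0] == pairs[:, 1]
    obs_hom = np.bincount(cls[pairs[hom_mask, 0]], minlength=n_classes)

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(alleles), size=(n_mc, n, 2), p=freqs)
    mc_hom = draws[:, :, 0] == draws[:, :, 1]
    mc_cls = cls[draws[:, :, 0]]
    occupied = sorted(set(cls.tolist()))
    records = []
    n_sig = 0
    for c in occupied:
        mc_counts = (mc_hom & (mc_cls == c)).sum(axis=1)
        p = (1 + int((mc_counts >= obs_hom[c]).sum())) / (1 + n_mc)
        sig = p <= alpha
        n_sig += sig
        size_vals = sizes[cls == c]
        records.append({"size_class": int(c),
                        "size_range": (float(size_vals.min()),
                                       float(size_vals.max())),
                        "obs_homozygotes": int(obs_hom[c]),
                        "expected_homozygotes": float(mc_counts.mean()),
                        "p_value": p, "significant": bool(sig)})
    total_obs = int(obs_hom.sum())
    mc_total = mc_hom.sum(axis=1)
    p_total = (1 + int((mc_total >= total_obs).sum())) / (1 + n_mc)
    flagged = (n_sig > len(occupied) / 2) or (p_total <= alpha)
    return SizeClassReport(locus=locus, population=population,
                           classes=tuple(records), flagged=bool(flagged),
                           p_total=p_total)
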