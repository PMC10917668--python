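"""Weir-Cockerham F-statistics, per-locus theta, AMOVA and pairwise FST.

The F-statistics follow the variance-component estimators of Weir &
Cockerham (1984): for every allele at a locus three components are formed -
``a`` among populations, ``b`` among individuals within populations and
``c`` within individuals - and summed over alleles.  Per locus

    FST = a/(a+b+c),  FIS = b/(b+c),  FIT = (a+b)/(a+b+c),

so that (1-FIT) = (1-FIS)(1-FST) holds identically.  Multi-locus estimates
are ratios of component sums across loci (never averages of ratios).
Negative components are kept in the sums; only the forensic subdivision
coefficient theta is clamped at zero for reporting.

AMOVA is the one-level analysis on the allele-mismatch distance (0, 1 or 2
differing allele slots between two genotypes), with significance from
permutation of whole individuals across populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import GenotypeTable

__all__ = [
    "FStatsResult",
    "AmovaResult",
    "wc_fstats",
    "per_locus_theta",
    "amova",
    "pairwise_fst",
    "wright_band",
]


@dataclass(frozen=True)
class LocusComponents:
    a: float
    b: float
    c: float

    @property
    def defined(self) -> bool:
        return (self.a + self.b + self.c) != 0.0

    @property
    def fst(self) -> Optional[float]:
        t = self.a + self.b + self.c
        return self.a / t if t else None

    @property
    def fis(self) -> Optional[float]:
        t = self.b + self.c
        return self.b / t if t else None

    @property
    def fit(self) -> Optional[float]:
        t = self.a + self.b + self.c
        return (self.a + self.b) / t if t else None


@dataclass
class FStatsResult:
    per_locus: dict  # locus -> LocusComponents
    multilocus: dict  # {"FIS","FST","FIT"} by ratio of component sums

    @property
    def defined_loci(self) -> list:
        return [l for l, comp in self.per_locus.items() if comp.defined]


@dataclass(frozen=True)
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_perm: float
    n_perm: int
    per_locus_pct_among: dict


def wright_band(fst: float) -> str:
    """Wright's qualitative interpretation band for an FST value."""
    if fst < 0.05:
        return "little differentiation (0.00-0.05)"
    if fst < 0.15:
        return "moderate differentiation (0.05-0.15)"
    if fst < 0.25:
        return "great differentiation (0.15-0.25)"
    return "very great differentiation (>0.25)"


def _pop_allele_stats(table: GenotypeTable, locus: str, populations):
    """Per population: sample size, allele freqs, per-allele het frequency."""
    alleles = sorted({al for s in table.samples
                      if s.population in populations and s.is_typed(locus)
                      for al in s.genotypes[locus]},
                     key=lambda al: al.sort_key)
    index = {al: i for i, al in enumerate(alleles)}
    k = len(alleles)
    ns, ps, hs = [], [], []
    for pop in populations:
        cnt = np.zeros(k)
        het = np.zeros(k)
        n = 0
        for s in table.samples_in(pop):
            if not s.is_typed(locus):
                continue
            n += 1
            a, b = s.genotypes[locus]
            cnt[index[a]] += 1
            cnt[index[b]] += 1
            if a != b:
                het[index[a]] += 1
                het[index[b]] += 1
        if n > 0:
            ns.append(n)
            ps.append(cnt / (2 * n))
            hs.append(het / n)
    return np.array(ns, float), np.array(ps), np.array(hs), alleles


def _wc_components(ns: np.ndarray, ps: np.ndarray,
                   hs: np.ndarray) -> Optional[LocusComponents]:
    """Weir-Cockerham a/b/c summed over alleles for one locus.

    ``ns``: (r,) typed counts; ``ps``: (r, k) allele frequencies;
    ``hs``: (r, k) per-allele heterozygote frequencies.
    """
    r = len(ns)
    if r < 2:
        return None
    nbar = ns.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    w = ns[:, None]
    pbar = (w * ps).sum(axis=0) / (r * nbar)
    s2 = (w * (ps - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * hs).sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return LocusComponents(a=float(a.sum()), b=float(b.sum()),
                           c=float(c.sum()))


def wc_fstats(table: GenotypeTable, loci: Optional[Sequence[str]] = None,
              populations: Optional[Sequence[str]] = None) -> FStatsResult:
    """Per-locus and multi-locus Weir-Cockerham F-statistics.

    Loci with zero total variance (or insufficient data) are carried as
    undefined markers and excluded from the multi-locus component sums.
    """
    loci = list(loci) if loci is not None else table.autosomal_loci
    populations = (list(populations) if populations is not None
                   else table.populations)
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    per_locus: dict = {}
    A = B = C = 0.0
    for locus in loci:
        ns, ps, hs, _ = _pop_allele_stats(table, locus, populations)
        comp = _wc_components(ns, ps, hs) if len(ns) >= 2 else None
        if comp is None:
            per_locus[locus] = LocusComponents(0.0, 0.0, 0.0)
            continue
        per_locus[locus] = comp
        if comp.defined:
            A, B, C = A + comp.a, B + comp.b, C + comp.c
    tot = A + B + C
    multilocus = {
        "FST": A / tot if tot else None,
        "FIS": B / (B + C) if (B + C) else None,
        "FIT": (A + B) / tot if tot else None,
    }
    return FStatsResult(per_locus=per_locus, multilocus=multilocus)


def per_locus_theta(fstats: FStatsResult) -> dict:
    """Forensic subdivision coefficient per locus: FST clamped at zero.

    Undefined loci are omitted; iteration order is ascending theta with
    ties broken by locus name.
    """
    thetas = {locus: max(comp.fst, 0.0)
              for locus, comp in fstats.per_locus.items() if comp.defined}
    return dict(sorted(thetas.items(), key=lambda kv: (kv[1], kv[0])))


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _locus_count_matrix(table: GenotypeTable, locus: str, samples):
    """Per-individual allele-count matrix at one locus.

    Returns (C, typed_positions): C[i, a] counts how many copies of allele a
    the i-th typed individual carries (row sums are 2).
    """
    typed, pairs = [], []
    for pos, s in enumerate(samples):
        g = s.genotypes.get(locus)
        if g is None or g[0] is None:
            continue
        typed.append(pos)
        pairs.append(g)
    tokens = sorted({al for g in pairs for al in g}, key=lambda al: al.sort_key)
    index = {al: i for i, al in enumerate(tokens)}
    C = np.zeros((len(typed), len(tokens)), dtype=np.float64)
    for i, g in enumerate(pairs):
        C[i, index[g[0]]] += 1
        C[i, index[g[1]]] += 1
    return C, np.array(typed, dtype=np.int64)


def _locus_components_batch(C: np.ndarray, M: np.ndarray):
    """One-level AMOVA variance components on allele units, batched.

    The analysis units are the 2m allele copies of the m typed individuals,
    with the 0/1 mismatch (squared) distance; under this metric the sums of
    squares reduce to allele-count algebra:

        SSD_total  = (N - sum_a c_a^2 / N) / 2
        SSD_within = sum_g (n_g - sum_a c_ga^2 / n_g) / 2

    where N = 2m, c_a are total allele counts and c_ga the per-group counts.

    ``C``: (m, k) per-individual allele counts.  ``M``: (m, G, P) one-hot
    group membership for P labelings (individuals carry their two alleles
    with them).  Returns (sigma_among, sigma_within) arrays of shape (P,),
    NaN where degenerate.
    """
    m, k = C.shape
    _, G, P = M.shape
    N = 2.0 * m
    c_tot = C.sum(axis=0)
    ssd_total = (N - (c_tot ** 2).sum() / N) / 2.0
    # counts[a, g, p] = sum_i C[i, a] * M[i, g, p]
    counts = np.einsum("ik,igp->kgp", C, M)
    n_g = counts.sum(axis=0)                     # (G, P) allele units per group
    occupied = n_g > 0
    G_eff = occupied.sum(axis=0)                 # (P,)
    with np.errstate(divide="ignore", invalid="ignore"):
        within_g = np.where(occupied,
                            (n_g - (counts ** 2).sum(axis=0) / n_g) / 2.0, 0.0)
    ssd_within = within_g.sum(axis=0)            # (P,)
    df_within = N - G_eff
    df_among = G_eff - 1.0
    valid = (df_among > 0) & (df_within > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_within = ssd_within / df_within
        n_prime = (N - (np.where(occupied, n_g, 0.0) ** 2).sum(axis=0) / N) / df_among
        sigma_a = ((ssd_total - ssd_within) / df_among - ms_within) / n_prime
    sigma_a = np.where(valid, sigma_a, np.nan)
    ms_within = np.where(valid, ms_within, np.nan)
    return sigma_a, ms_within


def amova(table: GenotypeTable, loci: Optional[Sequence[str]] = None,
          populations: Optional[Sequence[str]] = None,
          n_perm: int = 999, seed: int = 0) -> AmovaResult:
    """One-level AMOVA on the allele-mismatch distance with a permutation test.

    Every allele copy is an analysis unit and two copies differ with squared
    distance 0 or 1 (the FST-like metric, not the squared-size RST-like one),
    so phi_st tracks the Weir-Cockerham multi-locus FST.  Variance components
    are summed across loci (locus-wise deletion of missing genotypes); the
    permutation unit is the whole individual - both allele copies move
    together - preserving any within-individual correlation under the null
    of no subdivision.  p_perm carries the +1/+1 correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    loci = list(loci) if loci is not None else table.autosomal_loci
    populations = (list(populations) if populations is not None
                   else table.populations)
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    samples = [s for s in table.samples if s.population in set(populations)]
    pop_index = {p: i for i, p in enumerate(populations)}
    labels = np.array([pop_index[s.population] for s in samples])
    N = len(samples)
    G = len(populations)

    per_locus = [(locus, *_locus_count_matrix(table, locus, samples))
                 for locus in loci]
    per_locus = [(locus, C, typed) for locus, C, typed in per_locus
                 if len(typed) >= 2]

    rng = np.random.default_rng(seed)
    perms = np.stack([labels] + [labels[rng.permutation(N)]
                                 for _ in range(n_perm)], axis=1)  # (N, P+1)
    onehot = (perms[:, None, :] == np.arange(G)[None, :, None])  # (N, G, P+1)

    sigma_a = np.zeros(n_perm + 1)
    sigma_w = np.zeros(n_perm + 1)
    locus_pct: dict = {}
    for locus, C, typed in per_locus:
        sa, sw = _locus_components_batch(C, onehot[typed].astype(np.float64))
        ok = ~np.isnan(sa)
        sigma_a[ok] += sa[ok]
        sigma_w[ok] += sw[ok]
        if ok[0]:
            tot = sa[0] + sw[0]
            locus_pct[locus] = 100.0 * sa[0] / tot if tot else np.nan

    total = sigma_a[0] + sigma_w[0]
    if total == 0:
        raise ValueError("zero total variance: AMOVA undefined")
    phi_obs = sigma_a[0] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_perm = sigma_a[1:] / (sigma_a[1:] + sigma_w[1:])
    hits = int((phi_perm >= phi_obs).sum())
    p_perm = (1 + hits) / (1 + n_perm)
    return AmovaResult(
        sigma_among=float(sigma_a[0]), sigma_within=float(sigma_w[0]),
        pct_among=100.0 * phi_obs, pct_within=100.0 * (1 - phi_obs),
        phi_st=float(phi_obs), p_perm=p_perm, n_perm=n_perm,
        per_locus_pct_among=locus_pct)


def pairwise_fst(table: GenotypeTable,
                 populations: Optional[Sequence[str]] = None,
                 loci: Optional[Sequence[str]] = None):
    """Symmetric matrix of multi-locus Weir-Cockerham FST between population
    pairs (pandas DataFrame; diagonal 0)."""
    import pandas as pd

    populations = (list(populations) if populations is not None
                   else table.populations)
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    mat = np.zeros((len(populations), len(populations)))
    for i in range(len(populations)):
        for j in range(i + 1, len(populations)):
            fst = wc_fstats(table, loci=loci,
                            populations=[populations[i], populations[j]]
                            ).multilocus["FST"]
            mat[i, j] = mat[j, i] = fst if fst is not None else np.nan
    return pd.DataFrame(mat, index=populations, columns=populations)
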