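"""Balding-Nichols genotype simulation with forensic corruption models.

The generator emulates the statistical structure of a two-population canid
STR study: a wolf-like sample (n = 103) and a dog-like sample (n = 198)
typed at 15 autosomal loci carrying 5-26 alleles each, with the two
populations diverged from a shared ancestral allele pool at subdivision
level theta ~= 0.08.  Under the Balding-Nichols model each population's
allele frequencies are a Dirichlet draw

    p_pop ~ Dirichlet(p_ancestral * (1 - theta) / theta),

which has mean p_ancestral and FST-type divergence theta - the same model
family that justifies the theta-corrected match-probability formulas, so
parameter recovery closes the loop.  Within-population departures from
random mating are injected through an inbreeding coefficient
(P(hom i) = p_i^2 + fis * p_i (1 - p_i); P(het ij) = 2 p_i p_j (1 - fis)).

Two corruption operators emulate the genotyping pathologies the screening
stages must detect: hidden null alleles (visible/null heterozygotes appear
as visible homozygotes, null/null as missing) and stutter-like miscalls
(adjacent-size heterozygotes rewritten as homozygotes for the larger
allele).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

from .model import AlleleLabel, GenotypeTable, LocusDef, SampleRecord, canonical_pair

__all__ = [
    "SimConfig",
    "simulate_panel",
    "simulate_populations",
    "simulate_table",
    "inject_null_alleles",
    "inject_stutter_errors",
]

#: Default sample sizes and inbreeding of the emulated study design: a
#: panmictic wild population and a larger domestic sample with mild
#: breeding-induced inbreeding.
DEFAULT_N = {"wolf": 103, "dog": 198}
DEFAULT_FIS = {"wolf": 0.0, "dog": 0.05}


@dataclass
class SimConfig:
    """Full parameterization of the Balding-Nichols generator."""

    n_loci: int = 15
    allele_count_range: Tuple[int, int] = (5, 26)
    ancestral_dirichlet_concentration: float = 1.0
    theta_between: float = 0.08
    fis: Mapping = field(default_factory=lambda: dict(DEFAULT_FIS))
    n_per_population: Mapping = field(default_factory=lambda: dict(DEFAULT_N))
    null_rates: Mapping = field(default_factory=dict)   # (pop, locus) -> r
    stutter_rate: float = 0.0                            # applied to every locus
    #: optional second-level subdivision inside one population, e.g. breed
    #: groups: {"population": "dog", "groups": {"shepherd": 22, ...}, "theta": 0.02}
    substructure: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_count_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid allele_count_range {self.allele_count_range}")
        if not (0.0 <= self.theta_between < 1.0):
            raise ValueError("theta_between must be in [0, 1)")
        if self.ancestral_dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if isinstance(self.fis, (int, float)):
            self.fis = {pop: float(self.fis) for pop in self.n_per_population}
        for pop, f in self.fis.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"fis[{pop!r}] must be in [0, 1)")
        if not (0.0 <= self.stutter_rate < 1.0):
            raise ValueError("stutter_rate must be in [0, 1)")

    def fis_for(self, population: str) -> float:
        return float(self.fis.get(population, 0.0))


def simulate_panel(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Draw the locus panel and its ancestral allele-frequency spectra.

    Per locus the allele count is uniform over ``allele_count_range`` and the
    ancestral frequencies are a symmetric Dirichlet draw; allele labels are
    consecutive size tokens starting at 10.  Returns
    (panel: list[LocusDef], ancestral: {locus: {"alleles": [...], "freqs": array}}).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.allele_count_range
    panel, ancestral = [], {}
    for i in range(config.n_loci):
        name = f"L{i + 1:02d}"
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.full(k, config.ancestral_dirichlet_concentration))
        panel.append(LocusDef(name=name, motif_length=4))
        ancestral[name] = {
            "alleles": [AlleleLabel(str(10 + j)) for j in range(k)],
            "freqs": freqs,
        }
    return panel, ancestral


def _balding_nichols(ancestral_freqs: np.ndarray, theta: float,
                     rng: np.random.Generator) -> np.ndarray:
    if theta == 0.0:
        return ancestral_freqs
    alpha = ancestral_freqs * (1.0 - theta) / theta
    # guard against zero alpha entries from numerically tiny ancestral freqs
    return rng.dirichlet(np.maximum(alpha, 1e-12))


def _draw_genotypes(freqs: np.ndarray, n: int, fis: float,
                    rng: np.random.Generator) -> np.ndarray:
    """n diploid genotypes (allele codes, shape (n, 2)) with inbreeding fis."""
    k = len(freqs)
    first = rng.choice(k, size=n, p=freqs)
    second = rng.choice(k, size=n, p=freqs)
    if fis > 0:
        autozygous = rng.random(n) < fis
        second = np.where(autozygous, first, second)
    return np.stack([first, second], axis=1)


def simulate_populations(panel, ancestral, config: SimConfig,
                         rng: Optional[np.random.Generator] = None) -> GenotypeTable:
    """Draw population allele frequencies and individual genotypes.

    Each population's per-locus frequencies are a Balding-Nichols draw around
    the ancestral spectrum at ``theta_between``; optional substructure adds a
    second Balding-Nichols level inside one population (its groups become the
    population labels of those samples).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sub = config.substructure or {}
    sub_pop = sub.get("population")
    cohorts = []  # (label, n, fis, extra_theta_level)
    for pop, n in config.n_per_population.items():
        if pop == sub_pop:
            for grp, n_grp in sub["groups"].items():
                cohorts.append((grp, int(n_grp), config.fis_for(pop), True))
        else:
            cohorts.append((pop, int(n), config.fis_for(pop), False))

    genotypes_by_cohort = {label: {} for label, *_ in cohorts}
    for loc in panel:
        anc = ancestral[loc.name]
        # one population-level draw per top-level population
        pop_freqs = {pop: _balding_nichols(anc["freqs"], config.theta_between, rng)
                     for pop in config.n_per_population}
        for label, n, fis, nested in cohorts:
            base = pop_freqs[sub_pop] if nested else pop_freqs[label]
            freqs = (_balding_nichols(base, float(sub.get("theta", 0.02)), rng)
                     if nested else base)
            genotypes_by_cohort[label][loc.name] = _draw_genotypes(freqs, n, fis, rng)

    samples = []
    for label, n, _, _ in cohorts:
        for i in range(n):
            genotypes = {}
            for loc in panel:
                codes = genotypes_by_cohort[label][loc.name][i]
                alleles = ancestral[loc.name]["alleles"]
                genotypes[loc.name] = canonical_pair(alleles[codes[0]],
                                                     alleles[codes[1]])
            samples.append(SampleRecord(sample_id=f"{label}_{i + 1:03d}",
                                        population=label, genotypes=genotypes))
    table = GenotypeTable(panel=list(panel), samples=samples)

    for (pop, locus), r in config.null_rates.items():
        table = inject_null_alleles(table, locus, pop, float(r),
                                    seed=int(rng.integers(2 ** 31)))
    if config.stutter_rate > 0:
        for loc in panel:
            table = inject_stutter_errors(table, loc.name, config.stutter_rate,
                                          seed=int(rng.integers(2 ** 31)))
    return table


def simulate_table(config: SimConfig) -> GenotypeTable:
    """Panel + populations in one deterministic call (same seed, same table)."""
    rng = np.random.default_rng(config.seed)
    panel, ancestral = simulate_panel(config, rng)
    return simulate_populations(panel, ancestral, config, rng)


def inject_null_alleles(table: GenotypeTable, locus: str, population: str,
                        r: float, seed: int = 0) -> GenotypeTable:
    """Re-draw one locus in one population with a hidden null allele at
    frequency ``r``.

    Visible frequencies are the currently observed spectrum rescaled by
    (1 - r).  A visible/null heterozygote is recorded as a visible
    homozygote; a null/null genotype is recorded as missing.  Other loci and
    populations are untouched.
    """
    if locus not in table.locus_names:
        raise KeyError(f"locus {locus!r} not in panel")
    if not (0.0 <= r < 1.0):
        raise ValueError("null-allele frequency must be in [0, 1)")
    out = copy.deepcopy(table)
    if r == 0.0:
        return out
    pool = [al for s in out.samples_in(population) if s.is_typed(locus)
            for al in s.genotypes[locus]]
    if not pool:
        raise ValueError(f"no typed genotypes at {locus} in {population}")
    alleles = sorted(set(pool), key=lambda al: al.sort_key)
    counts = np.array([pool.count(al) for al in alleles], dtype=float)
    freqs = np.concatenate([counts / counts.sum() * (1.0 - r), [r]])
    null_code = len(alleles)
    rng = np.random.default_rng(seed)
    targets = [s for s in out.samples if s.population == population]
    draws = np.stack([rng.choice(null_code + 1, size=len(targets), p=freqs),
                      rng.choice(null_code + 1, size=len(targets), p=freqs)],
                     axis=1)
    for s, (c1, c2) in zip(targets, draws):
        if c1 == null_code and c2 == null_code:
            s.genotypes[locus] = None
        elif c1 == null_code:
            s.genotypes[locus] = (alleles[c2], alleles[c2])
        elif c2 == null_code:
            s.genotypes[locus] = (alleles[c1], alleles[c1])
        else:
            s.genotypes[locus] = canonical_pair(alleles[c1], alleles[c2])
    return out


def inject_stutter_errors(table: GenotypeTable, locus: str, rate: float,
                          seed: int = 0) -> GenotypeTable:
    """Rewrite adjacent-size heterozygotes as homozygotes with probability
    ``rate`` (a stutter-driven allele-calling error model).

    Two alleles are adjacent when their parsed sizes are neighbours in the
    sorted set of sizes observed at the locus; the miscall keeps the larger
    allele.  Only heterozygotes are ever modified.
    """
    if locus not in table.locus_names:
        raise KeyError(f"locus {locus!r} not in panel")
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    out = copy.deepcopy(table)
    if rate == 0.0:
        return out
    sizes = sorted({al.parsed_size for s in out.samples if s.is_typed(locus)
                    for al in s.genotypes[locus] if al.parsed_size is not None})
    rank = {sz: i for i, sz in enumerate(sizes)}
    rng = np.random.default_rng(seed)
    for s in out.samples:
        if not s.is_typed(locus):
            continue
        a, b = s.genotypes[locus]
        if a == b or a.parsed_size is None or b.parsed_size is None:
            continue
        if abs(rank[a.parsed_size] - rank[b.parsed_size]) != 1:
            continue
        if rng.random() < rate:
            larger = a if a.sort_key > b.sort_key else b
            s.genotypes[locus] = (larger, larger)
    return out
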