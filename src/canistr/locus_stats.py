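"""Per-locus, per-population allele frequencies and summary statistics.

Implements the standard marker-polymorphism descriptors used to characterise
an STR panel: number of alleles (Na), effective number of alleles
(Ne = 1/Σp²), observed heterozygosity (HO), expected heterozygosity (HE,
with the unbiased small-sample correction 2n/(2n−1) by default), the
polymorphism information content of Botstein et al. (PIC), and a
major-allele dominance flag used during panel triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import AlleleLabel, GenotypeTable

__all__ = [
    "AlleleFrequencySpectrum",
    "LocusSummary",
    "allele_frequencies",
    "locus_summary",
    "pic",
    "major_allele_flag",
    "summary_table",
]


@dataclass
class AlleleFrequencySpectrum:
    """Allele frequencies at one locus in one population sample.

    ``n_typed`` counts individuals with a complete genotype; 2·n_typed is the
    allele-count denominator.  An empty spectrum (n_typed = 0) is a valid
    value, not an error.
    """

    locus: str
    population: str
    n_typed: int
    freqs: dict = field(default_factory=dict)  # AlleleLabel -> float

    def __post_init__(self) -> None:
        if self.n_typed > 0:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies sum to {total}, not 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError("all stored frequencies must be positive")

    @property
    def homozygosity(self) -> float:
        """Σ p_i², the expected homozygosity under random mating."""
        return float(sum(p * p for p in self.freqs.values()))

    def freq(self, allele: AlleleLabel, rare_policy: bool = False) -> float:
        """Frequency of ``allele``; with ``rare_policy`` an absent allele gets
        the conventional minimum frequency 1/(2n+1) instead of zero."""
        p = self.freqs.get(allele, 0.0)
        if p == 0.0 and rare_policy:
            return 1.0 / (2 * self.n_typed + 1)
        return p


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    population: str
    n_typed: int
    Na: int
    Ne: float
    HO: float
    HE: Optional[float]  # None when n_typed < 2
    PIC: float


def allele_frequencies(table: GenotypeTable, locus: str,
                       population: str) -> AlleleFrequencySpectrum:
    """Count alleles over typed individuals; missing genotypes are excluded
    from both numerator and denominator."""
    if locus not in table.locus_names:
        raise KeyError(f"locus {locus!r} not in panel")
    counts: dict = {}
    n_typed = 0
    for s in table.samples_in(population):
        if not s.is_typed(locus):
            continue
        n_typed += 1
        a, b = s.genotypes[locus]
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    denom = 2 * n_typed
    freqs = {al: c / denom for al, c in counts.items()} if n_typed else {}
    return AlleleFrequencySpectrum(locus=locus, population=population,
                                   n_typed=n_typed, freqs=freqs)


def _observed_het(table: GenotypeTable, locus: str, population: str) -> float:
    het = n = 0
    for s in table.samples_in(population):
        if not s.is_typed(locus):
            continue
        n += 1
        a, b = s.genotypes[locus]
        het += a != b
    return het / n if n else 0.0


def expected_heterozygosity(spectrum: AlleleFrequencySpectrum,
                            unbiased: bool = True) -> Optional[float]:
    """HE = 1 − Σp²; the unbiased form multiplies by 2n/(2n−1).

    Returns None when fewer than two typed individuals (the corrected form
    is undefined at n = 1 in any meaningful sense).
    """
    n = spectrum.n_typed
    if n == 0 or (unbiased and n < 2):
        return None
    he = 1.0 - spectrum.homozygosity
    if unbiased:
        he *= (2 * n) / (2 * n - 1)
    return he


def pic(spectrum: AlleleFrequencySpectrum) -> float:
    """Polymorphism information content.

    PIC = 1 − Σ p_i² − Σ_i Σ_{j>i} 2 p_i² p_j².
    """
    if spectrum.n_typed == 0:
        raise ValueError("PIC undefined for an empty spectrum")
    p = np.array(list(spectrum.freqs.values()))
    sq = p * p
    s2 = sq.sum()
    # Σ_i Σ_{j>i} 2 p_i² p_j² = (Σp²)² − Σp⁴
    cross = s2 * s2 - (sq * sq).sum()
    return float(1.0 - s2 - cross)


def locus_summary(spectrum: AlleleFrequencySpectrum, table: GenotypeTable,
                  unbiased: bool = True) -> LocusSummary:
    """Na, Ne, HO, HE and PIC for one (locus, population) cell."""
    if spectrum.n_typed == 0:
        raise ValueError(f"no typed individuals at {spectrum.locus} in "
                         f"{spectrum.population}")
    he = expected_heterozygosity(spectrum, unbiased=unbiased)
    return LocusSummary(
        locus=spectrum.locus,
        population=spectrum.population,
        n_typed=spectrum.n_typed,
        Na=len(spectrum.freqs),
        Ne=float(1.0 / spectrum.homozygosity),
        HO=_observed_het(table, spectrum.locus, spectrum.population),
        HE=he,
        PIC=pic(spectrum),
    )


def major_allele_flag(spectrum: AlleleFrequencySpectrum,
                      threshold: float = 0.5) -> dict:
    """Flag a locus whose most frequent allele reaches ``threshold``.

    Pronounced dominance of one allele depresses the identification power of
    a forensic marker even when many alleles segregate.
    """
    if spectrum.n_typed == 0:
        raise ValueError("dominance flag undefined for an empty spectrum")
    max_allele, max_freq = max(spectrum.freqs.items(), key=lambda kv: kv[1])
    return {"max_allele": max_allele, "max_freq": max_freq,
            "dominated": max_freq >= threshold}


def summary_table(table: GenotypeTable, loci=None, populations=None,
                  unbiased: bool = True):
    """One LocusSummary per (locus, population) with at least one typed
    sample, as a pandas DataFrame (used by the CLI ``stats`` report)."""
    import pandas as pd

    loci = list(loci) if loci is not None else table.autosomal_loci
    populations = list(populations) if populations is not None else table.populations
    rows = []
    for locus in loci:
        for pop in populations:
            spec = allele_frequencies(table, locus, pop)
            if spec.n_typed == 0:
                continue
            s = locus_summary(spec, table, unbiased=unbiased)
            rows.append({"locus": s.locus, "population": s.population,
                         "n_typed": s.n_typed, "Na": s.Na, "Ne": s.Ne,
                         "HO": s.HO, "HE": s.HE, "PIC": s.PIC})
    return pd.DataFrame(rows)
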