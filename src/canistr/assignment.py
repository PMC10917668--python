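"""Frequency-based population assignment with leave-one-out correction.

Each individual's multi-locus genotype frequency is computed in every
candidate reference population under random mating (p^2 for homozygotes,
2pq for heterozygotes, product over typed loci) and reported on the
-ln scale.  The individual is assigned to the population where its genotype
is most probable (smallest -ln frequency).  When scoring an individual
against its own population its two alleles per locus are first removed from
the reference counts (leave-one-out), which removes the upward bias of
self-inclusion.  Alleles unseen in a reference of n typed individuals
receive the conventional minimum frequency 1/(2n+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

from .locus_stats import AlleleFrequencySpectrum, allele_frequencies
from .model import GenotypeTable, SampleRecord

__all__ = [
    "AssignmentResult",
    "genotype_log_frequency",
    "assignment_test",
    "build_spectra",
]


@dataclass
class AssignmentResult:
    per_sample: dict  # sample_id -> record dict
    summary: dict     # population -> {"pct_self_assigned", "mean_delta", "n"}


def build_spectra(table: GenotypeTable, population: Optional[str] = None,
                  loci: Optional[Sequence[str]] = None) -> dict:
    """Reference spectra (locus -> AlleleFrequencySpectrum) for one
    population, or for the pooled table when ``population`` is None."""
    loci = list(loci) if loci is not None else table.autosomal_loci
    if population is None:
        pooled = GenotypeTable(panel=table.panel, samples=[
            SampleRecord(s.sample_id, "all", s.genotypes, s.sex)
            for s in table.samples])
        return {loc: allele_frequencies(pooled, loc, "all") for loc in loci}
    return {loc: allele_frequencies(table, loc, population) for loc in loci}


def _loo_frequency(spectrum: AlleleFrequencySpectrum, allele,
                   own_pair) -> Tuple[float, int]:
    """Allele frequency after removing one individual's own two alleles.

    Returns (count, n_reference): the adjusted allele count and adjusted
    number of typed individuals.
    """
    n_ref = spectrum.n_typed - 1
    count = round(spectrum.freqs.get(allele, 0.0) * 2 * spectrum.n_typed)
    count -= sum(1 for al in own_pair if al == allele)
    return count, n_ref


def genotype_log_frequency(sample: SampleRecord, spectra: Mapping,
                           rare_policy: bool = True,
                           leave_one_out: bool = False) -> Optional[float]:
    """-ln of the multi-locus genotype frequency of ``sample`` in the
    reference described by ``spectra`` (locus -> spectrum).

    Returns None when the sample is typed at none of the reference loci.
    With ``leave_one_out``, the sample's own alleles are removed from the
    counts of any spectrum whose population label matches the sample's.
    """
    total = 0.0
    n_loci = 0
    for locus, spectrum in spectra.items():
        if not sample.is_typed(locus):
            continue
        a, b = sample.genotypes[locus]
        loo = leave_one_out and spectrum.population == sample.population
        if loo:
            n_ref = spectrum.n_typed - 1
            denom = 2 * n_ref
            fa, _ = _loo_frequency(spectrum, a, (a, b))
            fb, _ = _loo_frequency(spectrum, b, (a, b))
            floor = 1.0 / (2 * n_ref + 1)
            pa = fa / denom if denom > 0 and fa > 0 else (floor if rare_policy else 0.0)
            pb = fb / denom if denom > 0 and fb > 0 else (floor if rare_policy else 0.0)
        else:
            pa = spectrum.freq(a, rare_policy=rare_policy)
            pb = spectrum.freq(b, rare_policy=rare_policy)
        if pa <= 0.0 or pb <= 0.0:
            return math.inf  # impossible genotype without the rare policy
        prob = pa * pa if a == b else 2.0 * pa * pb
        total += -math.log(prob)
        n_loci += 1
    return total if n_loci else None


def assignment_test(table: GenotypeTable, populations: Tuple[str, str],
                    loci: Optional[Sequence[str]] = None,
                    rare_policy: bool = True, seed: int = 0) -> AssignmentResult:
    """Leave-one-out assignment test between exactly two populations.

    For every individual: -ln genotype frequency in its own population
    (leave-one-out) versus the other population (full reference); assignment
    goes to the smaller -ln.  The summary reports, per population, the
    percentage of individuals assigned to their own sample and the mean
    absolute difference of the two -ln frequencies.  The computation is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    pop_a, pop_b = populations
    if pop_a == pop_b:
        raise ValueError("population labels must differ")
    for pop in (pop_a, pop_b):
        if len(table.samples_in(pop)) < 10:
            raise ValueError(f"population {pop!r} has fewer than 10 individuals")
    loci = list(loci) if loci is not None else table.autosomal_loci
    spectra = {pop: build_spectra(table, pop, loci) for pop in (pop_a, pop_b)}
    per_sample: dict = {}
    tallies = {pop: {"n": 0, "self": 0, "deltas": []} for pop in (pop_a, pop_b)}
    for s in table.samples:
        if s.population not in (pop_a, pop_b):
            continue
        other = pop_b if s.population == pop_a else pop_a
        own = genotype_log_frequency(s, spectra[s.population],
                                     rare_policy=rare_policy,
                                     leave_one_out=True)
        alt = genotype_log_frequency(s, spectra[other],
                                     rare_policy=rare_policy,
                                     leave_one_out=False)
        if own is None or alt is None:
            continue
        neg_ln = {s.population: own, other: alt}
        assigned = min(neg_ln, key=neg_ln.get)
        delta = abs(own - alt)
        per_sample[s.sample_id] = {"population": s.population,
                                   "neg_ln_freq": neg_ln,
                                   "assigned": assigned, "delta": delta}
        t = tallies[s.population]
        t["n"] += 1
        t["self"] += assigned == s.population
        t["deltas"].append(delta)
    summary = {}
    for pop, t in tallies.items():
        summary[pop] = {
            "n": t["n"],
            "pct_self_assigned": 100.0 * t["self"] / t["n"] if t["n"] else float("nan"),
            "mean_delta": (sum(t["deltas"]) / len(t["deltas"])
                           if t["deltas"] else float("nan")),
        }
    return AssignmentResult(per_sample=per_sample, summary=summary)
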