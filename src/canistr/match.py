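"""Theta-corrected forensic match probabilities.

Single-locus genotype probabilities follow the subdivision-corrected
(NRC-II recommendation 4.2 style) formulas with coancestry coefficient
theta:

    homozygote  (p):    P = [2t + (1-t)p][3t + (1-t)p] / [(1+t)(1+2t)]
    heterozygote (p,q): P = 2[t + (1-t)p][t + (1-t)q] / [(1+t)(1+2t)]

At theta = 0 these reduce exactly to the product rule p^2 and 2pq.  The
multi-locus report lists loci in increasing theta order and carries running
products with and without the correction; the cohort average summarises the
final cumulative frequency across all fully typed animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .locus_stats import AlleleFrequencySpectrum
from .model import GenotypeTable, SampleRecord

__all__ = [
    "MatchReport",
    "CohortAverage",
    "single_locus_match_prob",
    "multilocus_match_probability",
    "cohort_average_match_probability",
]


@dataclass
class MatchReport:
    sample_id: str
    locus_order: list
    per_locus: dict  # locus -> {genotype, theta, p_no_theta, p_with_theta}
    cumulative_no_theta: list
    cumulative_with_theta: list

    @property
    def final_no_theta(self) -> float:
        return self.cumulative_no_theta[-1]

    @property
    def final_with_theta(self) -> float:
        return self.cumulative_with_theta[-1]


@dataclass(frozen=True)
class CohortAverage:
    mean_freq_no_theta: float
    mean_freq_with_theta: float
    averaging_mode: str  # "geometric" | "arithmetic"
    n_samples: int


def single_locus_match_prob(genotype, spectrum: AlleleFrequencySpectrum,
                            theta: float = 0.0,
                            rare_policy: bool = True) -> float:
    """Subdivision-corrected probability of one single-locus genotype.

    ``genotype`` is an (AlleleLabel, AlleleLabel) pair; frequencies come from
    ``spectrum`` with the 1/(2n+1) floor for unseen alleles when
    ``rare_policy`` is on.
    """
    if not (0.0 <= theta < 1.0):
        raise ValueError(f"theta must be in [0, 1), got {theta}")
    a, b = genotype
    p = spectrum.freq(a, rare_policy=rare_policy)
    if p <= 0.0:
        raise ValueError(f"allele {a.token!r} absent from reference and rare "
                         f"policy disabled")
    denom = (1.0 + theta) * (1.0 + 2.0 * theta)
    if a == b:
        return ((2 * theta + (1 - theta) * p)
                * (3 * theta + (1 - theta) * p)) / denom
    q = spectrum.freq(b, rare_policy=rare_policy)
    if q <= 0.0:
        raise ValueError(f"allele {b.token!r} absent from reference and rare "
                         f"policy disabled")
    return 2.0 * (theta + (1 - theta) * p) * (theta + (1 - theta) * q) / denom


def multilocus_match_probability(sample: SampleRecord, spectra: Mapping,
                                 thetas: Mapping, use_theta: bool = True,
                                 rare_policy: bool = True) -> Optional[MatchReport]:
    """Per-locus and cumulative genotype probabilities for one profile.

    Loci are ordered by ascending theta (ties by name) over loci present in
    both ``spectra`` and ``thetas`` at which the sample is typed; cumulative
    column k is the product of the first k per-locus values.  Returns None
    when the sample is typed at no panel locus.
    """
    order = sorted((loc for loc in thetas if loc in spectra
                    and sample.is_typed(loc)),
                   key=lambda loc: (thetas[loc], loc))
    if not order:
        return None
    per_locus: dict = {}
    cum0, cumt = [], []
    r0 = rt = 1.0
    for locus in order:
        g = sample.genotypes[locus]
        theta = float(thetas[locus]) if use_theta else 0.0
        p0 = single_locus_match_prob(g, spectra[locus], 0.0, rare_policy)
        pt = single_locus_match_prob(g, spectra[locus], theta, rare_policy)
        per_locus[locus] = {"genotype": g, "theta": theta,
                            "p_no_theta": p0, "p_with_theta": pt}
        r0 *= p0
        rt *= pt
        cum0.append(r0)
        cumt.append(rt)
    return MatchReport(sample_id=sample.sample_id, locus_order=order,
                       per_locus=per_locus, cumulative_no_theta=cum0,
                       cumulative_with_theta=cumt)


def cohort_average_match_probability(table: GenotypeTable, spectra: Mapping,
                                     thetas: Mapping,
                                     mode: str = "geometric",
                                     rare_policy: bool = True) -> CohortAverage:
    """Average final multi-locus genotype frequency across all animals fully
    typed at the panel, with and without the theta correction.

    Geometric mode (default) exponentiates the mean log10 frequency, the
    natural average for multiplicative quantities; arithmetic mode is the
    plain mean.
    """
    if mode not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    loci = [loc for loc in thetas if loc in spectra]
    finals0, finalst = [], []
    for s in table.samples:
        if not all(s.is_typed(loc) for loc in loci):
            continue
        rep = multilocus_match_probability(s, spectra, thetas,
                                           use_theta=True,
                                           rare_policy=rare_policy)
        finals0.append(rep.final_no_theta)
        finalst.append(rep.final_with_theta)
    if not finals0:
        raise ValueError("no sample is fully typed at the panel")
    if mode == "geometric":
        avg0 = 10.0 ** (sum(map(math.log10, finals0)) / len(finals0))
        avgt = 10.0 ** (sum(map(math.log10, finalst)) / len(finalst))
    else:
        avg0 = sum(finals0) / len(finals0)
        avgt = sum(finalst) / len(finalst)
    return CohortAverage(mean_freq_no_theta=avg0, mean_freq_with_theta=avgt,
                         averaging_mode=mode, n_samples=len(finals0))
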