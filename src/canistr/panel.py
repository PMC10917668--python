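"""Locus-triage cascade for assembling a forensic STR panel.

From a candidate locus set, loci are excluded on four independent grounds,
applied in order: (1) genotyping-error evidence from the homozygote-excess
size-class scan, (2) null-allele burden in two or more population samples,
(3) pronounced major-allele dominance in every population, and (4)
statistically significant Hardy-Weinberg deviation that survives the
Bonferroni correction (family = loci within each population).  A locus is
excluded as soon as any rule fires; the report records every reason so that
the triage is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hwe import (bonferroni_adjust, homozygote_excess_scan, hwe_exact_test,
                  null_allele_estimates)
from .locus_stats import (allele_frequencies, expected_heterozygosity,
                          major_allele_flag)
from .model import GenotypeTable, LocusDef

__all__ = ["FilterCriteria", "FilterReport", "apply_locus_filters",
           "DEFAULT_PANEL"]

#: The 15 autosomal markers of the published canid identification panel.
#: Inferred composition: the candidate set minus the error-flagged,
#: null-burdened and dominance-excluded markers; 13 tetranucleotide loci
#: plus the two dinucleotide survivors FH2054 and FH2079.
DEFAULT_PANEL = [
    LocusDef("CPH4", 4), LocusDef("CPH12", 4), LocusDef("FH2001", 4),
    LocusDef("FH2004", 4), LocusDef("FH2010", 4), LocusDef("FH2016", 4),
    LocusDef("FH2054", 2), LocusDef("FH2079", 2), LocusDef("FH2096", 4),
    LocusDef("FH2328", 4), LocusDef("FH2361", 4), LocusDef("PEZ16", 4),
    LocusDef("PEZ17", 4), LocusDef("VGL3438", 4), LocusDef("vWF.x", 4),
]


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the four exclusion rules."""

    error_alpha: float = 0.05          # size-class scan significance level
    null_threshold: float = 0.05       # min of the two null estimates
    null_min_populations: int = 2      # populations exceeding it to exclude
    dominance_threshold: float = 0.5   # major-allele frequency
    hwe_alpha: float = 0.05            # per-population Bonferroni family
    n_shuffles: int = 2000             # HWE Monte-Carlo shuffles
    n_mc: int = 1000                   # scan Monte-Carlo draws
    n_size_classes: int = 4


@dataclass
class FilterReport:
    per_locus: dict   # locus -> audit dict
    retained: list    # ordered retained locus names
    criteria: FilterCriteria
    seed: int

    def reasons(self, locus: str) -> list:
        return self.per_locus[locus]["reasons"]


def apply_locus_filters(table: GenotypeTable,
                        loci: Optional[Sequence[str]] = None,
                        populations: Optional[Sequence[str]] = None,
                        criteria: Optional[FilterCriteria] = None,
                        seed: int = 0) -> FilterReport:
    """Run the four-rule exclusion cascade over loci x populations.

    All Monte-Carlo sub-tests derive their seeds deterministically from
    ``seed`` and the (locus, population) position, so the report is
    reproducible.
    """
    crit = criteria if criteria is not None else FilterCriteria()
    loci = list(loci) if loci is not None else table.autosomal_loci
    populations = (list(populations) if populations is not None
                   else table.populations)
    if len(populations) < 2:
        raise ValueError("need at least two populations")

    # HWE first, because the Bonferroni family spans loci within a population
    hwe_by_pop: dict = {}
    for pj, pop in enumerate(populations):
        results = []
        for li, locus in enumerate(loci):
            child = int(np.random.SeedSequence([seed, 1, li, pj]).generate_state(1)[0]
                        % (2 ** 31))
            results.append(hwe_exact_test(table, locus, pop,
                                          n_shuffles=crit.n_shuffles,
                                          seed=child, alpha=crit.hwe_alpha))
        hwe_by_pop[pop] = {r.locus: r for r in
                           bonferroni_adjust(results, alpha=crit.hwe_alpha)}

    per_locus: dict = {}
    retained: list = []
    for li, locus in enumerate(loci):
        error_pops, null_pops, dominated_pops, analyzed_pops = [], [], [], []
        hwe_pops = []
        for pj, pop in enumerate(populations):
            spec = allele_frequencies(table, locus, pop)
            if spec.n_typed == 0:
                continue
            analyzed_pops.append(pop)
            child = int(np.random.SeedSequence([seed, 2, li, pj]).generate_state(1)[0]
                        % (2 ** 31))
            try:
                scan = homozygote_excess_scan(
                    table, locus, pop, n_size_classes=crit.n_size_classes,
                    n_mc=crit.n_mc, seed=child, alpha=crit.error_alpha)
                if scan.flagged:
                    error_pops.append(pop)
            except ValueError:
                pass  # too few typed individuals for the scan
            ho = sum(1 for s in table.samples_in(pop) if s.is_typed(locus)
                     and s.genotypes[locus][0] != s.genotypes[locus][1])
            ho /= spec.n_typed
            he = expected_heterozygosity(spec)
            if he is not None:
                est = null_allele_estimates(ho, he, threshold=crit.null_threshold)
                if est.flagged:
                    null_pops.append(pop)
            if major_allele_flag(spec, crit.dominance_threshold)["dominated"]:
                dominated_pops.append(pop)
            res = hwe_by_pop[pop].get(locus)
            if res is not None and res.defined and res.significant_bonferroni:
                hwe_pops.append(pop)

        error_flag = len(error_pops) > 0
        null_flag = len(null_pops)
        dominance_flag = (len(analyzed_pops) > 0
                          and len(dominated_pops) == len(analyzed_pops))
        hwe_flag = len(hwe_pops)
        reasons = []
        if error_flag:
            reasons.append(f"genotyping-error signal in {sorted(error_pops)}")
        if null_flag >= crit.null_min_populations:
            reasons.append(f"null-allele burden in {null_flag} populations "
                           f"{sorted(null_pops)}")
        if dominance_flag:
            reasons.append(f"major-allele dominance (>= "
                           f"{crit.dominance_threshold}) in all populations")
        if hwe_flag >= 1:
            reasons.append(f"post-Bonferroni HWE deviation in {sorted(hwe_pops)}")
        decision = "exclude" if reasons else "retain"
        per_locus[locus] = {
            "error_flag": error_flag,
            "null_flag": null_flag,
            "dominance_flag": dominance_flag,
            "hwe_flag": hwe_flag,
            "decision": decision,
            "reasons": reasons,
        }
        if decision == "retain":
            retained.append(locus)
    return FilterReport(per_locus=per_locus, retained=retained,
                        criteria=crit, seed=seed)
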