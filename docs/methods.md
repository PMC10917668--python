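# Methods

This note documents the statistical model behind each analysis stage, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

A genotype table is a panel of STR loci plus one record per individual:
population label, optional sex, and an unordered allele pair per locus.
Allele labels are opaque string tokens compared by string equality; the
leading digits give a size class used only for ordering and for the
size-class scan, so repeat counts, base-pair sizes and suffixed
microvariants (`10in`) coexist without arithmetic being done on them.
`0` or an empty cell denotes a missing allele, and a genotype with either
allele missing is treated as wholly missing — the standard codominant-table
convention. Sex markers (marker class `sex`) are carried for sexing only and
are excluded from every statistical operation. Within a pair, alleles are
stored ascending by (size class, token), so a file with swapped allele
columns reads to an equal table.

## Locus summaries

Per locus and population: allele frequencies over 2n typed individuals;
Na = number of alleles; Ne = 1/Σp² (effective number of alleles);
HO = fraction of heterozygous typed individuals; HE = (2n/(2n−1))(1 − Σp²),
the unbiased small-sample form (the biased 1 − Σp² is available via
`unbiased=False`; at n = 10⁴ the two differ by < 10⁻⁴). PIC follows
Botstein: 1 − Σpᵢ² − ΣᵢΣ_{j>i} 2pᵢ²pⱼ², computed via the closed form
(Σp²)² − Σp⁴ for the cross term and checked in tests against a literal
double loop. A locus is "dominated" when its most frequent allele reaches
the dominance threshold (default 0.5); dominance depresses identification
power even at high allele counts.

## Hardy–Weinberg exact test

The conditional exact test for multi-allelic loci, evaluated by Monte
Carlo: the 2n observed alleles are repeatedly shuffled into n diploid
genotypes (default 5000 shuffles), and the p-value is the proportion of
shuffled arrays whose conditional probability given the allele counts is at
most that of the observed array, with the +1/+1 correction so p ≥ 1/(B+1).
Because the allele counts are fixed within a shuffle set, only the
non-constant part of the log probability is compared:
H·ln2 − Σ log(genotype-cell count!), with a 10⁻⁹ tie tolerance on the log
scale. The statistic is the probability itself (two-sided by probability
ordering), which is well defined for any number of alleles — not a
heterozygote-deficit direction test. Monomorphic loci admit a single array
and return p = 1; fewer than 5 typed individuals returns an undefined
marker rather than a number. Under the null the test is calibrated: over
2000 HWE populations (n = 50, four alleles at 0.4/0.3/0.2/0.1, 1000
shuffles) the rejection rate at α = 0.05 is 0.049 and the p-value
distribution passes a Kolmogorov–Smirnov uniformity check.

Bonferroni correction: significant_bonferroni = (p ≤ α/m) with m the number
of defined tests in the family the caller groups — in the triage cascade,
loci within each population. A family of one reduces to the raw decision.

## Null-allele estimators and the homozygote-excess scan

Two moment estimators driven by the heterozygote deficit:
Chakraborty r = (HE−HO)/(HE+HO) and Brookfield r = (HE−HO)/(1+HE).
Negative values (heterozygote excess) are reported as-is; the flag fires
only when both exceed the threshold (default 0.05). Under the hidden-null
model used throughout (a null allele of frequency r; visible/null
heterozygotes appear as visible homozygotes; null/null as missing) the
Chakraborty estimator is exactly consistent — the apparent allele
frequencies are p/(1−r) and apparent HO = HE·(1−r)/(1+r), which solves back
to r — and simulation recovery at n = 500 over 200 replicates is within
±0.03 for r ∈ {0.05, 0.1, 0.2}.

The size-class scan bins alleles by parsed size into equal-width classes
(default 4) and compares the observed homozygote count per occupied class
with its Monte-Carlo HWE expectation (genotypes resampled from the
spectrum, default 1000 draws, one-sided α = 0.05). The locus-level error
flag fires when a strict majority of occupied classes shows significant
excess **or** when the total homozygote count is itself in significant
excess. The second clause is load-bearing: a stutter miscall always
converts an adjacent-size heterozygote into a homozygote for the *larger*
allele, so the excess concentrates in upper classes and a per-class
majority alone can never fire at k = 2 and rarely fires at realistic allele
counts; the total-excess test restores power (≈ 92 % detection at miscall
rate 0.2, five equifrequent alleles, n = 500) at a measured clean-data
false-flag rate of ≈ 2 %. This scan is a deliberately simplified surrogate
for a full stutter/dropout diagnostic: it detects that homozygotes are in
excess and where in the size range, not the mechanism.

## F-statistics, θ, AMOVA

Weir–Cockerham (1984) estimators: for every allele, variance components
a (among populations), b (among individuals within populations) and
c (within individuals) from the per-population sample sizes, allele
frequencies and per-allele heterozygote frequencies; components are summed
over alleles within a locus, and multi-locus estimates are ratios of
component sums across loci — never averages of per-locus ratios. Per locus
FST = a/(a+b+c), FIS = b/(b+c), FIT = (a+b)/(a+b+c), so
(1−FIT) = (1−FIS)(1−FST) holds to machine precision wherever all three are
defined. Negative components are kept in all sums for estimator fidelity;
loci with zero total variance are carried as undefined and excluded from
the sums. The forensic subdivision coefficient is θ = max(FST, 0) per locus
(only the display/forensic quantity is clamped), ordered ascending with
ties broken by locus name.

AMOVA is one-level on the allele-mismatch metric: every allele copy is an
analysis unit and two copies differ with squared distance 0 or 1 (the
FST-like choice; a squared-size RST-like metric is out of scope). Under
this metric the sums of squares reduce to allele-count algebra —
SSD_total = (N − Σc²/N)/2 over all copies, SSD_within likewise per group —
so no distance matrix is formed and permutations are batched as matrix
products. Working at the allele-copy level matters: decomposing distances
between whole genotypes (d ∈ {0,1,2}) inflates φ_ST by roughly 1.6× over
the Weir–Cockerham FST on the same data, while the allele-copy
decomposition agrees with it to four decimals on Balding–Nichols
simulations. Components are summed across loci with locus-wise deletion of
missing genotypes. The permutation test moves whole individuals (both
allele copies together), preserving within-individual correlation under
the null; p carries the +1/+1 correction and is calibrated (rejection rate
0.05 at α = 0.05 over 1000 null datasets, 199 permutations each).

## Assignment test

For each individual and each of two reference populations, −ln Π over typed
loci of the genotype frequency (p² or 2pq) in that reference; assignment to
the smaller −ln. Against its own population the individual's two alleles
are first removed from the counts (leave-one-out), which removes the
upward self-inclusion bias — tests verify self-assignment without the
correction is never lower. Alleles unseen in a reference of n typed
individuals (including after removal) receive 1/(2n+1), the standard floor
in frequency-based assignment; with leave-one-out, n is the reduced
reference size, which keeps the score finite even when the reference
consisted of that single individual. Loci untyped in a sample are skipped
(product over typed loci only); the reported delta is |−ln f_own − (−ln
f_other)|, averaged arithmetically per population.

## Match probabilities

Single-locus genotype probabilities with the subdivision correction
(coancestry θ):

    P(AiAi) = [2θ + (1−θ)p][3θ + (1−θ)p] / [(1+θ)(1+2θ)]
    P(AiAj) = 2[θ + (1−θ)p][θ + (1−θ)q] / [(1+θ)(1+2θ)]

which reduce exactly (≤ 10⁻¹⁵ in tests) to p² and 2pq at θ = 0. The
homozygote correction is conservative for all p and θ (≥ p² on a 10⁴-point
grid with zero violations); the heterozygote correction is *not* uniformly
conservative (p = q = 0.5, θ = 0.2 gives 0.4286 < 0.5) — a known
non-property, tested as such. Multi-locus reports list loci ascending by θ
with running products with and without the correction; the final cumulative
equals the brute-force product of per-locus values. The θ source is the
per-locus truncated Weir–Cockerham FST by default; a fixed scalar (e.g.
0.03) can be supplied for conservative reporting. Unseen alleles get the
same 1/(2n+1) floor as in assignment.

Cohort averaging is geometric by default — the mean of log₁₀ final
frequencies, exponentiated — because the averaged quantity is
multiplicative across loci and spans many orders of magnitude; an
arithmetic mode exists for sensitivity analysis (it is dominated by the
most common profiles). On the default simulated cohort the with-θ average
exceeds the product-rule average by several orders of magnitude, the
direction that makes θ-corrected figures the defensible ones in casework.

## Panel triage

Four independent rules, applied per locus in a fixed order with
any-rule-fires semantics, every reason recorded: (1) genotyping-error
signal — the size-class scan flags the locus in at least one population;
(2) null-allele burden — both null estimators exceed the threshold
(default 0.05) in at least `null_min_populations` (default 2) populations;
(3) major-allele dominance — the dominance threshold (default 0.5) is
reached in *every* analyzed population; (4) HWE deviation that survives
Bonferroni within its population's locus family (α = 0.05). Rules do not
interact: a locus with injected null alleles genuinely exhibits homozygote
excess, so it typically carries the error-scan reason alongside the
null-burden reason — both statements are true of the data. Decisions are
monotone in the thresholds, and all Monte-Carlo sub-tests derive their
seeds deterministically from the report seed and the (locus, population)
position, so the audit is exactly reproducible.

## Synthetic data

The generator emulates the structure of the emulated study design: a
wolf-like sample (n = 103, panmictic) and a dog-like sample (n = 198, mild
inbreeding fis = 0.05 by default) typed at 15 autosomal loci with 5–26
alleles each, diverged at θ = 0.08. Per locus, the allele count is uniform
on the configured range, ancestral frequencies are a symmetric Dirichlet
draw (concentration 1.0 — realistic skewed spectra; large values give
equifrequent alleles), and each population's frequencies follow
Balding–Nichols: Dirichlet(p_anc·(1−θ)/θ), mean p_anc, divergence θ. This
is the same model family that justifies the θ-corrected match formulas, so
FST/θ recovery closes the loop (multi-locus Weir–Cockerham FST recovers
θ ∈ {0.02, 0.08, 0.15} within ±0.02 over 100 replicates at n = 100/pop).
Genotypes are drawn with P(hom i) = pᵢ² + fis·pᵢ(1−pᵢ),
P(het ij) = 2pᵢpⱼ(1−fis); FIS recovery at fis = 0.2, n = 500 is within
±0.03. Optional second-level substructure (breed groups inside the dog-like
population, their own small θ) is off by default. Null alleles and stutter
miscalls are injected by the corruption operators described above;
injection with r = 0 or rate = 0 is the identity.

What the generator does **not** emulate: stepwise mutation (allele
frequencies are exchangeable across size classes, so RST-type size
structure is absent), linkage between loci (all loci independent, matching
the panel's design intent), allele dropout at low template, population
growth or migration history, and real breed structure. Passing tests
therefore demonstrate that the estimators and the triage behave correctly
under the stated model — not that any particular real population satisfies
that model. Headline published values from the original casework database
(e.g. the 8.28 % AMOVA partition or the three-orders-of-magnitude cohort
gap) are treated as qualitative envelopes, since those genotypes are not
public; the one quantitative surrogate (`scripts/acceptance.py`) is the
100 % leave-one-out self-assignment on the study-sized simulation.

## Numerical and design choices

- Monte-Carlo p-values always use the +1/+1 correction; same seed + same
  inputs ⇒ identical p-values everywhere.
- HWE log-probability ties are compared with a 10⁻⁹ tolerance on the log
  scale; the monomorphic shortcut returns p = 1 without sampling.
- Frequencies are exact count ratios; the leave-one-out adjustment
  reconstructs integer counts from the spectrum before subtraction.
- The simulator guards Balding–Nichols Dirichlet parameters at ≥ 10⁻¹²
  against numerically tiny ancestral frequencies; θ = 0 bypasses the draw
  entirely (exact-ancestral special case).
- Default problem sizes in tests and acceptance checks (e.g. 100–1000
  replicates, n = 100–500 per population, 199–1000 permutations/shuffles)
  were chosen to put Monte-Carlo noise well inside each stated tolerance
  while keeping the full suite around a minute on one core.
- Sex loci are supported at the data-model level (carried, excluded from
  statistics); the simulator does not generate them — its purpose is the
  autosomal statistics.
- The shipped 15-locus default panel is an inferred reconstruction of the
  published marker set (13 tetranucleotide loci plus FH2054 and FH2079) and
  is marked as such in the source; analyses never require it.

## Known limitations

- The exact HWE test is Monte-Carlo only; full enumeration for small n and
  mid-p variants are not implemented.
- The error scan detects homozygote excess patterns; it cannot separate
  stutter from null alleles or short-allele dominance by mechanism, only by
  where the excess falls.
- AMOVA is one-level (no hierarchical designs, no RST) and the assignment
  test supports exactly two reference populations.
- Cohort match averages depend on the averaging convention; both geometric
  and arithmetic modes are reported by the API for sensitivity.
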