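import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from canistr.model import (AlleleLabel, GenotypeTable, LocusDef, SampleRecord,
                           canonical_pair)
from canistr.simulate import SimConfig, simulate_table


def make_locus_table(freq_map, n, seed=0, fis=0.0, population="A",
                     locus="LOC", extra_pops=()):
    """Single-locus HWE (or inbred) population drawn from explicit allele
    frequencies; ``freq_map`` maps token -> frequency."""
    rng = np.random.default_rng(seed)
    tokens = list(freq_map)
    p = np.array([freq_map[t] for t in tokens], dtype=float)
    p = p / p.sum()
    alleles = [AlleleLabel(t) for t in tokens]
    samples = []
    pops = [(population, n)] + list(extra_pops)
    for pop, n_pop in pops:
        a = rng.choice(len(tokens), size=n_pop, p=p)
        b = rng.choice(len(tokens), size=n_pop, p=p)
        if fis > 0:
            b = np.where(rng.random(n_pop) < fis, a, b)
        for i, (x, y) in enumerate(zip(a, b)):
            samples.append(SampleRecord(
                sample_id=f"{pop}{i}", population=pop,
                genotypes={locus: canonical_pair(alleles[x], alleles[y])}))
    return GenotypeTable(panel=[LocusDef(locus)], samples=samples)


def make_multipop_table(freqs_by_pop, n_by_pop, seed=0, locus="LOC"):
    """Single-locus table with explicit per-population frequencies."""
    rng = np.random.default_rng(seed)
    samples = []
    for pop, freq_map in freqs_by_pop.items():
        tokens = list(freq_map)
        p = np.array([freq_map[t] for t in tokens], dtype=float)
        p = p / p.sum()
        alleles = [AlleleLabel(t) for t in tokens]
        a = rng.choice(len(tokens), size=n_by_pop[pop], p=p)
        b = rng.choice(len(tokens), size=n_by_pop[pop], p=p)
        for i, (x, y) in enumerate(zip(a, b)):
            samples.append(SampleRecord(
                sample_id=f"{pop}{i}", population=pop,
                genotypes={locus: canonical_pair(alleles[x], alleles[y])}))
    return GenotypeTable(panel=[LocusDef(locus)], samples=samples)


@pytest.fixture
def tiny_table():
    """Three samples, two loci, one missing genotype, mixed suffix labels."""
    a10, a12, a10in = AlleleLabel("10"), AlleleLabel("12"), AlleleLabel("10in")
    return GenotypeTable(
        panel=[LocusDef("FH2001"), LocusDef("CPH4")],
        samples=[
            SampleRecord("w1", "wolf",
                         {"FH2001": (a10, a10in), "CPH4": (a10, a12)}),
            SampleRecord("w2", "wolf",
                         {"FH2001": (a10, a10), "CPH4": None}),
            SampleRecord("d1", "dog",
                         {"FH2001": (a12, a12), "CPH4": (a12, a12)}),
        ])


def make_triage_table(seed=3, n=400):
    """Six-locus, two-population triage fixture: one stutter-corrupted locus,
    one null-allele locus (r = 0.2 in both populations), one major-allele
    dominated locus, three clean loci."""
    from canistr.simulate import inject_null_alleles, inject_stutter_errors

    rng = np.random.default_rng(seed)
    freqs = {
        "STUT": {str(10 + i): 0.2 for i in range(5)},
        "NULLED": {str(10 + i): f for i, f in
                   enumerate((0.3, 0.25, 0.2, 0.1, 0.1, 0.05))},
        "DOM": {"10": 0.8, "11": 0.1, "12": 0.05, "13": 0.05},
        "CLEAN1": {str(10 + i): 1 / 6 for i in range(6)},
        "CLEAN2": {str(10 + i): f for i, f in
                   enumerate((0.3, 0.25, 0.2, 0.15, 0.1))},
        "CLEAN3": {str(10 + i): 0.125 for i in range(8)},
    }
    panel = [LocusDef(name) for name in freqs]
    samples = []
    for pop in ("wolf", "dog"):
        for i in range(n):
            genotypes = {}
            for locus, fm in freqs.items():
                tokens = list(fm)
                p = np.array([fm[t] for t in tokens])
                p = p / p.sum()
                x, y = rng.choice(len(tokens), size=2, p=p)
                genotypes[locus] = canonical_pair(AlleleLabel(tokens[x]),
                                                  AlleleLabel(tokens[y]))
            samples.append(SampleRecord(f"{pop}{i}", pop, genotypes))
    t = GenotypeTable(panel=panel, samples=samples)
    t = inject_stutter_errors(t, "STUT", 0.25, seed=seed + 1)
    t = inject_null_alleles(t, "NULLED", "wolf", 0.2, seed=seed + 2)
    t = inject_null_alleles(t, "NULLED", "dog", 0.2, seed=seed + 3)
    return t


@pytest.fixture(scope="session")
def study_table():
    """The default two-population study scenario without inbreeding
    (15 loci, 5-26 alleles, theta 0.08, n = 103 wolves + 198 dogs)."""
    return simulate_table(SimConfig(seed=11, fis=0.0))
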