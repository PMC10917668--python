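import numpy as np
import pytest

from canistr.fstats import amova, pairwise_fst, per_locus_theta, wc_fstats
from canistr.model import AlleleLabel, GenotypeTable, LocusDef, SampleRecord
from canistr.simulate import SimConfig, simulate_table

from conftest import make_multipop_table


# ---------------------------------------------------------------------------
# independent oracles: plain-loop transcriptions of the published estimators
# ---------------------------------------------------------------------------

def wc_oracle(table, locus, populations):
    """Weir-Cockerham (1984) a/b/c via explicit per-allele loops."""
    stats = {}
    alleles = set()
    for pop in populations:
        genos = [s.genotypes[locus] for s in table.samples_in(pop)
                 if s.is_typed(locus)]
        n = len(genos)
        counts, hets = {}, {}
        for g in genos:
            for al in g:
                counts[al] = counts.get(al, 0) + 1
            if g[0] != g[1]:
                for al in g:
                    hets[al] = hets.get(al, 0) + 1
        stats[pop] = (n, counts, hets)
        alleles |= set(counts)
    r = len(populations)
    nbar = sum(stats[p][0] for p in populations) / r
    nc = (r * nbar - sum(stats[p][0] ** 2 for p in populations) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        pbar = sum(stats[p][1].get(al, 0) / 2 for p in populations) / (r * nbar)
        s2 = sum(stats[p][0] * (stats[p][1].get(al, 0) / (2 * stats[p][0]) - pbar) ** 2
                 for p in populations) / ((r - 1) * nbar)
        hbar = sum(stats[p][2].get(al, 0) for p in populations) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        A += nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        B += nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        C += hbar / 2
    return A, B, C


def amova_oracle(table, loci, populations):
    """One-level AMOVA on allele units via explicit sums of squares."""
    sigma_a = sigma_w = 0.0
    for locus in loci:
        units, labels = [], []
        for pop in populations:
            for s in table.samples_in(pop):
                if s.is_typed(locus):
                    units += [al.token for al in s.genotypes[locus]]
                    labels += [pop, pop]
        N = len(units)
        groups = sorted(set(labels))
        ssd_t = sum(units[i] != units[j]
                    for i in range(N) for j in range(i + 1, N)) / N
        ssd_w = 0.0
        for g in groups:
            idx = [i for i, l in enumerate(labels) if l == g]
            ssd_w += sum(units[i] != units[j]
                         for i in idx for j in idx if i < j) / len(idx)
        G = len(groups)
        ms_w = ssd_w / (N - G)
        n_prime = (N - sum(labels.count(g) ** 2 for g in groups) / N) / (G - 1)
        sigma_a += ((ssd_t - ssd_w) / (G - 1) - ms_w) / n_prime
        sigma_w += ms_w
    return sigma_a, sigma_w


class TestWCFstats:
    def test_matches_loop_oracle_on_divergent_populations(self):
        t = make_multipop_table(
            {"A": {"10": 0.9, "11": 0.1}, "B": {"10": 0.1, "11": 0.9}},
            {"A": 200, "B": 200}, seed=3)
        res = wc_fstats(t, populations=["A", "B"])
        a, b, c = wc_oracle(t, "LOC", ["A", "B"])
        comp = res.per_locus["LOC"]
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)
        assert comp.fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_strong_divergence_yields_large_fst(self):
        t = make_multipop_table(
            {"A": {"10": 0.9, "11": 0.1}, "B": {"10": 0.1, "11": 0.9}},
            {"A": 1000, "B": 1000}, seed=5)
        fst = wc_fstats(t).per_locus["LOC"].fst
        # E[FST] for these frequencies is high; oracle equivalence pins it
        a, b, c = wc_oracle(t, "LOC", ["A", "B"])
        assert fst == pytest.approx(a / (a + b + c), abs=1e-12)
        assert fst > 0.5

    def test_identical_populations_near_zero(self):
        t = make_multipop_table(
            {"A": {"10": 0.6, "11": 0.4}, "B": {"10": 0.6, "11": 0.4}},
            {"A": 1000, "B": 1000}, seed=7)
        assert abs(wc_fstats(t).per_locus["LOC"].fst) < 0.01

    def test_fit_identity_per_locus(self, study_table):
        res = wc_fstats(study_table)
        for locus, comp in res.per_locus.items():
            if not comp.defined or (comp.b + comp.c) == 0:
                continue
            assert (1 - comp.fit) == pytest.approx(
                (1 - comp.fis) * (1 - comp.fst), abs=1e-12)

    def test_single_population_rejected(self, study_table):
        with pytest.raises(ValueError):
            wc_fstats(study_table, populations=["wolf"])

    def test_monomorphic_locus_undefined_and_excluded(self):
        a = AlleleLabel("10")
        t = GenotypeTable(panel=[LocusDef("L")], samples=(
            [SampleRecord(f"a{i}", "A", {"L": (a, a)}) for i in range(10)]
            + [SampleRecord(f"b{i}", "B", {"L": (a, a)}) for i in range(10)]))
        res = wc_fstats(t)
        assert not res.per_locus["L"].defined
        assert res.multilocus["FST"] is None


class TestTheta:
    def test_negative_fst_truncates_to_zero(self):
        t = make_multipop_table(
            {"A": {"10": 0.5, "11": 0.5}, "B": {"10": 0.5, "11": 0.5}},
            {"A": 40, "B": 40}, seed=11)
        res = wc_fstats(t)
        thetas = per_locus_theta(res)
        assert thetas["LOC"] >= 0.0
        if res.per_locus["LOC"].fst < 0:
            assert thetas["LOC"] == 0.0

    def test_ordering_matches_fst_ordering(self, study_table):
        res = wc_fstats(study_table)
        thetas = per_locus_theta(res)
        vals = list(thetas.values())
        assert vals == sorted(vals)
        for locus, th in thetas.items():
            assert th == max(res.per_locus[locus].fst, 0.0)


class TestAmova:
    def test_components_match_loop_oracle(self):
        t = make_multipop_table(
            {"A": {"10": 0.8, "11": 0.2}, "B": {"10": 0.3, "11": 0.7}},
            {"A": 15, "B": 12}, seed=13)
        res = amova(t, n_perm=9, seed=1)
        sa, sw = amova_oracle(t, ["LOC"], ["A", "B"])
        assert res.sigma_among == pytest.approx(sa, abs=1e-10)
        assert res.sigma_within == pytest.approx(sw, abs=1e-10)

    def test_percentages_sum_to_100(self, study_table):
        res = amova(study_table, n_perm=19, seed=2)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_phi_tracks_wc_fst(self, study_table):
        res = amova(study_table, n_perm=19, seed=3)
        fst = wc_fstats(study_table).multilocus["FST"]
        assert res.phi_st == pytest.approx(fst, abs=0.02)

    def test_divergent_populations_significant(self, study_table):
        res = amova(study_table, n_perm=199, seed=4)
        assert res.p_perm < 0.05
        assert 5.0 < res.pct_among < 12.0

    def test_single_population_rejected(self, study_table):
        with pytest.raises(ValueError):
            amova(study_table, populations=["wolf"], n_perm=10)


class TestPairwiseFst:
    def test_two_population_consistency(self, study_table):
        m = pairwise_fst(study_table)
        fst = wc_fstats(study_table).multilocus["FST"]
        assert m.loc["wolf", "dog"] == pytest.approx(fst, abs=1e-12)
        assert m.loc["dog", "wolf"] == m.loc["wolf", "dog"]
        assert m.loc["wolf", "wolf"] == 0.0

    def test_four_group_matrix(self):
        cfg = SimConfig(seed=23, n_loci=6, theta_between=0.05, fis=0.0,
                        n_per_population={"a": 30, "b": 30, "c": 30, "d": 30})
        t = simulate_table(cfg)
        m = pairwise_fst(t)
        assert np.allclose(m.values, m.values.T)
        assert (m.values >= -0.05).all()
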