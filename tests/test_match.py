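import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canistr.assignment import build_spectra
from canistr.fstats import per_locus_theta, wc_fstats
from canistr.locus_stats import AlleleFrequencySpectrum
from canistr.match import (cohort_average_match_probability,
                           multilocus_match_probability,
                           single_locus_match_prob)
from canistr.model import AlleleLabel, GenotypeTable, LocusDef, SampleRecord


def spectrum(freq_map, n=100, locus="L"):
    return AlleleFrequencySpectrum(
        locus=locus, population="P", n_typed=n,
        freqs={AlleleLabel(t): f for t, f in freq_map.items()})


def pair(t1, t2):
    return (AlleleLabel(t1), AlleleLabel(t2))


class TestSingleLocus:
    def test_theta_zero_is_product_rule(self):
        spec = spectrum({"10": 0.2, "11": 0.3, "12": 0.5})
        assert single_locus_match_prob(pair("10", "10"), spec, 0.0) == \
            pytest.approx(0.04, abs=1e-15)
        assert single_locus_match_prob(pair("10", "11"), spec, 0.0) == \
            pytest.approx(0.12, abs=1e-15)

    def test_theta_correction_hand_value(self):
        # homozygote p = 0.1, theta = 0.03:
        # (0.06 + 0.097)(0.09 + 0.097) / (1.03 * 1.06)
        spec = spectrum({"10": 0.1, "11": 0.9})
        val = single_locus_match_prob(pair("10", "10"), spec, 0.03)
        assert val == pytest.approx(0.157 * 0.187 / (1.03 * 1.06), abs=1e-12)
        assert val == pytest.approx(0.02689, abs=5e-5)

    def test_fixed_allele_probability_one(self):
        spec = spectrum({"10": 1.0})
        for theta in (0.0, 0.1, 0.5, 0.9):
            assert single_locus_match_prob(pair("10", "10"), spec, theta) == \
                pytest.approx(1.0, abs=1e-12)

    def test_heterozygote_correction_not_always_conservative(self):
        # p = q = 0.5, theta = 0.2 gives 0.4286 < 0.5 = 2pq: the correction
        # can shrink heterozygote probabilities (a known non-property)
        spec = spectrum({"10": 0.5, "11": 0.5})
        val = single_locus_match_prob(pair("10", "11"), spec, 0.2)
        assert val == pytest.approx(2 * 0.36 / (1.2 * 1.4), abs=1e-12)
        assert val < 2 * 0.5 * 0.5

    def test_invalid_theta_rejected(self):
        spec = spectrum({"10": 1.0})
        for theta in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                single_locus_match_prob(pair("10", "10"), spec, theta)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.998))
    def test_theta_zero_reduction_random(self, p, q_frac):
        q = (1.0 - p) * q_frac
        spec = AlleleFrequencySpectrum(
            locus="L", population="P", n_typed=1000,
            freqs={AlleleLabel("10"): p, AlleleLabel("11"): q,
                   AlleleLabel("12"): 1.0 - p - q})
        hom = single_locus_match_prob(pair("10", "10"), spec, 0.0)
        het = single_locus_match_prob(pair("10", "11"), spec, 0.0)
        assert hom == pytest.approx(p * p, abs=1e-15)
        assert het == pytest.approx(2 * p * q, abs=1e-15)

    def test_homozygote_correction_conservative_on_grid(self):
        """theta-corrected homozygote probability >= p^2 over a dense grid."""
        ps = np.linspace(0.01, 1.0, 100)
        thetas = np.linspace(0.0, 0.99, 100)
        for p in ps:
            spec = spectrum({"10": float(p), "11": 1.0 - float(p)} if p < 1
                            else {"10": 1.0})
            for th in thetas:
                val = single_locus_match_prob(pair("10", "10"), spec, float(th))
                assert val >= p * p - 1e-12


class TestMultilocus:
    def _table_and_refs(self):
        a, b = AlleleLabel("10"), AlleleLabel("11")
        s = SampleRecord("x", "P", {"L1": (a, a), "L2": (a, b)})
        spectra = {"L1": spectrum({"10": 0.2, "11": 0.8}, locus="L1"),
                   "L2": spectrum({"10": 0.5, "11": 0.5}, locus="L2")}
        return s, spectra

    def test_cumulative_is_running_product(self):
        s, spectra = self._table_and_refs()
        rep = multilocus_match_probability(s, spectra, {"L1": 0.0, "L2": 0.0})
        # per-locus 0.04 and 0.5 -> cumulative [0.04, 0.02]
        assert rep.cumulative_no_theta == pytest.approx([0.04, 0.02])

    def test_locus_order_ascending_theta(self):
        s, spectra = self._table_and_refs()
        rep = multilocus_match_probability(s, spectra, {"L1": 0.1, "L2": 0.02})
        assert rep.locus_order == ["L2", "L1"]

    def test_cumulative_matches_bruteforce_product(self, study_table):
        spectra = build_spectra(study_table)
        thetas = per_locus_theta(wc_fstats(study_table))
        for s in study_table.samples[:10]:
            rep = multilocus_match_probability(s, spectra, thetas)
            brute0 = brute1 = 1.0
            for locus in rep.locus_order:
                brute0 *= rep.per_locus[locus]["p_no_theta"]
                brute1 *= rep.per_locus[locus]["p_with_theta"]
            assert rep.final_no_theta == pytest.approx(brute0, rel=1e-12)
            assert rep.final_with_theta == pytest.approx(brute1, rel=1e-12)
            assert np.all(np.diff(rep.cumulative_no_theta) <= 0)
            assert np.all(np.diff(rep.cumulative_with_theta) <= 0)

    def test_untyped_sample_returns_none(self):
        s = SampleRecord("x", "P", {"L1": None})
        assert multilocus_match_probability(
            s, {"L1": spectrum({"10": 1.0})}, {"L1": 0.0}) is None


class TestCohortAverage:
    def _identical_cohort(self):
        a = AlleleLabel("10")
        samples = [SampleRecord(f"s{i}", "P",
                                {"L1": (a, AlleleLabel("11"))})
                   for i in range(5)]
        t = GenotypeTable(panel=[LocusDef("L1")], samples=samples)
        spectra = {"L1": spectrum({"10": 0.3, "11": 0.7}, locus="L1")}
        return t, spectra

    def test_identical_samples_both_modes(self):
        t, spectra = self._identical_cohort()
        for mode in ("geometric", "arithmetic"):
            avg = cohort_average_match_probability(t, spectra, {"L1": 0.05},
                                                   mode=mode)
            one = multilocus_match_probability(t.samples[0], spectra,
                                               {"L1": 0.05})
            assert avg.mean_freq_no_theta == pytest.approx(one.final_no_theta)
            assert avg.mean_freq_with_theta == pytest.approx(one.final_with_theta)

    def test_geometric_mean_is_log_midpoint(self):
        # two frequencies 1e-10 and 1e-14 -> geometric mean 1e-12
        vals = [1e-10, 1e-14]
        mid = 10 ** (np.mean([math.log10(v) for v in vals]))
        assert mid == pytest.approx(1e-12, rel=1e-9)

    def test_theta_average_exceeds_product_rule_average(self, study_table):
        spectra = build_spectra(study_table)
        thetas = per_locus_theta(wc_fstats(study_table))
        avg = cohort_average_match_probability(study_table, spectra, thetas)
        # the subdivision correction is conservative by an order of magnitude
        # or more on a theta ~= 0.08 panel
        assert avg.mean_freq_with_theta >= 10 * avg.mean_freq_no_theta

    def test_unknown_mode_rejected(self, study_table):
        spectra = build_spectra(study_table)
        with pytest.raises(ValueError):
            cohort_average_match_probability(study_table, spectra,
                                             {"L01": 0.0}, mode="median")
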