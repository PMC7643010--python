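import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmsflow.errors import ValidationError
from apmsflow.phospho import (
    DEPTH_WEIGHTS,
    FragmentSpectrum,
    PHOSPHO_DELTA,
    SiteEvidence,
    UNAMBIGUOUS_SENTINEL,
    aggregate_sites,
    ascore,
    binomial_tail,
    confidence_from_ascore,
    merge_site_evidence,
    peptide_score,
    read_mgf,
    reduce_to_depth,
    theoretical_ions,
    write_mgf,
)


def spectrum_from(peaks, spectrum_id="s1", precursor=500.0, charge=2):
    return FragmentSpectrum(spectrum_id, precursor, charge, np.array(peaks, dtype=float))


class TestTheoreticalIons:
    def test_gg_dipeptide_oracle(self):
        # independent recomputation: b1 = 57.02146 + 1.00728, y1 = 57.02146 + 18.01056 + 1.00728
        iso = theoretical_ions("GG")
        ions = {(series, index): mz for series, index, mz in iso.theoretical_ions}
        assert ions[("b", 1)] == pytest.approx(58.0287, abs=1e-3)
        assert ions[("y", 1)] == pytest.approx(76.0393, abs=1e-3)

    def test_phospho_shifts_covering_ions_only(self):
        plain = {(s, i): mz for s, i, mz in theoretical_ions("GSGK").theoretical_ions}
        shifted = {(s, i): mz for s, i, mz in theoretical_ions("GSGK", {2}).theoretical_ions}
        # b1 excludes residue 2, b2/b3 include it; y3 includes it, y1/y2 do not
        assert shifted[("b", 1)] == pytest.approx(plain[("b", 1)])
        for key in (("b", 2), ("b", 3), ("y", 3)):
            assert shifted[key] == pytest.approx(plain[key] + PHOSPHO_DELTA)
        for key in (("y", 1), ("y", 2)):
            assert shifted[key] == pytest.approx(plain[key])

    @pytest.mark.parametrize("peptide", ["GG", "ACDEK", "STYSTYK"])
    def test_ion_count(self, peptide):
        iso = theoretical_ions(peptide)
        assert len(iso.theoretical_ions) == 2 * (len(peptide) - 1)

    def test_non_sty_position_rejected(self):
        with pytest.raises(ValidationError):
            theoretical_ions("GAGK", {2})


class TestReduceToDepth:
    def test_keeps_most_intense(self):
        peaks = [(10 + i, 100 + i) for i in range(5)]
        reduced = reduce_to_depth(np.array(peaks), 2)
        assert set(reduced[:, 1]) == {103, 104}

    def test_depth_ten_identity(self):
        peaks = np.array([(10.0 + i, 50.0 + i) for i in range(8)])
        np.testing.assert_array_equal(reduce_to_depth(peaks, 10), peaks)

    def test_window_boundary(self):
        peaks = np.array([(99.9, 10.0), (100.1, 5.0)])
        reduced = reduce_to_depth(peaks, 1)
        assert len(reduced) == 2  # different windows, both survive depth 1

    def test_tie_breaks_to_lower_mz(self):
        peaks = np.array([(50.0, 10.0), (40.0, 10.0), (60.0, 10.0)])
        reduced = reduce_to_depth(peaks, 1)
        assert reduced[0, 0] == 40.0

    def test_depth_bounds(self):
        with pytest.raises(ValidationError):
            reduce_to_depth(np.zeros((0, 2)), 11)


class TestBinomialTail:
    def test_half_enumeration(self):
        assert binomial_tail(2, 1, 0.5) == pytest.approx(0.75)

    def test_all_successes(self):
        assert binomial_tail(5, 5, 0.1) == pytest.approx(1e-5, rel=1e-9)

    def test_k_zero_is_one(self):
        assert binomial_tail(7, 0, 0.3) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            binomial_tail(3, 4, 0.5)
        with pytest.raises(ValidationError):
            binomial_tail(3, 1, 0.0)

    @settings(max_examples=150, deadline=None)
    @given(
        st.integers(1, 25),
        st.integers(0, 25),
        st.floats(0.01, 0.99),
    )
    def test_brute_force_parity(self, n, k, pi):
        """Exact enumeration oracle of the mass function, all n <= 25."""
        if k > n:
            k = n
        expected = float(
            sum(
                Fraction(comb(n, j)) * Fraction(pi) ** j * (1 - Fraction(pi)) ** (n - j)
                for j in range(k, n + 1)
            )
        )
        assert binomial_tail(n, k, pi) == pytest.approx(expected, abs=1e-12)


class TestPeptideScore:
    def test_no_matching_ion_scores_zero(self):
        iso = theoretical_ions("GSGK", {2})
        spectrum = spectrum_from([(5000.0, 100.0)])
        scores, weighted = peptide_score(spectrum, iso)
        np.testing.assert_array_equal(scores, np.zeros(10))
        assert weighted == 0.0

    def test_empty_spectrum_scores_zero(self):
        iso = theoretical_ions("GSGK", {2})
        scores, weighted = peptide_score(spectrum_from(np.empty((0, 2))), iso)
        np.testing.assert_array_equal(scores, np.zeros(10))
        assert weighted == 0.0

    def test_all_eight_ions_at_depth_five(self):
        # derived: tail(8, 8, 0.05) = 0.05^8 => score_5 = -10*log10(0.05^8) ~ 104.1
        peptide = "GSGKA"
        iso = theoretical_ions(peptide, {2})
        peaks = [(mz, 100.0) for _, _, mz in iso.theoretical_ions]
        scores, _ = peptide_score(spectrum_from(peaks), iso)
        assert scores[4] == pytest.approx(-10 * math.log10(0.05**8), abs=1e-6)
        assert scores[4] == pytest.approx(104.08, abs=0.01)

    def test_deleting_peaks_never_increases_score(self):
        iso = theoretical_ions("GSGKA", {2})
        peaks = [(mz, 100.0) for _, _, mz in iso.theoretical_ions]
        full, _ = peptide_score(spectrum_from(peaks), iso)
        fewer, _ = peptide_score(spectrum_from(peaks[:-3]), iso)
        assert (fewer <= full + 1e-12).all()

    def test_tighter_tolerance_never_matches_more(self):
        iso = theoretical_ions("GSGKA", {2})
        peaks = [(mz + 0.03, 100.0) for _, _, mz in iso.theoretical_ions]
        wide, _ = peptide_score(spectrum_from(peaks), iso, tolerance=0.05)
        narrow, _ = peptide_score(spectrum_from(peaks), iso, tolerance=0.01)
        assert (narrow <= wide + 1e-12).all()


def build_depth5_fixture():
    """Spectrum for SASAAK with phospho truly on S1: all 4 site-determining
    ions of isoform {1} present at modest intensity, plus 4 intense decoys
    per SD-ion window so the SD ions only surface at depth 5."""
    peptide = "SASAAK"
    true_iso = theoretical_ions(peptide, {1})
    alt_iso = theoretical_ions(peptide, {3})
    alt_mz = {round(mz, 4) for _, _, mz in alt_iso.theoretical_ions}
    sd_true = [mz for _, _, mz in true_iso.theoretical_ions if round(mz, 4) not in
               {round(m, 4) for _, _, m in alt_iso.theoretical_ions}]
    assert len(sd_true) == 4
    windows = {math.floor(mz / 100.0) for mz in sd_true}
    assert len(windows) == 4  # each SD ion in its own 100 m/z window
    peaks = [(mz, 100.0) for mz in sd_true]
    for w in windows:
        for offset in (11.0, 22.0, 33.0, 44.0):
            decoy = w * 100.0 + offset
            assert all(abs(decoy - mz) > 0.5 for mz in sd_true)
            assert all(abs(decoy - mz) > 0.5 for mz in alt_mz)
            peaks.append((decoy, 10_000.0))
    return peptide, spectrum_from(peaks)


class TestAscore:
    def test_constructed_depth5_fixture(self):
        """Derived oracle: 4/4 SD ions at depth 5 and 0 for the competitor
        gives A = -10*log10(0.05^4) ~ 52.0 at optimal depth 5."""
        peptide, spectrum = build_depth5_fixture()
        outcome = ascore(spectrum, peptide, n_phospho=1)
        assert outcome.best_isoform.phospho_positions == frozenset({1})
        assert outcome.optimal_depth == 5
        expected = -10 * math.log10(0.05**4)
        assert outcome.ascore_per_site[1] == pytest.approx(expected, abs=1e-6)
        assert outcome.ascore_per_site[1] == pytest.approx(52.04, abs=0.01)

    def test_shared_ions_only_ambiguous(self):
        peptide = "SASAAK"
        true_iso = theoretical_ions(peptide, {1})
        alt_iso = theoretical_ions(peptide, {3})
        shared = [
            mz
            for _, _, mz in true_iso.theoretical_ions
            if round(mz, 4) in {round(m, 4) for _, _, m in alt_iso.theoretical_ions}
        ]
        outcome = ascore(spectrum_from([(mz, 50.0) for mz in shared]), peptide, 1)
        assert set(outcome.ascore_per_site.values()) == {0.0}

    def test_single_candidate_site_sentinel(self):
        outcome = ascore(spectrum_from([(100.0, 5.0)]), "GSGAK", 1)
        assert outcome.second_isoform is None
        assert outcome.ascore_per_site == {2: UNAMBIGUOUS_SENTINEL}

    def test_too_many_phospho_rejected(self):
        with pytest.raises(ValidationError):
            ascore(spectrum_from([(100.0, 5.0)]), "GSGAK", 2)

    def test_invariant_to_peak_order_and_intensity_scale(self):
        peptide, spectrum = build_depth5_fixture()
        base = ascore(spectrum, peptide, 1)
        reversed_peaks = spectrum.peaks[::-1].copy()
        shuffled = ascore(spectrum_from(reversed_peaks), peptide, 1)
        scaled = ascore(
            spectrum_from(np.column_stack([spectrum.peaks[:, 0], spectrum.peaks[:, 1] * 7.3])),
            peptide,
            1,
        )
        for other in (shuffled, scaled):
            assert other.best_isoform.phospho_positions == base.best_isoform.phospho_positions
            assert other.ascore_per_site == pytest.approx(base.ascore_per_site)


class TestConfidence:
    def test_a20_maps_to_99(self):
        assert confidence_from_ascore(20.0) == pytest.approx(99.0)

    def test_a15_in_over_90_band(self):
        value = confidence_from_ascore(15.0)
        assert value == pytest.approx(100 * (1 - 10 ** (-1.5)))
        assert value == pytest.approx(96.84, abs=0.01)
        assert value > 90.0

    def test_a0_zero(self):
        assert confidence_from_ascore(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            confidence_from_ascore(-1.0)


class TestAggregation:
    def test_high_band_counting(self):
        evidence = [
            SiteEvidence("BAIT", (940,), ("S",), 25.0, rep) for rep in (1, 2, 3, 4)
        ]
        (call,) = merge_site_evidence(evidence)
        assert call.site_label == "S940"
        assert call.n_detect_high == 4
        assert call.n_detect_mid == 0
        assert call.max_ascore == 25.0

    def test_mid_band_counting(self):
        evidence = [SiteEvidence("BAIT", (902,), ("T",), 17.0, 1)]
        (call,) = merge_site_evidence(evidence)
        assert call.n_detect_mid == 1
        assert call.n_detect_high == 0

    def test_adjacent_ambiguous_sites_merge_composite(self):
        evidence = [
            SiteEvidence("BAIT", (25, 26), ("S", "S"), 0.0, 1),
            SiteEvidence("BAIT", (25,), ("S",), 22.0, 2),
        ]
        (call,) = merge_site_evidence(evidence)
        assert call.site_label == "S25/26"
        assert call.coords == (25, 26)
        assert call.n_detect_high == 1

    def test_aggregate_sites_end_to_end(self):
        peptide, spectrum = build_depth5_fixture()
        outcomes = [(ascore(spectrum, peptide, 1), rep) for rep in (1, 2, 3, 4)]
        calls = aggregate_sites(outcomes, {peptide: ("BAIT", 100)})
        (call,) = calls
        assert call.accession == "BAIT"
        assert call.site_label == "S100"  # peptide position 1 at protein start 100
        assert call.n_detect_high == 4

    def test_mature_offset_shifts_coordinates(self):
        peptide, spectrum = build_depth5_fixture()
        outcomes = [(ascore(spectrum, peptide, 1), 1)]
        (call,) = aggregate_sites(outcomes, {peptide: ("BAIT", 100)}, mature_offset=18)
        assert call.coords == (82,)

    def test_unmapped_peptide_rejected(self):
        peptide, spectrum = build_depth5_fixture()
        outcomes = [(ascore(spectrum, peptide, 1), 1)]
        with pytest.raises(ValidationError, match="placement"):
            aggregate_sites(outcomes, {})


class TestMgfRoundTrip:
    def test_round_trip(self, tmp_path):
        spectra = [
            spectrum_from([(100.12345, 55.0), (250.5, 10.0)], spectrum_id="a", precursor=432.1),
            spectrum_from([(90.0, 1.0)], spectrum_id="b", precursor=300.0, charge=3),
        ]
        path = tmp_path / "test.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.spectrum_id for s in back] == ["a", "b"]
        assert back[1].charge == 3
        np.testing.assert_allclose(back[0].peaks[:, 0], [100.12345, 250.5], atol=1e-5)
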