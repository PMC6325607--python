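"""Fragment ladders, CoA diagnostic scanning, annotation and localization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coalscan.chem import PROTON_MASS, mz
from coalscan.fragments import (
    DEFAULT_RULES,
    CoAFragRules,
    MS2Spectrum,
    annotate_spectrum,
    diagnostic_scan,
    fragment_ladder,
    localize_site,
    read_mgf,
    write_mgf,
)
from coalscan.modifications import CAM, COALATION, make_form
from coalscan.proteins import PeptideSpan
from coalscan.simulate import SpectrumSynthConfig, gen_ms2


def _span(seq, start=1):
    return PeptideSpan("p", start, start + len(seq) - 1, seq, seq[:-1].count("K"))


def _clean_spectrum(form, charge=2):
    return gen_ms2(
        SpectrumSynthConfig(
            form=form, precursor_charge=charge, jitter_sd=0.0, n_noise_peaks=0
        )
    )


random_cys_seq = st.text(
    alphabet="ACDEFGHILMNPQRSTVWY", min_size=5, max_size=25
).filter(lambda s: "C" in s)


class TestCoAFragRules:
    def test_every_loss_remnant_pair_reconstructs_coalation_delta(self):
        for loss, rem in zip(DEFAULT_RULES.losses, DEFAULT_RULES.remnants):
            assert 764.0 <= loss + rem <= 766.0

    def test_inconsistent_pairing_rejected(self):
        with pytest.raises(ValueError, match="reconstruct"):
            CoAFragRules(losses=(410.0,), loss_variants=(409.0,), remnants=(100.0,))


class TestFragmentLadder:
    def test_gk_closed_form_b1_y1(self):
        ions = {i.label: i.mz for i in fragment_ladder(make_form(_span("GK")))}
        assert ions["b1+"] == pytest.approx(58.0287, abs=1e-3)
        assert ions["y1+"] == pytest.approx(147.1128, abs=1e-3)

    @given(random_cys_seq)
    def test_by_complementarity_identity(self, seq):
        form = make_form(_span(seq), {seq.index("C") + 1: CAM})
        ions = fragment_ladder(form)
        n = len(seq)
        b = {i.ordinal: i.mz for i in ions if i.series == "b" and i.remnant_state in ("none", "fullCoA")}
        y = {i.ordinal: i.mz for i in ions if i.series == "y" and i.remnant_state in ("none", "fullCoA")}
        for i in range(1, n):
            assert b[i] + y[n - i] == pytest.approx(
                form.neutral_mass + 2 * PROTON_MASS, rel=1e-12
            )

    def test_coalated_ion_variants_sit_at_remnant_offsets(self, cys_peptide):
        coalated = make_form(cys_peptide, {149: COALATION, 153: CAM})
        bare = make_form(cys_peptide, {153: CAM})
        coal_ions = {
            (i.series, i.ordinal, i.remnant_state): i.mz
            for i in fragment_ladder(coalated)
        }
        bare_ions = {
            (i.series, i.ordinal): i.mz
            for i in fragment_ladder(bare)
            if i.remnant_state == "none"
        }
        # y11 contains Cys149 (position 12 of 22) on the C-terminal side
        key = ("y", 11)
        unmod = bare_ions[key]
        assert coal_ions[key + ("fullCoA",)] - unmod == pytest.approx(765.10, abs=1.0)
        assert coal_ions[key + ("remnant356",)] - unmod == pytest.approx(356, abs=1.0)
        assert coal_ions[key + ("remnant338",)] - unmod == pytest.approx(338, abs=1.0)
        assert coal_ions[key + ("remnant258",)] - unmod == pytest.approx(258, abs=1.0)

    def test_disulfide_ring_suppresses_internal_cleavages(self, cys_peptide):
        form = make_form(cys_peptide, {}, [(149, 153)])
        ions = fragment_ladder(form)
        b_ordinals = {i.ordinal for i in ions if i.series == "b"}
        # cys at peptide indices 12 and 16: cleavages 12..15 sit inside the ring
        assert b_ordinals.isdisjoint(range(12, 16))
        ring_open = fragment_ladder(form, emit_ring_ions=True)
        assert {i.ordinal for i in ring_open if i.series == "b"} >= set(range(12, 16))

    def test_single_residue_peptide_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fragment_ladder(make_form(_span("K")))


class TestDiagnosticScan:
    def test_three_same_charge_loss_peaks_flag_coalation(self):
        z, prec = 3, 1040.765
        m_prec = prec * z - z * PROTON_MASS
        peaks = [(m_prec - loss + z * PROTON_MASS) / z for loss in (410, 428, 508)]
        spec = MS2Spectrum(prec, z, np.array(peaks), np.array([100.0] * 3))
        result = diagnostic_scan(spec, min_losses=3)
        assert result.is_coalated_candidate
        assert result.n_losses_matched == 3
        matched = sorted({h.matched_mz for h in result.hits})
        assert matched == pytest.approx(sorted(peaks), abs=1e-6)

    def test_spectrum_without_loss_peaks_not_flagged(self):
        spec = MS2Spectrum(1040.765, 3, np.array([300.0, 500.0]), np.array([10.0, 100.0]))
        result = diagnostic_scan(spec)
        assert not result.is_coalated_candidate
        assert result.n_losses_matched == 0

    def test_hydrogen_shift_variant_accepted(self):
        z, prec = 3, 1040.765
        m_prec = prec * z - z * PROTON_MASS
        peak = (m_prec - 409.0 + z * PROTON_MASS) / z
        spec = MS2Spectrum(prec, z, np.array([peak]), np.array([100.0]))
        result = diagnostic_scan(spec, min_losses=1, tolerance=0.3)
        assert result.is_coalated_candidate
        assert result.hits[0].variant_used == 409.0
        assert result.hits[0].loss == 410.0

    def test_charge_reduced_product_ions_found(self):
        z, prec = 3, 1040.765
        m_prec = prec * z - z * PROTON_MASS
        peaks = [(m_prec - loss + 1 * PROTON_MASS) / 1 for loss in (410, 428)]
        spec = MS2Spectrum(prec, z, np.array(peaks), np.array([100.0, 100.0]))
        result = diagnostic_scan(spec, min_losses=2)
        assert result.is_coalated_candidate
        assert {h.product_charge for h in result.hits} == {1}

    def test_low_intensity_peaks_do_not_count(self):
        z, prec = 3, 1040.765
        m_prec = prec * z - z * PROTON_MASS
        loss_peak = (m_prec - 410 + z * PROTON_MASS) / z
        spec = MS2Spectrum(prec, z, np.array([500.0, loss_peak]), np.array([100.0, 1.0]))
        assert not diagnostic_scan(spec, min_losses=1, min_rel_intensity=0.05).is_coalated_candidate
        assert diagnostic_scan(spec, min_losses=1, min_rel_intensity=0.001).is_coalated_candidate

    @given(st.floats(min_value=0.1, max_value=1.5), st.floats(min_value=0.1, max_value=1.5))
    def test_monotone_in_tolerance(self, tol_a, tol_b, ):
        z, prec = 3, 1040.765
        m_prec = prec * z - z * PROTON_MASS
        rng = np.random.default_rng(7)
        peaks = np.array(
            [(m_prec - loss + z * PROTON_MASS) / z + rng.normal(0, 0.4)
             for loss in (410, 428, 508)]
        )
        spec = MS2Spectrum(prec, z, peaks, np.full(3, 100.0))
        lo, hi = sorted((tol_a, tol_b))
        assert (
            diagnostic_scan(spec, tolerance=lo, min_losses=1).n_losses_matched
            <= diagnostic_scan(spec, tolerance=hi, min_losses=1).n_losses_matched
        )

    def test_missing_precursor_charge_rejected(self):
        spec = MS2Spectrum(1040.765, None, np.array([500.0]), np.array([100.0]))
        with pytest.raises(ValueError, match="charge"):
            diagnostic_scan(spec)


class TestAnnotateSpectrum:
    @given(random_cys_seq)
    def test_noiseless_self_annotation_has_full_coverage(self, seq):
        form = make_form(_span(seq), {seq.index("C") + 1: CAM})
        ann = annotate_spectrum(_clean_spectrum(form), form)
        assert ann.coverage == 1.0

    def test_wrong_mass_form_covers_strictly_less(self, cys_peptide):
        truth = make_form(cys_peptide, {149: COALATION, 153: CAM})
        wrong = make_form(cys_peptide, {149: CAM, 153: CAM})
        spec = _clean_spectrum(truth, charge=3)
        assert annotate_spectrum(spec, wrong).coverage < annotate_spectrum(spec, truth).coverage

    def test_zero_tolerance_on_jittered_peaks_matches_nothing(self, cys_peptide):
        form = make_form(cys_peptide, {149: CAM, 153: CAM})
        spec = gen_ms2(
            SpectrumSynthConfig(form=form, jitter_sd=0.2, n_noise_peaks=0, seed=3)
        )
        assert annotate_spectrum(spec, form, fragment_tolerance=0.0).coverage == 0.0

    def test_empty_spectrum_gives_zero_coverage_without_error(self, cys_peptide):
        form = make_form(cys_peptide, {149: CAM, 153: CAM})
        spec = MS2Spectrum(mz(form.neutral_mass, 2), 2, np.array([]), np.array([]))
        ann = annotate_spectrum(spec, form)
        assert ann.coverage == 0.0 and ann.matched == ()

    def test_inconsistent_precursor_flagged(self, cys_peptide):
        form = make_form(cys_peptide, {149: CAM, 153: CAM})
        spec = MS2Spectrum(999.0, 2, np.array([500.0]), np.array([100.0]))
        assert not annotate_spectrum(spec, form).precursor_consistent


class TestLocalizeSite:
    def _candidates(self, cys_peptide):
        return [
            make_form(cys_peptide, {149: COALATION, 153: CAM}),
            make_form(cys_peptide, {149: CAM, 153: COALATION}),
        ]

    @pytest.mark.parametrize("truth_idx", [0, 1])
    def test_generating_site_recovered_and_swaps_with_generator(
        self, cys_peptide, truth_idx
    ):
        candidates = self._candidates(cys_peptide)
        spec = _clean_spectrum(candidates[truth_idx], charge=3)
        result = localize_site(spec, candidates)
        assert result.best is candidates[truth_idx]
        assert not result.tie

    def test_no_site_determining_ions_sets_tie_flag(self, cys_peptide):
        candidates = self._candidates(cys_peptide)
        spec = MS2Spectrum(
            mz(candidates[0].neutral_mass, 3), 3, np.array([55.5]), np.array([100.0])
        )
        assert localize_site(spec, candidates).tie

    def test_fewer_than_two_candidates_rejected(self, cys_peptide):
        form = make_form(cys_peptide, {149: CAM, 153: CAM})
        with pytest.raises(ValueError, match="nothing to localize"):
            localize_site(_clean_spectrum(form), [form])

    def test_non_isobaric_candidates_rejected(self, cys_peptide):
        a = make_form(cys_peptide, {149: CAM, 153: CAM})
        b = make_form(cys_peptide, {149: COALATION, 153: CAM})
        with pytest.raises(ValueError, match="isobaric"):
            localize_site(_clean_spectrum(a), [a, b])


class TestMgfIO:
    def test_spectra_round_trip_through_mgf(self, tmp_path, cys_peptide):
        form = make_form(cys_peptide, {149: COALATION, 153: CAM})
        original = gen_ms2(
            SpectrumSynthConfig(form=form, precursor_charge=3, seed=11)
        )
        path = tmp_path / "spec.mgf"
        write_mgf([original], path)
        (loaded,) = read_mgf(path)
        assert loaded.precursor_charge == 3
        assert loaded.precursor_mz == pytest.approx(original.precursor_mz, abs=1e-6)
        np.testing.assert_allclose(loaded.mz, original.mz, atol=1e-6)
        np.testing.assert_allclose(loaded.intensity, original.intensity, atol=1e-6)
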