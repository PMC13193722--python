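"""Spectrum matching, site localization, neutral-loss diagnostics, pairing."""

import math

import numpy as np
import pytest

from hgmod.chem import MOD_2HG, PROTON_MASS, mz, peptide_neutral_mass
from hgmod.digest import Peptide
from hgmod.fragments import theoretical_fragments
from hgmod.spectra import (
    PSM,
    Spectrum,
    detect_neutral_loss,
    find_isotope_pairs,
    localize_site,
    match_spectrum,
    nl_frequency_summary,
)

from conftest import noiseless_spectrum


def psm_from(peptide, spectrum=None, heavy=False, **kw):
    spectrum = spectrum or noiseless_spectrum(peptide, heavy=heavy)
    best, _ = match_spectrum(spectrum, [peptide], heavy=heavy, **kw)
    assert best is not None
    return best


class TestSpectrum:
    def test_peaks_sorted_on_construction(self):
        s = Spectrum.from_peaks("s", 500.0, 1, 1.0, [(300.0, 1.0), (200.0, 2.0)])
        assert list(s.mz) == [200.0, 300.0]
        assert list(s.intensity) == [2.0, 1.0]

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Spectrum.from_peaks("s", 500.0, 1, 1.0, [(300.0, -1.0)])


class TestMatchSpectrum:
    def test_planted_peptide_beats_decoy(self, gsk_modified):
        spectrum = noiseless_spectrum(gsk_modified)
        # decoy: same composition rearranged so the precursor matches
        decoy = Peptide("SGK", mods=((0, MOD_2HG),))
        best, ranked = match_spectrum(spectrum, [decoy, gsk_modified])
        assert best.peptide == gsk_modified
        assert len(ranked) == 2
        assert ranked[0].match_score > ranked[1].match_score

    def test_zero_peak_spectrum_scores_zero(self, gsk_modified):
        empty = Spectrum.from_peaks(
            "e", noiseless_spectrum(gsk_modified).precursor_mz, 2, 1.0, []
        )
        best, ranked = match_spectrum(empty, [gsk_modified])
        assert best.match_score == 0.0
        assert best.matched_ion_count == 0

    def test_no_candidate_in_precursor_window_flags_empty(self, gsk_modified):
        spectrum = noiseless_spectrum(gsk_modified)
        far = Peptide("WWWWWWK")
        best, ranked = match_spectrum(spectrum, [far])
        assert best is None and ranked == []

    def test_planted_peptide_survives_spurious_peaks(self):
        rng = np.random.default_rng(11)
        pep = Peptide("TGGAEGTGDAVLGEK", mods=((6, MOD_2HG),))
        clean = noiseless_spectrum(pep)
        decoy = Peptide("TGGAEGTGDAVLGEK", mods=((0, MOD_2HG),))
        n_noise = int(0.2 * clean.n_peaks)
        noise_mz = rng.uniform(150.0, 1500.0, n_noise)
        noise_int = rng.uniform(10.0, 80.0, n_noise)
        noisy = Spectrum(
            id="noisy",
            precursor_mz=clean.precursor_mz,
            precursor_charge=clean.precursor_charge,
            rt=clean.rt,
            mz=np.concatenate([clean.mz, noise_mz]),
            intensity=np.concatenate([clean.intensity, noise_int]),
        )
        best, _ = match_spectrum(noisy, [decoy, pep])
        assert best.peptide == pep

    def test_tie_breaks_deterministically(self):
        # zero peaks -> equal (zero) scores for isobaric candidates; the
        # lexicographically smaller sequence must win regardless of order
        spectrum = Spectrum.from_peaks(
            "t", mz(peptide_neutral_mass("GAK"), 2), 2, 1.0, []
        )
        a, b = Peptide("GAK"), Peptide("AGK")
        best1, _ = match_spectrum(spectrum, [a, b])
        best2, _ = match_spectrum(spectrum, [b, a])
        assert best1.peptide.sequence == best2.peptide.sequence == "AGK"


class TestLocalization:
    def test_single_candidate_site_gets_sentinel_delta(self):
        pep = Peptide("GASK", mods=((2, MOD_2HG),))
        psm = psm_from(pep)
        best, runner, delta = localize_site(psm)
        assert best == 2 and runner is None and math.isinf(delta)

    def test_planted_site_wins_on_noiseless_spectrum(self):
        # two serines: site-determining ions separate the hypotheses
        pep = Peptide("TSAGSK", mods=((4, MOD_2HG),))
        psm = psm_from(pep)
        best, runner, delta = localize_site(psm)
        assert best == 4
        assert delta >= 1

    def test_no_site_determining_evidence_is_ambiguous(self):
        pep = Peptide("TSAGSK", mods=((4, MOD_2HG),))
        spectrum = noiseless_spectrum(pep)
        # strip every peak, leaving nothing to discriminate the sites
        empty = Spectrum.from_peaks(
            "e", spectrum.precursor_mz, spectrum.precursor_charge, 1.0, []
        )
        best_psm, _ = match_spectrum(empty, [pep])
        _, _, delta = localize_site(best_psm)
        assert delta == 0


class TestNeutralLossDetection:
    def test_noiseless_spectrum_flags_both_channels(self, gsk_modified):
        psm = psm_from(gsk_modified)
        flags = detect_neutral_loss(psm)
        assert flags["A"].fragment_observed and flags["B"].fragment_observed

    def test_planted_precursor_loss_peak_detected(self, gsk_modified):
        neutral = peptide_neutral_mass("GSK", [(1, MOD_2HG)])
        peak = mz(neutral - 130.0266, 1)  # z=1 charge-reduced loss position
        spectrum = Spectrum.from_peaks(
            "p", mz(neutral, 1), 1, 1.0, [(peak, 50.0), (400.0, 100.0)]
        )
        best, _ = match_spectrum(spectrum, [gsk_modified])
        flags = detect_neutral_loss(best)
        assert flags["A"].precursor_observed
        assert not flags["B"].precursor_observed

    def test_no_loss_peaks_gives_both_false(self, gsk_modified):
        spectrum = noiseless_spectrum(gsk_modified, include_losses=False)
        psm = psm_from(gsk_modified, spectrum)
        flags = detect_neutral_loss(psm)
        assert not flags["A"].observed and not flags["B"].observed

    def test_relative_abundance_is_fraction_of_base_peak(self, gsk_modified):
        neutral = peptide_neutral_mass("GSK", [(1, MOD_2HG)])
        loss_peak = mz(neutral - 130.0266, 1)
        spectrum = Spectrum.from_peaks(
            "p", mz(neutral, 1), 1, 1.0, [(loss_peak, 4.0), (400.0, 100.0)]
        )
        best, _ = match_spectrum(spectrum, [gsk_modified])
        flags = detect_neutral_loss(best)
        assert math.isclose(flags["A"].relative_abundance, 0.04, abs_tol=1e-9)

    def test_unmodified_peptide_rejected(self):
        pep = Peptide("GAK")
        psm = psm_from(pep)
        with pytest.raises(ValueError, match="unmodified"):
            detect_neutral_loss(psm)


class TestNLFrequencySummary:
    def _psm_with_abundance(self, rel, observed=True):
        from hgmod.spectra import NeutralLossFlags

        psm = PSM("s", Peptide("GSK", mods=((1, MOD_2HG),)), 0.0, 0)
        psm.nl_flags = {
            "A": NeutralLossFlags(observed, False, rel if observed else 0.0)
        }
        return psm

    def test_binning_boundaries(self):
        """0.06 -> high, 0.05 and 0.03 -> mid, 0.005 -> low, absent counted."""
        psms = [
            self._psm_with_abundance(0.06),
            self._psm_with_abundance(0.05),
            self._psm_with_abundance(0.03),
            self._psm_with_abundance(0.005),
            self._psm_with_abundance(0.0, observed=False),
        ]
        counts = nl_frequency_summary(psms)["A"]
        assert counts == {"high": 1, "mid": 2, "low": 1, "absent": 1}
        assert sum(counts.values()) == len(psms)

    def test_invariant_under_reordering(self):
        psms = [self._psm_with_abundance(r) for r in (0.2, 0.04, 0.001)]
        assert nl_frequency_summary(psms) == nl_frequency_summary(psms[::-1])

    def test_all_absent(self):
        psms = [self._psm_with_abundance(0.0, observed=False) for _ in range(4)]
        assert nl_frequency_summary(psms)["A"] == {
            "high": 0, "mid": 0, "low": 0, "absent": 4
        }


class TestIsotopePairs:
    def _duo(self, seq="TGGAESTGDK", site=5):
        pep = Peptide(seq, mods=((site, MOD_2HG),))
        light = psm_from(pep, noiseless_spectrum(pep, rt=20.0))
        heavy = psm_from(
            pep, noiseless_spectrum(pep, heavy=True, rt=20.1), heavy=True
        )
        return light, heavy

    def test_synthetic_duo_pairs(self):
        light, heavy = self._duo()
        pairs, ul, uh = find_isotope_pairs([light], [heavy])
        assert len(pairs) == 1 and not ul and not uh
        assert math.isclose(pairs[0].mass_shift, 4.0251, abs_tol=1e-3)

    def test_light_without_partner_stays_unpaired(self):
        light, heavy = self._duo()
        other = Peptide("GASGSGK", mods=((2, MOD_2HG),))
        lone = psm_from(other, noiseless_spectrum(other, rt=5.0))
        pairs, ul, uh = find_isotope_pairs([light, lone], [heavy])
        assert len(pairs) == 1
        assert [p.peptide.sequence for p in ul] == ["GASGSGK"]

    def test_rt_mismatch_rejected(self):
        pep = Peptide("TGGAESTGDK", mods=((5, MOD_2HG),))
        light = psm_from(pep, noiseless_spectrum(pep, rt=20.0))
        heavy = psm_from(
            pep, noiseless_spectrum(pep, heavy=True, rt=25.0), heavy=True
        )
        pairs, ul, uh = find_isotope_pairs([light], [heavy], rt_tol_min=1.0)
        assert not pairs and len(ul) == 1 and len(uh) == 1

    def test_shifted_nonmod_ion_violates_ladder_rule(self):
        """A heavy spectrum whose mod-free y-ion moved must be rejected."""
        pep = Peptide("TGGAESTGDK", mods=((5, MOD_2HG),))
        light = psm_from(pep, noiseless_spectrum(pep, rt=20.0))
        ions = theoretical_fragments(pep, (1, 2), True, heavy=True)
        peaks = []
        for ion in ions:
            mz_val = ion.mz
            if ion.series == "y" and ion.index == 2 and ion.charge == 1:
                mz_val += 4.0251  # y2 = DK contains no mod; shift it anyway
            peaks.append((mz_val, 100.0))
        neutral = peptide_neutral_mass(pep.sequence, [(5, MOD_2HG.heavy())])
        corrupted = Spectrum.from_peaks("bad", mz(neutral, 2), 2, 20.1, peaks)
        heavy_psm, _ = match_spectrum(corrupted, [pep], heavy=True)
        pairs, ul, uh = find_isotope_pairs([light], [heavy_psm])
        assert not pairs

    def test_pairing_is_symmetric_under_swap(self):
        light, heavy = self._duo()
        pairs_fwd, _, _ = find_isotope_pairs([light], [heavy])
        # swapping roles: the heavy-minus-light shift becomes negative, so
        # symmetric behaviour means the same single pair is found by mass
        assert len(pairs_fwd) == 1

    def test_empty_input_rejected(self):
        light, heavy = self._duo()
        with pytest.raises(ValueError):
            find_isotope_pairs([], [heavy])
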