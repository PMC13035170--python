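"""Diagnostic checks and confidence tiering."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oglyco import (
    HEXNAC,
    HEXNAC_NEUTRAL_LOSS,
    Loss,
    PSMRecord,
    Peptide,
    SimulationConfig,
    Spectrum,
    Tier,
    ValidationConfig,
    classify,
    detect_neutral_loss,
    generate_dataset,
    generate_fragments,
    match_peaks,
    mz_from_mass,
    peptide_neutral_mass,
    scan_oxonium,
    simulate_spectrum,
    site_support,
    validate_psm,
)
from oglyco.fragment_model import DEFAULT_OXONIUM


def spectrum_of(peaks, sid="scan=1", mz=872.4, z=2):
    return Spectrum(identifier=sid, precursor_mz=mz, precursor_charge=z, peaks=tuple(peaks))


def psm_of(peptide, score, expect=0.001, sid="scan=1", z=2, mz=None):
    if mz is None:
        mz = mz_from_mass(peptide_neutral_mass(peptide), z)
    return PSMRecord(
        spectrum_id=sid, peptide=peptide, ion_score=score, p_expect=expect,
        precursor_mz_observed=mz, charge=z, source_strain="WT-N2-L1",
    )


class TestOxoniumScan:
    def test_primary_and_secondary(self):
        s = spectrum_of([(204.0867, 100.0), (138.0550, 50.0)])
        assert scan_oxonium(s) == (True, True)

    def test_either_secondary_suffices(self):
        s = spectrum_of([(204.0867, 100.0), (144.066, 50.0)])
        assert scan_oxonium(s) == (True, True)

    def test_empty_spectrum(self):
        assert scan_oxonium(spectrum_of([])) == (False, False)

    def test_outside_window(self):
        s = spectrum_of([(204.15, 100.0)])
        assert scan_oxonium(s, tol_da=0.05)[0] is False

    def test_ppm_window(self):
        s = spectrum_of([(204.0867 * (1 + 8e-6), 100.0)])
        assert scan_oxonium(s, tol_ppm=10.0)[0] is True
        assert scan_oxonium(s, tol_ppm=5.0)[0] is False


class TestNeutralLoss:
    def test_precursor_level_planted(self, glycopeptide):
        mass = peptide_neutral_mass(glycopeptide)
        z = 2
        loss_mz = mz_from_mass(mass - HEXNAC_NEUTRAL_LOSS, z)
        s = spectrum_of([(loss_mz, 80.0)], z=z)
        flag, count = detect_neutral_loss(s, glycopeptide)
        assert flag is True and count == 0

    def test_charge_reduced_precursor_loss(self, glycopeptide):
        mass = peptide_neutral_mass(glycopeptide)
        loss_mz = mz_from_mass(mass - HEXNAC_NEUTRAL_LOSS, 1)  # z-1 of a 2+ precursor
        s = spectrum_of([(loss_mz, 80.0)], z=2)
        assert detect_neutral_loss(s, glycopeptide)[0] is True

    def test_fragment_level_pairs(self, glycopeptide):
        frags = generate_fragments(glycopeptide, max_charge=1)
        wanted = [f for f in frags if f.carries_mod and f.loss in (Loss.NONE, Loss.HEXNAC)
                  and f.series == "y" and f.index == 5]
        s = spectrum_of([(f.mz, 60.0) for f in wanted])
        flag, count = detect_neutral_loss(s, glycopeptide)
        assert count >= 1

    def test_unmodified_peptide_rejected(self):
        with pytest.raises(ValueError, match="without HexNAc"):
            detect_neutral_loss(spectrum_of([]), Peptide("PEPTIDEK"))


class TestSiteSupport:
    def planted_matches(self, p, keep=lambda f: True):
        frags = [f for f in generate_fragments(p, max_charge=1, losses_enabled=())
                 if keep(f)]
        s = spectrum_of([(f.mz, 50.0) for f in frags])
        return match_peaks(s, frags, 0.05)

    def test_full_ladder_supports_site(self):
        p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC),))
        support = site_support(self.planted_matches(p), p)
        assert support[9] == (True, True)

    def test_short_y_ladder_fails_far_site(self):
        # site 4 residues from the C-terminus; only y1..y2 matched
        p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC),))
        matches = self.planted_matches(
            p, keep=lambda f: f.series == "y" and f.index <= 2
        )
        assert site_support(matches, p)[9][1] is False

    def test_no_matches_no_support(self):
        p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC),))
        assert site_support([], p)[9] == (False, False)

    def test_n_terminal_site_supported_by_b1(self):
        p = Peptide("SAGAK", ((1, HEXNAC),))
        support = site_support(self.planted_matches(p), p)
        assert support[1][0] is True  # b1 alone localizes position 1


class TestClassify:
    @pytest.mark.parametrize(
        "score, expected",
        [
            (41.0, Tier.VERY_HIGH),
            (43.2, Tier.VERY_HIGH),
            (33.6, Tier.HIGH),
            (30.0, Tier.HIGH),   # ">=30" inclusive
            (40.0, Tier.VERY_HIGH),  # "40 or higher" inclusive
            (22.2, Tier.CANDIDATE),
            (29.9, Tier.CANDIDATE),
            (20.0, Tier.REJECTED),   # "more than 20" strict
            (15.0, Tier.REJECTED),
        ],
    )
    def test_score_tiers_with_passing_diagnostics(
        self, glycopeptide, passing_diagnostics, score, expected
    ):
        tier = classify(psm_of(glycopeptide, score), passing_diagnostics)
        assert tier.tier is expected

    def test_expect_gate_dominates(self, glycopeptide, passing_diagnostics):
        psm = psm_of(glycopeptide, 45.0, expect=0.05)
        assert classify(psm, passing_diagnostics).tier is Tier.REJECTED

    @pytest.mark.parametrize(
        "field, value, needle",
        [
            ("oxonium_primary_found", False, "oxonium"),
            ("oxonium_secondary_found", False, "secondary"),
            ("neutral_loss_precursor", False, "neutral loss"),
            ("site_flanking_b", False, "site support"),
            ("precursor_ppm", 14.0, "ppm"),
        ],
    )
    def test_failed_diagnostic_demotes_with_reason(
        self, glycopeptide, passing_diagnostics, field, value, needle
    ):
        d = dataclasses.replace(passing_diagnostics, **{field: value})
        if field == "neutral_loss_precursor":
            d = dataclasses.replace(d, neutral_loss_fragment_count=0)
        if field == "site_flanking_b":
            d = dataclasses.replace(d, site_flanking_y=False)
        tier = classify(psm_of(glycopeptide, 41.0), d)
        assert tier.tier is Tier.CANDIDATE
        assert any(needle in r for r in tier.reasons)

    @given(st.floats(20.1, 60.0), st.floats(20.1, 60.0))
    def test_monotone_in_score(self, s1, s2):
        p = Peptide("PNSRHDNVSPSK", ((9, HEXNAC),))
        d = dict(
            oxonium_primary_found=True, oxonium_secondary_found=True,
            neutral_loss_precursor=True, neutral_loss_fragment_count=1,
            site_flanking_b=True, site_flanking_y=True,
            precursor_ppm=2.0, matched_fraction=0.8,
        )
        from oglyco import DiagnosticOutcome
        diag = DiagnosticOutcome(**d)
        lo, hi = sorted((s1, s2))
        assert classify(psm_of(p, lo), diag).tier.rank <= classify(psm_of(p, hi), diag).tier.rank

    def test_demotion_always_explained(self, glycopeptide, passing_diagnostics):
        import dataclasses as dc
        d = dc.replace(passing_diagnostics, oxonium_primary_found=False)
        tier = classify(psm_of(glycopeptide, 35.0), d)
        assert tier.tier is Tier.CANDIDATE and tier.reasons


class TestValidatePSM:
    def test_spectrum_id_mismatch(self, glycopeptide):
        psm = psm_of(glycopeptide, 41.0, sid="scan=1")
        s = spectrum_of([], sid="scan=2")
        with pytest.raises(ValueError, match="scan=1"):
            validate_psm(psm, s)

    def test_zero_noise_true_glycopeptide(self, clean_config):
        ds = generate_dataset(clean_config)
        for truth, psm, s in zip(ds.truth, ds.psms, ds.spectra):
            if truth.is_glyco and psm.ion_score >= 30 and psm.p_expect < 0.05:
                report = validate_psm(psm, s)
                assert report.tier.tier in (Tier.HIGH, Tier.VERY_HIGH)
                assert report.mr_calc == peptide_neutral_mass(psm.peptide)
                break
        else:
            pytest.fail("no score-eligible glycopeptide in the clean world")

    def test_oxonium_ablation_demotes(self, clean_config):
        ds = generate_dataset(clean_config)
        for truth, psm, s in zip(ds.truth, ds.psms, ds.spectra):
            if truth.is_glyco and psm.ion_score >= 30 and psm.p_expect < 0.05:
                stripped = Spectrum(
                    identifier=s.identifier,
                    precursor_mz=s.precursor_mz,
                    precursor_charge=s.precursor_charge,
                    peaks=tuple(
                        (mz, i) for mz, i in s.peaks
                        if all(abs(mz - t) > 0.05 for t in
                               (DEFAULT_OXONIUM.primary, *DEFAULT_OXONIUM.secondary))
                    ),
                )
                report = validate_psm(psm, stripped)
                assert report.tier.tier is Tier.CANDIDATE
                assert any("oxonium" in r for r in report.tier.reasons)
                return
        pytest.fail("no eligible glycopeptide found")

    def test_determinism(self, clean_config):
        ds = generate_dataset(clean_config)
        r1 = validate_psm(ds.psms[0], ds.spectra[0])
        r2 = validate_psm(ds.psms[0], ds.spectra[0])
        assert r1 == r2


def test_config_round_trip(tmp_path):
    import yaml
    cfg_file = tmp_path / "run.yaml"
    cfg_file.write_text(yaml.safe_dump({
        "fragment_tol_da": 0.02,
        "oxonium": {"primary": 204.0867, "secondary": [138.055]},
        "losses_enabled": ["NH3", "HexNAc"],
    }))
    cfg = ValidationConfig.from_yaml(cfg_file)
    assert cfg.fragment_tol_da == 0.02
    assert cfg.oxonium.secondary == (138.055,)
    assert cfg.losses_enabled == ("NH3", "HexNAc")
    assert cfg.score_high == 30.0  # defaults retained
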