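"""Peak-list / PSM-table I/O and tolerance-based matching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oglyco import (
    Peptide,
    SimulationConfig,
    Spectrum,
    generate_dataset,
    generate_fragments,
    match_peaks,
    read_mgf,
    read_psm_table,
    write_mgf,
)
from oglyco.spectra_io import MGFError, nearest_peak


def make_spectrum(peaks, sid="scan=1", mz=500.0, z=2):
    return Spectrum(identifier=sid, precursor_mz=mz, precursor_charge=z, peaks=tuple(peaks))


class TestMGF:
    def test_round_trip(self, tmp_path, clean_config):
        ds = generate_dataset(clean_config)
        path = tmp_path / "spectra.mgf"
        write_mgf(ds.spectra, path)
        back = read_mgf(path)
        assert len(back) == len(ds.spectra)
        for a, b in zip(ds.spectra, back):
            assert a.identifier == b.identifier
            assert a.precursor_charge == b.precursor_charge
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
            assert len(a.peaks) == len(b.peaks)
            for (m1, _), (m2, _) in zip(a.peaks, b.peaks):
                assert m2 == pytest.approx(m1, abs=1e-6)

    def test_two_blocks(self, tmp_path):
        path = tmp_path / "two.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=a\nPEPMASS=500.1\nCHARGE=2+\n"
            "300.1 10\n100.2 5\nEND IONS\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=600.2\nCHARGE=3+\nEND IONS\n"
        )
        spectra = read_mgf(path)
        assert [s.identifier for s in spectra] == ["a", "b"]
        assert spectra[0].peaks[0][0] < spectra[0].peaks[1][0]  # sorted on load
        assert spectra[1].peaks == ()  # empty block preserved

    def test_malformed_block_names_ordinal(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=a\nPEPMASS=500.1\n100.0 1\nEND IONS\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=600.1\nnot-a-peak here\nEND IONS\n"
        )
        with pytest.raises(MGFError, match="block 2"):
            read_mgf(path)

    def test_missing_pepmass_rejected(self, tmp_path):
        path = tmp_path / "nopm.mgf"
        path.write_text("BEGIN IONS\nTITLE=a\n100.0 1\nEND IONS\n")
        with pytest.raises(MGFError, match="PEPMASS"):
            read_mgf(path)

    def test_unparseable_charge_flagged_missing(self, tmp_path):
        path = tmp_path / "q.mgf"
        path.write_text("BEGIN IONS\nTITLE=a\nPEPMASS=500.1\nCHARGE=zz\n100.0 1\nEND IONS\n")
        assert read_mgf(path)[0].precursor_charge is None


class TestPSMTable:
    HEADER = "spectrum_id,sequence,mods,ion_score,p_expect,precursor_mz,charge,source_strain\n"

    def test_valid_row(self, tmp_path):
        path = tmp_path / "psms.csv"
        path.write_text(
            self.HEADER
            + "scan=1,PNSRHDNVSPSK,HexNAc@S9; HexNAc@S11,41.0,0.001,872.41,2,WT-N2-L1\n"
        )
        records, rejects = read_psm_table(path)
        assert len(records) == 1 and rejects.empty
        assert len(records[0].peptide.hexnac_sites) == 2
        assert records[0].ion_score == 41.0

    def test_invalid_target_quarantined(self, tmp_path):
        path = tmp_path / "psms.csv"
        path.write_text(
            self.HEADER
            + "scan=1,GAGAK,HexNAc@A3,25.0,0.01,230.1,2,WT-N2-L1\n"
            + "scan=2,GSGAK,HexNAc@S2,25.0,0.01,250.1,2,WT-N2-L1\n"
        )
        records, rejects = read_psm_table(path)
        assert len(records) == 1
        assert len(rejects) == 1
        assert "not permitted" in rejects.iloc[0]["reject_reason"]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "psms.csv"
        path.write_text("spectrum_id,sequence,mods\n")
        with pytest.raises(ValueError, match="ion_score"):
            read_psm_table(path)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "psms.csv"
        path.write_text(self.HEADER)
        records, rejects = read_psm_table(path)
        assert records == [] and rejects.empty


class TestMatching:
    def test_planted_identity(self):
        p = Peptide("PEPTIDESK")
        frags = generate_fragments(p, max_charge=1, losses_enabled=())
        s = make_spectrum([(f.mz, 100.0) for f in frags])
        matches = match_peaks(s, frags, tol_da=0.05)
        assert len(matches) == len(frags)
        assert all(m.error_da == 0.0 for m in matches)

    def test_boundary_outside(self):
        s = make_spectrum([(400.06, 100.0)])
        frag = generate_fragments(Peptide("GK"), max_charge=1, losses_enabled=())[0]
        shifted = make_spectrum([(frag.mz + 0.06, 100.0)])
        assert match_peaks(shifted, [frag], tol_da=0.05) == []

    def test_nearest_peak_chosen(self):
        frags = generate_fragments(Peptide("GK"), max_charge=1, losses_enabled=())
        b1 = frags[0]
        s = make_spectrum([(b1.mz - 0.03, 500.0), (b1.mz + 0.01, 10.0)])
        (m,) = match_peaks(s, [b1], tol_da=0.05)
        assert m.error_da == pytest.approx(0.01)

    def test_equidistant_tie_breaks_to_intensity(self):
        peaks = ((99.99, 5.0), (100.01, 50.0))
        assert nearest_peak(peaks, 100.0, 0.05) == (100.01, 50.0)

    @given(st.permutations([(101.0, 1.0), (105.0, 2.0), (108.3, 3.0), (104.96, 9.0)]))
    def test_order_invariance(self, peaks):
        frags = generate_fragments(Peptide("GK"), max_charge=1, losses_enabled=())
        s = make_spectrum(peaks, mz=300.0)
        target = 105.0
        assert nearest_peak(s.peaks, target, 0.05) == (105.0, 2.0)

    def test_ppm_window_option(self):
        frags = generate_fragments(Peptide("PEPTIDESK"), max_charge=1, losses_enabled=())
        f = frags[-1]
        s = make_spectrum([(f.mz * (1 + 8e-6), 10.0)])
        assert match_peaks(s, [f], tol_ppm=10.0)
        assert match_peaks(s, [f], tol_ppm=5.0) == []


class TestSpectrumInvariants:
    def test_negative_mz_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum([(-1.0, 5.0)])

    def test_charge_range(self):
        with pytest.raises(ValueError):
            make_spectrum([(100.0, 1.0)], z=9)
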