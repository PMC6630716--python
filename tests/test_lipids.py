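"""Lipid composition rules and in-silico spectrum generation."""

import pytest

from lipidbridge.chem import F
from lipidbridge.lipids import (
    AcylChain,
    ChainSpace,
    LipidSpecies,
    acyl_anion_mz,
    build_library,
    generate_spectrum,
    neutral_formula,
    read_msp,
    write_msp,
)


def fragment_mzs(spectrum, ndigits=3):
    return {round(f.mz, ndigits) for f in spectrum.fragments}


class TestAcylChain:
    @pytest.mark.parametrize("text,carbons,db,ox", [
        ("18:0", 18, 0, 0), ("20:4", 20, 4, 0), ("20:4+2O", 20, 4, 2),
    ])
    def test_parse(self, text, carbons, db, ox):
        c = AcylChain.parse(text)
        assert (c.carbons, c.double_bonds, c.extra_oxygens) == (carbons, db, ox)

    def test_fatty_acid_formula(self):
        assert AcylChain(18, 0).fatty_acid.counts == {"C": 18, "H": 36, "O": 2}
        assert AcylChain(20, 4, 2).fatty_acid.counts == {"C": 20, "H": 32, "O": 4}

    @pytest.mark.parametrize("chain,expected", [
        ((18, 0, 0), 283.264),
        ((16, 1, 0), 253.217),
        ((16, 2, 0), 251.202),  # printed as 251.201 (truncation)
        ((20, 4, 0), 303.233),
        ((20, 4, 2), 335.223),
    ])
    def test_acyl_anion_mz(self, chain, expected):
        assert abs(round(acyl_anion_mz(AcylChain(*chain)), 3) - expected) \
            <= 0.0015

    def test_invalid_chains_rejected(self):
        with pytest.raises(ValueError):
            AcylChain(1, 0)
        with pytest.raises(ValueError):
            AcylChain(18, 18)


class TestNeutralFormula:
    def test_ffa_is_the_fatty_acid(self):
        sp = LipidSpecies.parse("FFA 18:0")
        assert neutral_formula(sp).counts == {"C": 18, "H": 36, "O": 2}

    def test_dgcc_example(self):
        # validated by its neutral-loss fragment C30H52NO7+ at 538.374
        sp = LipidSpecies.parse("DGCC 18:0-20:4")
        assert str(neutral_formula(sp)) == "C48H87NO9"

    def test_chain_count_enforced(self):
        with pytest.raises(ValueError):
            LipidSpecies("LPG", (AcylChain(16, 0), AcylChain(18, 0)))
        with pytest.raises(ValueError):
            LipidSpecies("PC", (AcylChain(16, 0),))

    def test_ox_class_needs_extra_oxygen(self):
        with pytest.raises(ValueError):
            LipidSpecies.parse("OxPE 18:0-20:4")

    def test_underscore_dialect_normalized(self):
        assert LipidSpecies.parse("PC 16:0_18:1") == \
            LipidSpecies.parse("PC 16:0-18:1")


class TestGenerateSpectrum:
    def test_dgcc_fragments(self):
        s = generate_spectrum(LipidSpecies.parse("DGCC 18:0-20:4"))
        assert {104.107, 132.102, 538.374, 520.363, 518.405, 500.395} \
            <= fragment_mzs(s)
        assert {round(f.mz, 3) for f in s.class_fragments} == {104.107, 132.102}
        assert len(s.chain_fragments) == 4

    def test_oxpe_fragments_include_dehydrations(self):
        s = generate_spectrum(LipidSpecies.parse("OxPE 18:0-20:4+2O"))
        assert {196.038, 283.264, 335.223, 317.212, 299.202} <= fragment_mzs(s)
        minor = [f for f in s.fragments if f.minor]
        assert len(minor) == 1 and round(minor[0].mz, 3) == 299.202

    def test_lps_serine_neutral_loss(self):
        s = generate_spectrum(LipidSpecies.parse("LPS 18:0"))
        assert {437.267, 283.264} <= fragment_mzs(s)

    def test_oxpc_demethylation_from_formate_adduct(self):
        s = generate_spectrum(LipidSpecies.parse("OxPC 18:0-20:4+2O"))
        nl = [f for f in s.class_fragments][0]
        assert round(nl.mz, 2) == 826.56

    def test_ldgcc_has_no_chain_fragments(self):
        s = generate_spectrum(LipidSpecies.parse("LDGCC 18:0"))
        assert s.chain_fragments == []
        assert {round(f.mz, 3) for f in s.class_fragments} == {104.107, 132.102}

    def test_dgdg_class_ion(self):
        s = generate_spectrum(LipidSpecies.parse("DGDG 16:0-18:3"))
        assert 397.135 in fragment_mzs(s)

    def test_unsupported_pair_lists_supported(self):
        with pytest.raises(ValueError, match=r"\[M\+H\]\+"):
            generate_spectrum(LipidSpecies.parse("DGCC 18:0-20:4"), "[M-H]-")

    def test_base_peak_is_100_and_sorted(self):
        s = generate_spectrum(LipidSpecies.parse("MGDG 16:0-18:3"))
        assert max(f.relative_abundance for f in s.fragments) == 100.0
        mzs = [f.mz for f in s.fragments]
        assert mzs == sorted(mzs)

    def test_swapping_chain_positions_keeps_precursor(self):
        a = generate_spectrum(LipidSpecies.parse("PMeOH 18:0-20:4"))
        b = generate_spectrum(LipidSpecies.parse("PMeOH 20:4-18:0"))
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-9)
        assert fragment_mzs(a) == fragment_mzs(b)

    def test_fragments_rederivable_from_formulas(self):
        from lipidbridge.chem import ion_mz
        for name in ("DGCC 18:0-20:4", "OxPI 18:0-20:4+2O", "LPS 18:0"):
            s = generate_spectrum(LipidSpecies.parse(name))
            for f in s.fragments:
                assert f.formula is not None
                assert ion_mz(f.formula) == pytest.approx(f.mz, abs=1e-9)


class TestBuildLibrary:
    def test_lpg_enumeration_count(self):
        lib = build_library(["LPG"], ChainSpace((16, 17, 18), (0, 1)))
        assert len(lib) == 6

    def test_single_pair_single_spectrum(self):
        lib = build_library(
            ["DGCC"], [ChainSpace((18,), (0,)), ChainSpace((20,), (4,))])
        assert len(lib) == 1

    def test_dedup_by_chain_multiset(self):
        lib = build_library(["PMeOH"], ChainSpace((16, 18), (0,)))
        names = {(s.name, s.adduct) for s in lib}
        assert len(names) == len(lib) == 3  # 16/16, 16/18, 18/18

    def test_empty_enumeration_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            lib = build_library([], ChainSpace((16,), (0,)))
        assert lib == []


class TestMsp:
    def test_round_trip(self, tmp_path, dgdg_library):
        path = tmp_path / "lib.msp"
        spectra = list(dgdg_library)
        spectra[0].retention_time = 10.25
        write_msp(spectra, path)
        back = read_msp(path)
        assert len(back) == len(spectra)
        for a, b in zip(spectra, back):
            assert b.name == a.name and b.adduct == a.adduct
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-6)
            assert len(b.fragments) == len(a.fragments)
            for fa, fb in zip(a.fragments, b.fragments):
                assert fb.mz == pytest.approx(fa.mz, abs=1e-6)
                assert fb.relative_abundance == pytest.approx(
                    fa.relative_abundance, abs=1e-4)
                assert fb.annotation == fa.annotation
                assert fb.diagnostic == fa.diagnostic
                assert fb.minor == fa.minor
        assert back[0].retention_time == pytest.approx(10.25)

    def test_peak_count_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text("NAME: X\nPRECURSORMZ: 100.0\nPRECURSORTYPE: [M-H]-\n"
                        "Num Peaks: 2\n50.0\t10.0\n\n")
        with pytest.raises(ValueError, match="expected 2"):
            read_msp(path)
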