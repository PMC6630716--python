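"""Targeted MS/MS-chromatogram quantification and posterior scoring."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from lipidbridge.annotate import annotate_feature
from lipidbridge.lipids import LipidSpecies, generate_spectrum
from lipidbridge.peaks import PeakFeature
from lipidbridge.synthdata import PlantedCompound, SimConfig, simulate_run
from lipidbridge.targeted import (
    TargetedParams,
    posterior,
    quantify_entry,
    resolve_coeluted,
)
from lipidbridge.transitions import (
    Product,
    TransitionEntry,
    build_transitions,
)

PARAMS = TargetedParams()


def entry_for(name, rt, extra_candidates=()):
    lib = [generate_spectrum(LipidSpecies.parse(n))
           for n in (name, *extra_candidates)]
    feature = PeakFeature(apex_rt=rt, apex_index=0, left_edge=0,
                          right_edge=10, height=1e4, area=1e3,
                          mz=lib[0].precursor_mz)
    merged = {}
    for s in lib:
        for f in s.fragments:
            key = round(f.mz, 4)
            merged[key] = merged.get(key, 0.0) + f.relative_abundance
    cands = annotate_feature(feature, sorted(merged.items()), lib, cutoff=0.0)
    return build_transitions(cands)


class TestPosterior:
    def test_perfect_agreement(self):
        assert posterior(0.0, 0.0, True) == 1.0

    def test_missing_qualifier_zeroes(self):
        assert posterior(0.0, 0.0, False) == 0.0

    def test_one_sigma_rt_deviation(self):
        assert posterior(PARAMS.rt_tol, 0.0, True) == \
            pytest.approx(math.exp(-1))

    def test_one_sigma_amplitude_deviation(self):
        assert posterior(0.0, PARAMS.amplitude_tol, True) == \
            pytest.approx(math.exp(-1))

    def test_negative_deviation_rejected(self):
        with pytest.raises(ValueError):
            posterior(-0.1, 0.0, True)


def plant(name="DGCC 18:0-20:4", rt=0.5, ms1=5e4, msms=1e4, **cfg_kwargs):
    cfg = SimConfig(rt_range=(0.0, 1.0), **cfg_kwargs)
    run, _ = simulate_run(
        [PlantedCompound(LipidSpecies.parse(name), rt_center=rt,
                         ms1_height=ms1, msms_yield=msms)], cfg)
    return run


class TestQuantifyEntry:
    def test_planted_compound_recovered(self):
        run = plant(noise_level=0.05, seed=4)
        entry = entry_for("DGCC 18:0-20:4", rt=0.5)[0]
        res = quantify_entry(run, entry)
        assert res.detected
        assert res.posterior > 0.9
        # quantifier is the most intense chain fragment: abundance 40/100
        assert res.quantifier_height == pytest.approx(1e4 * 0.4, rel=0.1)
        assert abs(res.apex_rt - 0.5) < 0.02

    def test_rt_shift_beyond_tolerance_not_detected(self):
        run = plant()
        entry = entry_for("DGCC 18:0-20:4", rt=1.0)[0]
        res = quantify_entry(run, entry)
        assert not res.detected

    def test_missing_qualifier_kills_posterior(self):
        run = plant()
        entry = entry_for("DGCC 18:0-20:4", rt=0.5)[0]
        spiked = TransitionEntry(
            name=entry.name, rt=entry.rt, precursor_mz=entry.precursor_mz,
            products=entry.products + [Product(450.45, "qualifier")])
        res = quantify_entry(run, spiked)
        assert res.posterior < 0.7
        assert not res.detected

    def test_quantifier_linearity(self):
        entry = entry_for("DGCC 18:0-20:4", rt=0.5)[0]
        h1 = quantify_entry(plant(msms=1e4), entry).quantifier_height
        h2 = quantify_entry(plant(msms=2e4), entry).quantifier_height
        assert h2 == pytest.approx(2 * h1, rel=0.01)

    def test_independent_of_unrelated_entries(self):
        run = plant()
        entries = entry_for("DGCC 18:0-20:4", rt=0.5)
        alone = quantify_entry(run, entries[0])
        other = TransitionEntry(
            name="decoy", rt=0.5, precursor_mz=entries[0].precursor_mz,
            products=[Product(900.0, "quantifier", 100.0)])
        _ = quantify_entry(run, other)
        again = quantify_entry(run, entries[0])
        assert again.quantifier_height == alone.quantifier_height
        assert again.posterior == alone.posterior

    def test_dda_run_rejected(self):
        run = plant(acquisition_mode="DDA")
        entry = entry_for("DGCC 18:0-20:4", rt=0.5)[0]
        with pytest.raises(ValueError, match="DIA"):
            quantify_entry(run, entry)


class TestResolveCoeluted:
    def simulate_mixture(self, fractions=(0.7, 0.2, 0.1), seed=0,
                         noise=0.05):
        names = ("DGDG 16:2-18:1", "DGDG 16:1-18:2", "DGDG 16:0-18:3")
        offsets = (-0.02, 0.0, 0.02)
        compounds = [
            PlantedCompound(LipidSpecies.parse(n), rt_center=0.5 + off,
                            ms1_height=6e4 * f, msms_yield=2e4 * f)
            for n, off, f in zip(names, offsets, fractions) if f > 0]
        cfg = SimConfig(rt_range=(0.0, 1.0), noise_level=noise, seed=seed)
        run, _ = simulate_run(compounds, cfg)
        entries = entry_for(names[0], rt=0.5, extra_candidates=names[1:])
        return run, entries, dict(zip(names, fractions))

    def test_mixture_ratios_recovered(self):
        run, entries, planted = self.simulate_mixture()
        results, comp = resolve_coeluted(run, entries)
        assert all(r.detected for r in results)
        for name, frac in planted.items():
            assert comp[name] == pytest.approx(100 * frac, abs=10)
        # the shared-precursor MS1 height is common to all entries
        ms1 = {round(r.ms1_height) for r in results}
        assert len(ms1) == 1

    def test_single_entry_composition_is_100(self):
        run, entries, _ = self.simulate_mixture(fractions=(1.0, 0, 0))
        planted = [e for e in entries if e.name == "DGDG 16:2-18:1"]
        results, comp = resolve_coeluted(run, planted)
        assert comp["DGDG 16:2-18:1"] == pytest.approx(100.0)

    def test_absent_isomer_not_detected_others_unaffected(self):
        run, entries, planted = self.simulate_mixture(
            fractions=(0.8, 0.2, 0.0))
        results, comp = resolve_coeluted(run, entries)
        by_name = {r.entry.name: r for r in results}
        assert not by_name["DGDG 16:0-18:3"].detected
        assert by_name["DGDG 16:2-18:1"].detected
        assert comp["DGDG 16:2-18:1"] == pytest.approx(80.0, abs=10)


class TestSaturation:
    def test_msms_saturation_degrades_rank_correlation(self):
        """With the MS/MS channel clipped at a ceiling, abundance ranking
        from MS/MS heights degrades relative to the MS1 ranking."""
        names = ["LPG 14:0", "LPG 16:0", "LPG 18:0", "LPG 18:1",
                 "LPG 20:0", "LPG 20:1"]
        heights = np.array([1e3, 4e3, 1.6e4, 6.4e4, 2.56e5, 1.02e6])
        compounds = [
            PlantedCompound(LipidSpecies.parse(n), rt_center=0.2 + 0.1 * i,
                            ms1_height=h, msms_yield=h)
            for i, (n, h) in enumerate(zip(names, heights))]
        cfg = SimConfig(rt_range=(0.0, 1.0), noise_level=0.02, seed=9,
                        msms_saturation_ceiling=2e4)
        run, _ = simulate_run(compounds, cfg)
        ms1_h, msms_h = [], []
        for i, name in enumerate(names):
            entry = entry_for(name, rt=0.2 + 0.1 * i)[0]
            res = quantify_entry(run, entry)
            ms1_h.append(res.ms1_height)
            msms_h.append(res.quantifier_height)
        rho_ms1 = spearmanr(heights, ms1_h).statistic
        rho_msms = spearmanr(heights, msms_h).statistic
        assert rho_msms <= rho_ms1
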