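"""Synthetic SWATH/DDA run generator with ground truth.

Emulates the acquisition geometry of a QTOF SWATH experiment: repeating
cycles of one MS1 survey scan plus 21-Da isolation windows stepped every
20 Da over m/z 100-1250, Gaussian elution profiles, class-specific fragment
patterns from the in-silico library, multiplicative intensity noise with an
optional additive baseline, and an optional MS/MS saturation ceiling (the
SWATH channel of a real QTOF saturates before MS1 does).

All randomness flows through one seeded generator; a fixed seed gives
byte-identical mzML output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lipids import LipidSpecies, ReferenceSpectrum, generate_spectrum
from .msdata import MSRun, Scan, WindowGrid

_EMPTY = np.array([], dtype=np.float64)
_EMPTY.setflags(write=False)


@dataclass(frozen=True)
class PlantedCompound:
    """Ground-truth spike: a lipid species eluting as a Gaussian peak."""

    lipid: LipidSpecies
    rt_center: float                 # minutes
    ms1_height: float                # counts at apex
    msms_yield: float                # fragment scale: base peak counts at apex
    rt_sigma: float = 0.05           # minutes (~12 points per peak at the
                                     # DIA cycle-time preset)
    adduct: Optional[str] = None     # default: the class's supported adduct

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.ms1_height <= 0 or self.msms_yield <= 0:
            raise ValueError("rt_sigma and heights must be > 0")

    def spectrum(self) -> ReferenceSpectrum:
        return generate_spectrum(self.lipid, self.adduct)


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and noise model for one simulated run."""

    cycle_time: float = 0.73         # seconds (DIA preset; DDA preset 0.65)
    window_grid: WindowGrid = field(default_factory=WindowGrid)
    rt_range: Tuple[float, float] = (0.0, 2.0)   # minutes
    noise_level: float = 0.0         # multiplicative Gaussian sigma
    baseline_noise: float = 0.0      # additive |Gaussian| counts
    msms_saturation_ceiling: Optional[float] = None
    acquisition_mode: str = "DIA"    # "DIA" | "DDA"
    dda_trigger_height: float = 1000.0
    seed: int = 0


def _merge_peaks(mz: np.ndarray, inten: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and sum intensities of coincident channels."""
    if len(mz) == 0:
        return _EMPTY, _EMPTY
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    key = np.round(mz, 6)
    uniq, index = np.unique(key, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, index, inten)
    return uniq, summed


def simulate_run(
    compounds: Sequence[PlantedCompound],
    config: SimConfig = SimConfig(),
) -> Tuple[MSRun, pd.DataFrame]:
    """Simulate one run; returns the run and its ground-truth table."""
    rng = np.random.default_rng(config.seed)
    grid = config.window_grid
    specs = [c.spectrum() for c in compounds]
    assignments = []
    for c, s in zip(compounds, specs):
        window = grid.window_for(s.precursor_mz)  # raises outside coverage
        assignments.append(window)
    polarity = ("positive" if specs and specs[0].adduct.endswith("+")
                else "negative")

    lo, hi = config.rt_range
    dt = config.cycle_time / 60.0
    times = np.arange(lo, hi, dt)
    profiles = [
        np.exp(-0.5 * ((times - c.rt_center) / c.rt_sigma) ** 2)
        for c in compounds
    ]

    def noisy(value: float) -> float:
        v = value
        if config.noise_level > 0:
            v *= 1.0 + rng.normal(0.0, config.noise_level)
        if config.baseline_noise > 0:
            v += abs(rng.normal(0.0, config.baseline_noise))
        return max(v, 0.0)

    scans: List[Scan] = []
    windows = grid.windows
    truth_rows = []
    for c, s, w in zip(compounds, specs, assignments):
        truth_rows.append({
            "name": s.name, "adduct": s.adduct,
            "precursor_mz": s.precursor_mz, "window_lower": w[0],
            "rt_center": c.rt_center, "rt_sigma": c.rt_sigma,
            "ms1_height": c.ms1_height, "msms_yield": c.msms_yield,
        })

    for k, t in enumerate(times):
        ms1_mz, ms1_int = [], []
        active: List[int] = []
        for ci, (c, prof) in enumerate(zip(compounds, profiles)):
            v = c.ms1_height * prof[k]
            if v > 1e-6:
                ms1_mz.append(specs[ci].precursor_mz)
                ms1_int.append(noisy(v))
                active.append(ci)
        mz_arr, in_arr = _merge_peaks(np.asarray(ms1_mz),
                                      np.asarray(ms1_int))
        scans.append(Scan(retention_time=float(t), ms_level=1,
                          mz=mz_arr, intensity=in_arr))

        if config.acquisition_mode == "DIA":
            by_window: Dict[Tuple[float, float], List[int]] = {}
            for ci in active:
                by_window.setdefault(assignments[ci], []).append(ci)
            for w in windows:
                members = by_window.get(w, [])
                if not members:
                    scans.append(Scan(retention_time=float(t), ms_level=2,
                                      mz=_EMPTY, intensity=_EMPTY,
                                      isolation_window=w))
                    continue
                fm, fi = [], []
                for ci in members:
                    c = compounds[ci]
                    scale = c.msms_yield * profiles[ci][k] / 100.0
                    for frag in specs[ci].fragments:
                        v = noisy(frag.relative_abundance * scale)
                        if config.msms_saturation_ceiling is not None:
                            v = min(v, config.msms_saturation_ceiling)
                        fm.append(frag.mz)
                        fi.append(v)
                mz_arr, in_arr = _merge_peaks(np.asarray(fm), np.asarray(fi))
                scans.append(Scan(retention_time=float(t), ms_level=2,
                                  mz=mz_arr, intensity=in_arr,
                                  isolation_window=w))
        else:  # DDA: trigger one narrow-window MS2 per sufficiently tall ion
            triggered = sorted(
                (ci for ci in active
                 if compounds[ci].ms1_height * profiles[ci][k]
                 >= config.dda_trigger_height),
                key=lambda ci: -compounds[ci].ms1_height * profiles[ci][k])
            for ci in triggered:
                c = compounds[ci]
                prec = specs[ci].precursor_mz
                scale = c.msms_yield * profiles[ci][k] / 100.0
                fm = np.array([f.mz for f in specs[ci].fragments])
                fi = np.array([noisy(f.relative_abundance * scale)
                               for f in specs[ci].fragments])
                mz_arr, in_arr = _merge_peaks(fm, fi)
                scans.append(Scan(
                    retention_time=float(t), ms_level=2,
                    mz=mz_arr, intensity=in_arr,
                    isolation_window=(prec - 0.5, prec + 0.5),
                    selected_ion=prec))

    run = MSRun(scans=scans, polarity=polarity,
                acquisition_mode=config.acquisition_mode, window_grid=grid)
    return run, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# The DGDG 34:3 co-elution showcase

DGDG_ISOMERS = ("DGDG 16:2-18:1", "DGDG 16:1-18:2", "DGDG 16:0-18:3")

#: Nine pseudo-samples named after algal taxa, each with a dominant DGDG
#: 34:3 isomer.  Mixing fractions are synthetic (no composition numbers
#: exist to copy); the dominant-isomer pattern mirrors the phylum split
#: reported for these taxa, with the P. lutheri major an arbitrary choice.
SHOWCASE_MIXTURES: Dict[str, Dict[str, float]] = {
    "A_protothecoides": {"DGDG 16:0-18:3": 70, "DGDG 16:1-18:2": 20, "DGDG 16:2-18:1": 10},
    "C_sorokiniana":    {"DGDG 16:0-18:3": 65, "DGDG 16:1-18:2": 15, "DGDG 16:2-18:1": 20},
    "C_variabilis":     {"DGDG 16:0-18:3": 75, "DGDG 16:1-18:2": 10, "DGDG 16:2-18:1": 15},
    "C_reinhardtii":    {"DGDG 16:0-18:3": 60, "DGDG 16:1-18:2": 25, "DGDG 16:2-18:1": 15},
    "D_salina":         {"DGDG 16:0-18:3": 70, "DGDG 16:1-18:2": 15, "DGDG 16:2-18:1": 15},
    "E_gracilis":       {"DGDG 16:2-18:1": 70, "DGDG 16:1-18:2": 20, "DGDG 16:0-18:3": 10},
    "N_oculata":        {"DGDG 16:1-18:2": 65, "DGDG 16:0-18:3": 20, "DGDG 16:2-18:1": 15},
    "P_carterae":       {"DGDG 16:1-18:2": 70, "DGDG 16:0-18:3": 15, "DGDG 16:2-18:1": 15},
    "P_lutheri":        {"DGDG 16:0-18:3": 60, "DGDG 16:1-18:2": 20, "DGDG 16:2-18:1": 20},
}

_ISOMER_RT_OFFSET = {"DGDG 16:2-18:1": -0.02, "DGDG 16:1-18:2": 0.0,
                     "DGDG 16:0-18:3": 0.02}


def dgdg_showcase(
    config: Optional[SimConfig] = None,
    rt_center: float = 10.0,
    total_ms1_height: float = 6.0e4,
    total_msms_yield: float = 2.0e4,
) -> Tuple[Dict[str, Tuple[MSRun, pd.DataFrame]], pd.DataFrame]:
    """Nine pseudo-samples, each planting the three DGDG 34:3 isomers at
    near-identical retention times (offsets within +/- 0.02 min).

    Returns ``(runs, truth)`` where ``runs`` maps sample name to
    ``(MSRun, per-run truth)`` and ``truth`` is the combined table with a
    ``fraction`` column (planted mixing percent) and ``sample`` column.
    """
    base = config or SimConfig(rt_range=(9.5, 10.5), noise_level=0.05)
    runs: Dict[str, Tuple[MSRun, pd.DataFrame]] = {}
    combined = []
    for i, (sample, mixture) in enumerate(sorted(SHOWCASE_MIXTURES.items())):
        compounds = []
        for name in DGDG_ISOMERS:
            frac = mixture[name] / 100.0
            compounds.append(PlantedCompound(
                lipid=LipidSpecies.parse(name),
                rt_center=rt_center + _ISOMER_RT_OFFSET[name],
                ms1_height=total_ms1_height * frac,
                msms_yield=total_msms_yield * frac,
            ))
        cfg = replace(base, seed=base.seed + i)
        run, truth = simulate_run(compounds, cfg)
        truth["sample"] = sample
        truth["fraction"] = [mixture[n] for n in DGDG_ISOMERS]
        truth["is_major"] = truth["fraction"] == truth["fraction"].max()
        runs[sample] = (run, truth)
        combined.append(truth)
    return runs, pd.concat(combined, ignore_index=True)
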