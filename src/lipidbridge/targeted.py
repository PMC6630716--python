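"""MRM-style targeted quantification on DIA MS/MS chromatograms.

For each reference entry the quantifier product's XIC is extracted from the
entry's SWATH window, lightly smoothed (level 1, so closely co-eluting peaks
stay separate), and peak-picked; all other product traces share the
quantifier peak's edges (the peak-group concept).  A 0-1 posterior scores
retention-time and abundance-ratio agreement with the reference, gated on
the presence of every "Q" qualifier ion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .msdata import Chromatogram, MSRun, extract_xic
from .peaks import detect_peaks, smooth
from .transitions import TransitionEntry


@dataclass(frozen=True)
class TargetedParams:
    """Targeted-stage parameters (field-standard defaults)."""

    ms1_tol: float = 0.01
    ms2_tol: float = 0.025
    smoothing_level: int = 1
    min_peak_width: int = 5
    min_peak_height: float = 200.0
    rt_tol: float = 0.1          # minutes
    amplitude_tol: float = 15.0  # percent points
    min_posterior: float = 0.7


def posterior(
    rt_deviation: float,
    amplitude_deviation: float,
    qualifiers_present: bool,
    params: TargetedParams = TargetedParams(),
) -> float:
    """Confidence that the detected peak group is the reference metabolite.

    Gaussian penalties on the RT and ratio deviations (sigma = the
    respective tolerance) times an indicator that every required qualifier
    ion is present.
    """
    if rt_deviation < 0 or amplitude_deviation < 0:
        raise ValueError("deviations must be >= 0")
    if not qualifiers_present:
        return 0.0
    return (math.exp(-((rt_deviation / params.rt_tol) ** 2))
            * math.exp(-((amplitude_deviation / params.amplitude_tol) ** 2)))


@dataclass
class TargetedResult:
    """Quantification outcome for one transition entry."""

    entry: TransitionEntry
    detected: bool
    apex_rt: Optional[float] = None
    quantifier_height: float = 0.0
    quantifier_area: float = 0.0
    observed_ratios: Dict[float, float] = field(default_factory=dict)
    rt_deviation: Optional[float] = None
    amplitude_deviation: Optional[float] = None
    posterior: float = 0.0
    ms1_height: float = 0.0


def _trace(run: MSRun, mz: float, window, params: TargetedParams
           ) -> Tuple[Chromatogram, Chromatogram]:
    raw = extract_xic(run, mz, params.ms2_tol, ms_level=2, window=window)
    return raw, smooth(raw, params.smoothing_level)


def quantify_entry(
    run: MSRun,
    entry: TransitionEntry,
    params: TargetedParams = TargetedParams(),
) -> TargetedResult:
    """Quantify one reference entry on its MS/MS chromatogram peak group.

    Returns a ``detected=False`` result (not an error) when no quantifier
    peak lies within the RT tolerance of the reference retention time.
    """
    if run.acquisition_mode != "DIA":
        raise ValueError("targeted quantification requires a DIA run")
    window = run.window_for(entry.precursor_mz)
    quant = entry.quantifier
    raw, smoothed = _trace(run, quant.product_mz, window, params)
    peaks = detect_peaks(smoothed, params.min_peak_width,
                         params.min_peak_height, raw=raw)
    in_tol = [p for p in peaks if abs(p.apex_rt - entry.rt) <= params.rt_tol]
    if not in_tol:
        return TargetedResult(entry=entry, detected=False)
    peak = min(in_tol, key=lambda p: abs(p.apex_rt - entry.rt))
    left, right = peak.left_edge, peak.right_edge

    # product traces share the quantifier peak's edges (peak group); each
    # product's height is the least-squares amplitude of the quantifier
    # peak shape fitted to its raw trace, which uses every point in the
    # group instead of a single noisy apex sample
    shape = smoothed.intensities[left:right + 1]
    denom = float(shape @ shape)
    apex_shape = float(shape.max())

    def fitted(trace: np.ndarray) -> float:
        return max(float(trace[left:right + 1] @ shape) / denom, 0.0)

    coeff_q = fitted(raw.intensities)
    heights: Dict[float, float] = {quant.product_mz: coeff_q * apex_shape}
    for p in entry.products:
        if p.product_mz == quant.product_mz:
            continue
        praw, _ = _trace(run, p.product_mz, window, params)
        heights[p.product_mz] = fitted(praw.intensities) * apex_shape

    ratios = {mz: 100.0 * h / heights[quant.product_mz]
              for mz, h in heights.items()}
    amp_dev = 0.0
    qualifiers_ok = True
    for p in entry.products:
        if p.role == "qualifier":
            if heights[p.product_mz] < params.min_peak_height:
                qualifiers_ok = False
        elif p.role == "ratio":
            amp_dev = max(amp_dev, abs(ratios[p.product_mz] - p.ratio))
    rt_dev = abs(peak.apex_rt - entry.rt)
    post = posterior(rt_dev, amp_dev, qualifiers_ok, params)

    ms1 = extract_xic(run, entry.precursor_mz, params.ms1_tol, ms_level=1)
    lo_rt, hi_rt = raw.times[left], raw.times[right]
    mask = (ms1.times >= lo_rt) & (ms1.times <= hi_rt)
    ms1_height = float(ms1.intensities[mask].max()) if mask.any() else 0.0

    return TargetedResult(
        entry=entry,
        detected=post >= params.min_posterior and rt_dev <= params.rt_tol,
        apex_rt=peak.apex_rt,
        quantifier_height=peak.height,
        quantifier_area=peak.area,
        observed_ratios=ratios,
        rt_deviation=rt_dev,
        amplitude_deviation=amp_dev,
        posterior=post,
        ms1_height=ms1_height,
    )


def resolve_coeluted(
    run: MSRun,
    entries: Sequence[TransitionEntry],
    params: TargetedParams = TargetedParams(),
) -> Tuple[List[TargetedResult], Dict[str, float]]:
    """Quantify entries sharing a precursor window, each on its own unique
    quantifier trace, and report their relative composition (percent of the
    summed quantifier heights of detected entries).

    The per-entry MS1 height is carried along for contrast: co-eluted
    isomers share one merged MS1 peak, so MS1-centric results cannot tell
    them apart.
    """
    results = [quantify_entry(run, e, params) for e in entries]
    total = sum(r.quantifier_height for r in results if r.detected)
    composition = {
        r.entry.name: (100.0 * r.quantifier_height / total
                       if r.detected and total > 0 else 0.0)
        for r in results
    }
    return results, composition


def results_table(results: Sequence[TargetedResult]) -> pd.DataFrame:
    recs = []
    for r in results:
        recs.append({
            "name": r.entry.name,
            "reference_rt": r.entry.rt,
            "detected": r.detected,
            "apex_rt": r.apex_rt,
            "posterior": r.posterior,
            "quantifier_mz": r.entry.quantifier.product_mz,
            "quantifier_height": r.quantifier_height,
            "quantifier_area": r.quantifier_area,
            "ms1_height": r.ms1_height,
            "rt_deviation": r.rt_deviation,
            "amplitude_deviation": r.amplitude_deviation,
        })
    return pd.DataFrame(recs)
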