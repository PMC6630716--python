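"""Untargeted spectral-match annotation against the in-silico library.

The match score combines a square-root-weighted dot product over the union of
fragment m/z values, a reverse dot product restricted to library fragments, a
class-diagnostic-ion coverage term, and Gaussian closeness penalties on the
precursor m/z and retention-time deviations.  Every candidate above the
cut-off is enumerated — not only the best hit — which is what later enables
isomer-specific transitions for co-eluted features.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .lipids import LipidSpecies, ReferenceSpectrum
from .msdata import MSRun
from .peaks import PeakFeature

Peak = Tuple[float, float]  # (mz, intensity)

DEFAULT_WEIGHTS = {"dot": 0.4, "reverse": 0.3, "diagnostic": 0.2,
                   "closeness": 0.1}


def _pair_fragments(
    measured: Sequence[Peak], reference: ReferenceSpectrum, ms2_tol: float
) -> List[Tuple[Optional[int], int]]:
    """Greedy nearest-m/z pairing of measured peaks to reference fragments."""
    pairs: List[Tuple[Optional[int], int]] = []
    used: set = set()
    for ri, frag in enumerate(reference.fragments):
        best, best_d = None, ms2_tol
        for mi, (mz, _) in enumerate(measured):
            if mi in used:
                continue
            d = abs(mz - frag.mz)
            if d <= best_d:
                best, best_d = mi, d
        if best is not None:
            used.add(best)
        pairs.append((best, ri))
    return pairs


def match_spectrum(
    measured: Sequence[Peak],
    reference: ReferenceSpectrum,
    ms2_tol: float = 0.05,
) -> Tuple[float, float, float]:
    """Score a measured fragment list against a reference spectrum.

    Returns ``(dot_product, reverse_dot_product, diagnostic_fraction)``.
    The dot product runs over the union of peaks (unpaired peaks contribute
    a zero partner); the reverse variant restricts to reference fragments;
    the diagnostic fraction is the matched share of class-diagnostic ions
    (1.0 when the reference defines none).
    """
    if not measured or not reference.fragments:
        raise ValueError("match_spectrum needs non-empty spectra")
    if ms2_tol <= 0:
        raise ValueError("ms2_tol must be > 0")
    pairs = _pair_fragments(measured, reference, ms2_tol)
    matched_measured = {mi for mi, _ in pairs if mi is not None}

    num = 0.0
    sum_m_matched = 0.0
    for mi, ri in pairs:
        if mi is not None:
            im = measured[mi][1]
            ir = reference.fragments[ri].relative_abundance
            num += math.sqrt(im * ir)
            sum_m_matched += im
    num2 = num * num
    sum_m = sum(i for _, i in measured)
    sum_r = sum(f.relative_abundance for f in reference.fragments)
    dot = 100.0 * num2 / (sum_m * sum_r) if num2 else 0.0
    reverse = 100.0 * num2 / (sum_m_matched * sum_r) if num2 else 0.0

    class_ids = [ri for ri, f in enumerate(reference.fragments)
                 if f.diagnostic == "class"]
    if class_ids:
        hit = sum(1 for mi, ri in pairs if ri in class_ids and mi is not None)
        diag = hit / len(class_ids)
    else:
        diag = 1.0
    return dot, reverse, diag


@dataclass
class AnnotationCandidate:
    """One library spectrum passing the score cut-off for a feature."""

    feature: PeakFeature
    spectrum: ReferenceSpectrum
    precursor_error: float
    rt_error: Optional[float]
    dot_product: float
    reverse_dot_product: float
    diagnostic_fraction: float
    total_score: float
    rank: int = 0

    @property
    def name(self) -> str:
        return self.spectrum.name


def annotate_feature(
    feature: PeakFeature,
    measured: Sequence[Peak],
    library: Sequence[ReferenceSpectrum],
    ms1_tol: float = 0.01,
    ms2_tol: float = 0.05,
    rt_tol: float = 4.0,
    cutoff: float = 70.0,
    weights: Optional[Dict[str, float]] = None,
) -> List[AnnotationCandidate]:
    """Enumerate all library candidates for a feature above the cut-off.

    Candidates are gated on precursor m/z (and retention time when the
    library entry carries one), scored, filtered at ``cutoff``, and returned
    sorted by total score (ties: higher diagnostic fraction, then smaller
    precursor error).
    """
    if not library:
        raise ValueError("empty spectral library")
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    out: List[AnnotationCandidate] = []
    for ref in library:
        dmz = abs(ref.precursor_mz - feature.mz)
        if dmz > ms1_tol:
            continue
        drt = None
        rt_term = 1.0
        if ref.retention_time is not None:
            drt = abs(ref.retention_time - feature.apex_rt)
            if drt > rt_tol:
                continue
            rt_term = math.exp(-((drt / rt_tol) ** 2))
        if not measured:
            continue
        dot, rev, diag = match_spectrum(measured, ref, ms2_tol)
        closeness = 100.0 * math.exp(-((dmz / ms1_tol) ** 2)) * rt_term
        total = (w["dot"] * dot + w["reverse"] * rev
                 + w["diagnostic"] * 100.0 * diag + w["closeness"] * closeness)
        if total >= cutoff:
            out.append(AnnotationCandidate(
                feature=feature, spectrum=ref, precursor_error=dmz,
                rt_error=drt, dot_product=dot, reverse_dot_product=rev,
                diagnostic_fraction=diag, total_score=total))
    out.sort(key=lambda c: (-c.total_score, -c.diagnostic_fraction,
                            c.precursor_error, c.name))
    for i, c in enumerate(out):
        c.rank = i + 1
    return out


def composite_ms2(
    run: MSRun,
    feature: PeakFeature,
    window: Tuple[float, float],
    ms2_tol: float = 0.05,
) -> List[Peak]:
    """DIA MS/MS spectrum for a feature: window scans averaged over the
    feature's RT span, baseline-subtracted (per-channel minimum).

    A simple stand-in for full spectral deconvolution: co-eluted precursors
    in the same window yield a composite spectrum by construction.
    """
    idx = run._index()
    scan_ids = idx.get(round(window[0], 6), [])
    span: List = []
    ms1_times = [run.scans[i].retention_time
                 for i in idx.get(None, [])]
    lo_rt = ms1_times[feature.left_edge]
    hi_rt = ms1_times[feature.right_edge]
    for i in scan_ids:
        s = run.scans[i]
        if lo_rt <= s.retention_time <= hi_rt and len(s.mz):
            span.append(s)
    if not span:
        return []
    allmz = np.concatenate([s.mz for s in span])
    order = np.argsort(allmz)
    allmz = allmz[order]
    breaks = np.flatnonzero(np.diff(allmz) > ms2_tol) + 1
    centers = [float(seg.mean()) for seg in np.split(allmz, breaks)]
    peaks: List[Peak] = []
    for c in centers:
        per_scan = []
        for s in span:
            lo = np.searchsorted(s.mz, c - ms2_tol, side="left")
            hi = np.searchsorted(s.mz, c + ms2_tol, side="right")
            per_scan.append(float(s.intensity[lo:hi].sum()))
        arr = np.asarray(per_scan)
        value = float(arr.mean() - arr.min())
        if value > 0:
            peaks.append((c, value))
    return peaks


def dda_ms2(
    run: MSRun,
    feature: PeakFeature,
    ms1_tol: float = 0.01,
    ms2_tol: float = 0.05,
) -> List[Peak]:
    """DDA MS/MS spectrum for a feature: triggered scans whose selected ion
    matches the feature m/z, averaged over the feature's RT span."""
    idx = run._index()
    ms1_times = [run.scans[i].retention_time for i in idx.get(None, [])]
    lo_rt = ms1_times[feature.left_edge]
    hi_rt = ms1_times[feature.right_edge]
    span = [s for s in run.scans
            if s.ms_level == 2 and s.selected_ion is not None
            and abs(s.selected_ion - feature.mz) <= ms1_tol
            and lo_rt <= s.retention_time <= hi_rt and len(s.mz)]
    if not span:
        return []
    allmz = np.sort(np.concatenate([s.mz for s in span]))
    breaks = np.flatnonzero(np.diff(allmz) > ms2_tol) + 1
    centers = [float(seg.mean()) for seg in np.split(allmz, breaks)]
    peaks: List[Peak] = []
    for c in centers:
        vals = []
        for s in span:
            lo = np.searchsorted(s.mz, c - ms2_tol, side="left")
            hi = np.searchsorted(s.mz, c + ms2_tol, side="right")
            vals.append(float(s.intensity[lo:hi].sum()))
        value = float(np.mean(vals))
        if value > 0:
            peaks.append((c, value))
    return peaks


def feature_ms2(run: MSRun, feature: PeakFeature, ms1_tol: float = 0.01,
                ms2_tol: float = 0.05) -> List[Peak]:
    """The MS/MS spectrum associated with a feature, by acquisition mode."""
    if run.acquisition_mode == "DIA":
        window = run.window_for(feature.mz)
        return composite_ms2(run, feature, window, ms2_tol)
    return dda_ms2(run, feature, ms1_tol, ms2_tol)


def annotate_run(
    run: MSRun,
    library: Sequence[ReferenceSpectrum],
    features: Optional[Sequence[PeakFeature]] = None,
    ms1_tol: float = 0.01,
    ms2_tol: float = 0.05,
    rt_tol: float = 4.0,
    cutoff: float = 70.0,
    mass_slice: float = 0.1,
    smoothing_level: int = 3,
    min_peak_width: int = 5,
    min_peak_height: float = 1000.0,
) -> List[AnnotationCandidate]:
    """Untargeted annotation of a whole run: spot MS1 features, associate an
    MS/MS spectrum with each, and enumerate all passing candidates."""
    from .peaks import find_features

    if features is None:
        features = find_features(run, mass_slice, smoothing_level,
                                 min_peak_width, min_peak_height)
    out: List[AnnotationCandidate] = []
    for f in features:
        try:
            measured = feature_ms2(run, f, ms1_tol, ms2_tol)
        except ValueError:
            continue  # precursor outside window coverage
        if not measured:
            continue
        out.extend(annotate_feature(
            f, measured, library, ms1_tol=ms1_tol, ms2_tol=ms2_tol,
            rt_tol=rt_tol, cutoff=cutoff))
    return out


def acyl_chain_census(
    annotations: Sequence[AnnotationCandidate],
    exclude_classes: frozenset = frozenset({"TAG"}),
) -> Counter:
    """Frequency table of acyl chains over annotated lipids.

    Counts chain occurrences (a chain appearing at two positions counts
    twice) over rank-1 annotations, excluding the given classes — ion
    abundances are deliberately not used, since ionization efficiency is
    class- and retention-time-dependent.
    """
    counts: Counter = Counter()
    for c in annotations:
        if c.rank not in (0, 1):
            continue
        species = c.spectrum.species
        if species is None:
            try:
                species = LipidSpecies.parse(c.spectrum.name.split("/")[0]
                                             if "/" not in c.spectrum.name
                                             else c.spectrum.name.replace(
                                                 "DGTS/DGTA", "DGTS"))
            except ValueError:
                continue
        if species.lipid_class in exclude_classes:
            continue
        for chain in species.chains:
            counts[str(chain)] += 1
    return counts
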