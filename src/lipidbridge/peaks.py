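"""Chromatographic smoothing, peak detection, alignment, blank filtering.

Smoothing is a linear-weighted (triangular) moving average.  The untargeted
defaults follow the workflow conventions of the field: smoothing level 3,
minimum peak width 5 scans, minimum peak height 1000; the targeted stage uses
level 1 / height 200 so that closely co-eluting peaks are not merged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .msdata import Chromatogram, MSRun, extract_xic


def smooth(c: Chromatogram, level: int) -> Chromatogram:
    """Triangular-weighted moving average with half-window = ``level``.

    Window 2*level+1, weights ``level+1-|offset|`` normalized to sum 1.
    Level 0 is the identity; edges use a truncated, renormalized kernel.
    """
    if level < 0:
        raise ValueError("smoothing level must be >= 0")
    if level == 0 or len(c.intensities) == 0:
        return c
    w = np.array([level + 1 - abs(k) for k in range(-level, level + 1)],
                 dtype=float)
    w /= w.sum()
    y = np.convolve(c.intensities, w, mode="same")
    norm = np.convolve(np.ones_like(c.intensities), w, mode="same")
    return Chromatogram(times=c.times, intensities=y / norm,
                        descriptor=dict(c.descriptor, smoothed=level))


@dataclass
class PeakFeature:
    """One detected chromatographic peak."""

    apex_rt: float
    apex_index: int
    left_edge: int
    right_edge: int
    height: float
    area: float
    mz: float
    source: dict = field(default_factory=dict)


def detect_peaks(
    c: Chromatogram,
    min_width_scans: int = 5,
    min_height: float = 1000.0,
    raw: Optional[Chromatogram] = None,
    edge_floor: float = 0.1,
    rel_prominence: float = 0.05,
) -> List[PeakFeature]:
    """Local-maximum peak detection with descent-to-minimum edges.

    Apexes are local maxima of ``c`` (leftmost scan wins on plateaus) whose
    topographic prominence exceeds ``rel_prominence`` of the apex — small
    noise bumps on the flank of a larger peak merge into it.  Edges descend
    to the flanking valleys, passing through sub-prominence bumps and
    stopping early once the trace falls below ``edge_floor`` of the apex
    (keeps edges from creeping along noisy baselines).  Height and area
    (trapezoid) are measured on ``raw`` when given — detect on the smoothed
    trace, quantify on the raw one.  All thresholds except ``min_height``
    are relative, so the feature set is invariant to uniform intensity
    scaling above threshold.
    """
    y = c.intensities
    n = len(y)
    if n == 0:
        return []
    ref = raw.intensities if raw is not None else y
    t = c.times
    mz = c.descriptor.get("target_mz", float("nan"))

    # leftmost points of (possibly flat) local maxima
    maxima: List[int] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1] and y[i] > 0:
            j = i
            while j + 1 < n and y[j + 1] == y[j]:
                j += 1
            if j + 1 >= n or y[j + 1] < y[j]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1

    def prominence(p: int) -> float:
        h = y[p]
        bases = []
        for step in (-1, 1):
            base = h
            q = p + step
            while 0 <= q < n and y[q] <= h:
                base = min(base, y[q])
                q += step
            bases.append(base)
        return h - max(bases)

    kept = [p for p in maxima if prominence(p) >= rel_prominence * y[p]]

    def walk(p: int, step: int) -> int:
        bump = rel_prominence * y[p]
        floor = edge_floor * y[p]
        best = p
        q = p + step
        while 0 <= q < n:
            if y[q] <= y[best]:
                best = q
                if y[q] <= floor:
                    break
            elif y[q] - y[best] > bump:
                break
            q += step
        return best

    feats: List[PeakFeature] = []
    for p in kept:
        left, right = walk(p, -1), walk(p, +1)
        width = right - left + 1
        height = float(ref[left:right + 1].max())
        if width >= min_width_scans and height >= min_height:
            area = float(np.trapezoid(ref[left:right + 1],
                                      t[left:right + 1]))
            apex = left + int(np.argmax(ref[left:right + 1]))
            # apex RT as the intensity-weighted centroid of the detection
            # trace above half-max: much lower jitter than the raw argmax
            seg = y[left:right + 1]
            top = seg >= 0.5 * seg.max()
            apex_rt = float(np.average(t[left:right + 1][top],
                                       weights=seg[top]))
            feats.append(PeakFeature(
                apex_rt=apex_rt, apex_index=apex,
                left_edge=left, right_edge=right,
                height=height, area=area, mz=mz,
                source=dict(c.descriptor),
            ))
    return feats


def find_features(
    run: MSRun,
    mass_slice: float = 0.1,
    smoothing_level: int = 3,
    min_width_scans: int = 5,
    min_height: float = 1000.0,
) -> List[PeakFeature]:
    """MS1 feature spotting: cluster observed m/z values into slices, extract
    an XIC per slice, smooth, and detect peaks."""
    mzs: List[np.ndarray] = []
    wts: List[np.ndarray] = []
    for s in run.scans:
        if s.ms_level == 1 and len(s.mz):
            mzs.append(s.mz)
            wts.append(s.intensity)
    if not mzs:
        return []
    allmz = np.concatenate(mzs)
    allw = np.concatenate(wts)
    order = np.argsort(allmz)
    allmz, allw = allmz[order], allw[order]
    # split sorted m/z values where the gap exceeds half a slice
    breaks = np.flatnonzero(np.diff(allmz) > mass_slice / 2) + 1
    features: List[PeakFeature] = []
    for seg_mz, seg_w in zip(np.split(allmz, breaks), np.split(allw, breaks)):
        center = float(np.average(seg_mz, weights=seg_w)) if seg_w.sum() else \
            float(seg_mz.mean())
        xic = extract_xic(run, center, mass_slice / 2, ms_level=1)
        smoothed = smooth(xic, smoothing_level)
        features.extend(detect_peaks(
            smoothed, min_width_scans, min_height, raw=xic))
    features.sort(key=lambda f: (f.mz, f.apex_rt))
    return features


@dataclass
class AlignmentRow:
    """One aligned feature across samples."""

    mz: float
    rt: float
    heights: Dict[int, float]
    areas: Dict[int, float]
    features: Dict[int, PeakFeature]
    blank_flagged: bool = False


@dataclass
class AlignmentTable:
    rows: List[AlignmentRow]
    n_samples: int
    blank_samples: Tuple[int, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.rows):
            rec = {"id": i, "average_mz": r.mz, "average_rt": r.rt,
                   "blank_flagged": r.blank_flagged}
            for s in range(self.n_samples):
                rec[f"height_{s}"] = r.heights.get(s, np.nan)
                rec[f"area_{s}"] = r.areas.get(s, np.nan)
            recs.append(rec)
        return pd.DataFrame(recs)


def align(
    samples: Sequence[List[PeakFeature]],
    rt_tol: float = 0.05,
    mz_tol: float = 0.015,
) -> AlignmentTable:
    """Greedy centroid clustering of per-sample features.

    Features are pooled, visited in descending height order, and attached to
    the first row within both tolerances; otherwise they seed a new row.
    Missing sample values stay absent (no gap filling).
    """
    if not samples:
        raise ValueError("align requires >= 1 sample")
    pool = [(f.height, si, f) for si, feats in enumerate(samples)
            for f in feats]
    pool.sort(key=lambda x: (-x[0], x[1], x[2].mz))
    rows: List[AlignmentRow] = []
    for _, si, f in pool:
        target = None
        for row in rows:
            if (abs(row.mz - f.mz) <= mz_tol and abs(row.rt - f.apex_rt)
                    <= rt_tol and si not in row.features):
                target = row
                break
        if target is None:
            rows.append(AlignmentRow(
                mz=f.mz, rt=f.apex_rt, heights={si: f.height},
                areas={si: f.area}, features={si: f}))
        else:
            target.features[si] = f
            target.heights[si] = f.height
            target.areas[si] = f.area
            n = len(target.features)
            target.mz += (f.mz - target.mz) / n
            target.rt += (f.apex_rt - target.rt) / n
    rows.sort(key=lambda r: (r.mz, r.rt))
    return AlignmentTable(rows=rows, n_samples=len(samples))


def blank_filter(
    table: AlignmentTable,
    blank_samples: Sequence[int],
    fold: float = 5.0,
) -> AlignmentTable:
    """Flag rows whose max sample height < fold x mean blank height.

    Flagged rows are retained (tagged for checking, not dropped).  Rows with
    zero blank signal are always kept.
    """
    if not blank_samples:
        warnings.warn("no blank samples designated; blank filter is a no-op")
        return table
    blanks = set(blank_samples)
    for row in table.rows:
        blank_vals = [h for s, h in row.heights.items() if s in blanks]
        sample_vals = [h for s, h in row.heights.items() if s not in blanks]
        blank_mean = float(np.mean(blank_vals)) if blank_vals else 0.0
        sample_max = max(sample_vals) if sample_vals else 0.0
        row.blank_flagged = blank_mean > 0 and sample_max < fold * blank_mean
    table.blank_samples = tuple(sorted(blanks))
    return table
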