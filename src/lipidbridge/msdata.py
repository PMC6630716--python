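"""Run model shared by real mzML data and the simulator.

An :class:`MSRun` is a time-ordered list of centroided scans.  DIA (SWATH)
runs repeat a fixed cycle: one MS1 survey scan followed by the same sequence
of wide-isolation-window MS/MS scans.  The default window grid steps 21-Da
windows every 20 Da (1 Da overlap) across m/z 100-1250; ions on an overlap
are assigned to the higher window (half-open interval convention).
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree

_EMPTY = np.array([], dtype=np.float64)
_EMPTY.setflags(write=False)


class MzmlError(ValueError):
    """Raised for malformed or unsupported mzML content."""


@dataclass(frozen=True)
class WindowGrid:
    """SWATH isolation-window layout: [lower, lower+width) every `step` Da."""

    start: float = 100.0
    stop: float = 1250.0
    step: float = 20.0
    width: float = 21.0

    @property
    def lowers(self) -> np.ndarray:
        return np.arange(self.start, self.stop, self.step)

    @property
    def windows(self) -> List[Tuple[float, float]]:
        return [(lo, lo + self.width) for lo in self.lowers]

    def window_for(self, mz: float) -> Tuple[float, float]:
        """The covering window with the greatest lower bound (half-open)."""
        lowers = self.lowers
        inside = (lowers <= mz) & (mz < lowers + self.width)
        if not inside.any():
            raise ValueError(
                f"precursor m/z {mz} outside window coverage "
                f"[{self.start}, {lowers[-1] + self.width})"
            )
        lo = float(lowers[inside].max())
        return (lo, lo + self.width)


@dataclass
class Scan:
    """One centroided scan; MS2 scans carry their isolation window."""

    retention_time: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    isolation_window: Optional[Tuple[float, float]] = None
    selected_ion: Optional[float] = None  # DDA-triggered precursor

    def __post_init__(self) -> None:
        if self.ms_level == 2 and self.isolation_window is None:
            raise MzmlError("MS2 scan requires an isolation window")
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz/intensity length mismatch")


@dataclass
class MSRun:
    """A time-ordered collection of scans plus acquisition metadata."""

    scans: List[Scan]
    polarity: str = "positive"
    acquisition_mode: str = "DIA"  # "DIA" | "DDA"
    window_grid: Optional[WindowGrid] = None
    _window_index: Optional[Dict[Optional[float], List[int]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    def window_for(self, precursor_mz: float) -> Tuple[float, float]:
        if self.acquisition_mode != "DIA":
            raise ValueError("window_for requires a DIA run")
        grid = self.window_grid or WindowGrid()
        return grid.window_for(precursor_mz)

    def _index(self) -> Dict[Optional[float], List[int]]:
        # scan indices keyed by isolation-window lower bound (None = MS1)
        if self._window_index is None:
            idx: Dict[Optional[float], List[int]] = {}
            for i, s in enumerate(self.scans):
                key = None if s.ms_level == 1 else round(s.isolation_window[0], 6)
                idx.setdefault(key, []).append(i)
            self._window_index = idx
        return self._window_index

    def cycle_windows(self) -> List[Tuple[float, float]]:
        """The per-cycle MS2 window sequence (validates cycle integrity)."""
        cycles: List[List[Tuple[float, float]]] = []
        current: Optional[List] = None
        for s in self.scans:
            if s.ms_level == 1:
                if current is not None:
                    cycles.append(current)
                current = []
            elif current is not None:
                current.append(s.isolation_window)
        if current is not None:
            cycles.append(current)
        full = [c for c in cycles[:-1]] or cycles
        if self.acquisition_mode == "DIA" and full:
            first = full[0]
            for c in full[1:]:
                if c != first:
                    raise MzmlError("broken DIA cycle: window sequence varies")
            return first
        return full[0] if full else []


@dataclass
class Chromatogram:
    """Intensity versus retention time at a fixed m/z band."""

    times: np.ndarray
    intensities: np.ndarray
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise ValueError("times/intensities length mismatch")


def extract_xic(
    run: MSRun,
    target_mz: float,
    tol: float,
    ms_level: int = 1,
    window: Optional[Tuple[float, float]] = None,
) -> Chromatogram:
    """Extracted ion chromatogram: per relevant scan, the summed intensity of
    peaks within ``|mz - target_mz| <= tol``.

    For MS2, only scans of the requested isolation window contribute (one
    point per DIA cycle).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    idx = run._index()
    if ms_level == 1:
        scan_ids = idx.get(None, [])
    else:
        if window is None:
            raise ValueError("MS2 XIC requires an isolation window")
        scan_ids = idx.get(round(window[0], 6), [])
    times = np.empty(len(scan_ids))
    vals = np.empty(len(scan_ids))
    for k, i in enumerate(scan_ids):
        s = run.scans[i]
        times[k] = s.retention_time
        if len(s.mz):
            lo = np.searchsorted(s.mz, target_mz - tol, side="left")
            hi = np.searchsorted(s.mz, target_mz + tol, side="right")
            vals[k] = s.intensity[lo:hi].sum()
        else:
            vals[k] = 0.0
    return Chromatogram(
        times=times,
        intensities=vals,
        descriptor={"ms_level": ms_level, "target_mz": target_mz,
                    "tolerance": tol, "isolation_window": window},
    )


# ---------------------------------------------------------------------------
# mzML writing (minimal deterministic mzML 1.1)

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value="", unit=None):
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrib.update({"unitCvRef": "UO", "unitAccession": unit[0],
                       "unitName": unit[1]})
    etree.SubElement(parent, "cvParam", attrib)


def _binary_array(parent, values: np.ndarray, is_mz: bool) -> None:
    data = base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")
    bda = etree.SubElement(parent, "binaryDataArray",
                           {"encodedLength": str(len(data))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    if is_mz:
        _cv(bda, "MS:1000514", "m/z array",
            unit=("MS:1000040", "m/z"))
    else:
        _cv(bda, "MS:1000515", "intensity array",
            unit=("MS:1000131", "number of detector counts"))
    etree.SubElement(bda, "binary").text = data


def write_mzml(run: MSRun, path) -> None:
    """Write a centroided run as minimal mzML 1.1 (deterministic bytes)."""
    root = etree.Element("mzML", nsmap={None: _NS},
                         attrib={"version": "1.1.0"})
    cv_list = etree.SubElement(root, "cvList", {"count": "2"})
    etree.SubElement(cv_list, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass "
        "Spectrometry Ontology", "URI": "https://raw.githubusercontent.com/"
        "HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    etree.SubElement(cv_list, "cv", {
        "id": "UO", "fullName": "Unit Ontology", "URI":
        "https://raw.githubusercontent.com/bio-ontology-research-group/"
        "unit-ontology/master/unit.obo"})
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000580", "MSn spectrum")
    softs = etree.SubElement(root, "softwareList", {"count": "1"})
    etree.SubElement(softs, "software", {"id": "lipidbridge", "version": "0"})
    icl = etree.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    etree.SubElement(icl, "instrumentConfiguration", {"id": "IC1"})
    dpl = etree.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = etree.SubElement(dpl, "dataProcessing", {"id": "DP1"})
    pm = etree.SubElement(dp, "processingMethod",
                          {"order": "1", "softwareRef": "lipidbridge"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mode_acc, mode_name = (
        ("MS:1000130", "positive scan") if run.polarity == "positive"
        else ("MS:1000129", "negative scan"))
    srun = etree.SubElement(root, "run", {
        "id": "run1", "defaultInstrumentConfigurationRef": "IC1"})
    slist = etree.SubElement(srun, "spectrumList", {
        "count": str(len(run.scans)), "defaultDataProcessingRef": "DP1"})
    for i, scan in enumerate(run.scans):
        sp = etree.SubElement(slist, "spectrum", {
            "index": str(i), "id": f"scan={i + 1}",
            "defaultArrayLength": str(len(scan.mz))})
        _cv(sp, "MS:1000511", "ms level", str(scan.ms_level))
        _cv(sp, "MS:1000579" if scan.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if scan.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, mode_acc, mode_name)
        sl = etree.SubElement(sp, "scanList", {"count": "1"})
        _cv(sl, "MS:1000795", "no combination")
        sc = etree.SubElement(sl, "scan")
        _cv(sc, "MS:1000016", "scan start time",
            repr(float(scan.retention_time)), unit=("UO:0000031", "minute"))
        if scan.ms_level == 2:
            lo, hi = (float(v) for v in scan.isolation_window)
            target = 0.5 * (lo + hi)
            pl = etree.SubElement(sp, "precursorList", {"count": "1"})
            pr = etree.SubElement(pl, "precursor")
            iw = etree.SubElement(pr, "isolationWindow")
            _cv(iw, "MS:1000827", "isolation window target m/z",
                repr(target), unit=("MS:1000040", "m/z"))
            _cv(iw, "MS:1000828", "isolation window lower offset",
                repr(target - lo), unit=("MS:1000040", "m/z"))
            _cv(iw, "MS:1000829", "isolation window upper offset",
                repr(hi - target), unit=("MS:1000040", "m/z"))
            if scan.selected_ion is not None:
                sil = etree.SubElement(pr, "selectedIonList", {"count": "1"})
                si = etree.SubElement(sil, "selectedIon")
                _cv(si, "MS:1000744", "selected ion m/z",
                    repr(float(scan.selected_ion)), unit=("MS:1000040", "m/z"))
        bal = etree.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(bal, scan.mz, is_mz=True)
        _binary_array(bal, scan.intensity, is_mz=False)

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    text = ""
    for child in bda:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem) -> Scan:
    ms_level = 1
    rt = 0.0
    window = None
    selected = None
    negative = False
    mz = intensity = None
    for node in elem.iter():
        name = _local(node.tag)
        if name == "cvParam":
            acc = node.get("accession")
            if acc == "MS:1000511":
                ms_level = int(node.get("value"))
            elif acc == "MS:1000128":
                raise MzmlError(
                    "profile-mode spectrum found; centroid the data first")
            elif acc == "MS:1000129":
                negative = True
            elif acc == "MS:1000016":
                rt = float(node.get("value"))
                if node.get("unitName") == "second":
                    rt /= 60.0
            elif acc == "MS:1000744":
                selected = float(node.get("value"))
    for node in elem.iter():
        if _local(node.tag) == "isolationWindow":
            target = lo_off = hi_off = None
            for cv in node:
                acc = cv.get("accession")
                if acc == "MS:1000827":
                    target = float(cv.get("value"))
                elif acc == "MS:1000828":
                    lo_off = float(cv.get("value"))
                elif acc == "MS:1000829":
                    hi_off = float(cv.get("value"))
            if target is not None and lo_off is not None and hi_off is not None:
                window = (target - lo_off, target + hi_off)
    for node in elem.iter():
        if _local(node.tag) == "binaryDataArray":
            kind = None
            for cv in node:
                if _local(cv.tag) == "cvParam":
                    if cv.get("accession") == "MS:1000514":
                        kind = "mz"
                    elif cv.get("accession") == "MS:1000515":
                        kind = "intensity"
            values = _decode_binary(node)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
    if mz is None or intensity is None:
        raise MzmlError("spectrum without m/z or intensity array")
    if ms_level >= 2 and window is None:
        raise MzmlError("MS2 scan without isolation window metadata")
    scan = Scan(retention_time=rt, ms_level=ms_level, mz=mz,
                intensity=intensity,
                isolation_window=window if ms_level >= 2 else None,
                selected_ion=selected)
    scan._negative = negative  # transient polarity hint
    return scan


def read_mzml(path) -> MSRun:
    """Read a centroided mzML file into an :class:`MSRun`.

    Namespace-agnostic cvParam-accession parsing (64/32-bit floats, zlib or
    uncompressed).  Errors on profile-mode spectra and on MS2 scans without
    isolation-window metadata.  Acquisition mode is DDA when MS2 scans carry
    a selected-ion record, DIA otherwise.
    """
    scans: List[Scan] = []
    polarity = "positive"
    any_selected = False
    for _, elem in etree.iterparse(str(path), events=("end",),
                                   tag=f"{{{_NS}}}spectrum"):
        scan = _parse_spectrum(elem)
        if getattr(scan, "_negative", False):
            polarity = "negative"
        if scan.selected_ion is not None:
            any_selected = True
        scans.append(scan)
        elem.clear()
    if not scans:
        raise MzmlError("empty run: no spectra found")
    mode = "DDA" if any_selected else "DIA"
    return MSRun(scans=scans, polarity=polarity, acquisition_mode=mode)
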