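"""Centroided two-event LC-MS runs: mzML I/O and extracted ion chromatograms.

A run alternates two scan events at a 1 Hz overall rate: event 1 is an
ordinary full scan, event 2 an all-ion-fragmentation (HCD) scan of the same
m/z range with no precursor selection.  mzML has no native concept of an
"alternating event", so event 2 is written and read as an MS-level-2 scan;
event 1 as MS level 1.  Times are minutes everywhere in this package.

The mzML layer is intentionally small: it writes standards-conformant
centroid mzML (64-bit float arrays, optional zlib compression) and reads
centroid mzML with the usual encodings via lxml.  Profile-mode input is
rejected because the whole screening chain assumes centroided peaks.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree

__all__ = [
    "CentroidSpectrum",
    "RunMetadata",
    "Run",
    "EIC",
    "read_run",
    "write_run",
    "extract_eic",
    "eic_to_tsv",
]

_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class CentroidSpectrum:
    """One centroided scan: time (minutes), event (1 or 2), peak arrays."""

    time_min: float
    event: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.event not in (1, 2):
            raise ValueError("event must be 1 or 2")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RunMetadata:
    run_id: str = "run"
    matrix: str = ""
    resolving_power: float = 50000.0
    scan_range: Tuple[float, float] = (55.0, 1000.0)
    scan_period_s: float = 1.0
    extra: Dict[str, object] = field(default_factory=dict)


@dataclass
class Run:
    """Ordered centroid spectra plus acquisition metadata.

    Scan times must be non-decreasing; when both events are present they
    must strictly alternate 1,2,1,2,...
    """

    spectra: List[CentroidSpectrum]
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self):
        if not self.spectra:
            raise ValueError("empty run")
        times = [s.time_min for s in self.spectra]
        if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
            raise ValueError("scan times must be non-decreasing")
        events = {s.event for s in self.spectra}
        if events == {1, 2}:
            for a, b in zip(self.spectra, self.spectra[1:]):
                if b.event == a.event:
                    raise ValueError("events must alternate 1,2,1,2,...")
        lo, hi = self.metadata.scan_range
        for s in self.spectra:
            if s.mz.size and (s.mz[0] < lo - 1e-6 or s.mz[-1] > hi + 1e-6):
                raise ValueError("centroid m/z outside configured scan range")

    @property
    def events(self) -> set:
        return {s.event for s in self.spectra}

    @property
    def single_event(self) -> bool:
        return len(self.events) == 1

    def spectra_of_event(self, event: int) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.event == event]


@dataclass
class EIC:
    """Extracted ion chromatogram for one target m/z, tolerance, and event.

    ``intensity[i]`` is the sum of centroid intensities within the window in
    the i-th spectrum of the event; ``mz_observed[i]`` the intensity-weighted
    mean m/z of those centroids (NaN where the window is empty).
    """

    target_mz: float
    ppm: float
    event: int
    time_min: np.ndarray
    intensity: np.ndarray
    mz_observed: np.ndarray

    def __len__(self) -> int:
        return self.time_min.size


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _spectrum_xml(index: int, s: CentroidSpectrum) -> str:
    mz_b64 = _encode_array(s.mz)
    int_b64 = _encode_array(s.intensity)
    level = 1 if s.event == 1 else 2
    kind = (
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        if level == 1
        else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
    )
    return f"""      <spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
        {kind}
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.time_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""


def write_run(run: Run, path) -> None:
    """Write a Run as centroid mzML.

    Run-level metadata (run id, matrix label, resolving power, scan range,
    scan period) travels as a JSON userParam in the fileContent element and
    survives a round-trip through :func:`read_run`.
    """
    md = run.metadata
    meta_json = json.dumps(
        {
            "run_id": md.run_id,
            "matrix": md.matrix,
            "resolving_power": md.resolving_power,
            "scan_range": list(md.scan_range),
            "scan_period_s": md.scan_period_s,
            "extra": md.extra,
        }
    )
    meta_attr = meta_json.replace("&", "&amp;").replace('"', "&quot;").replace("<", "&lt;")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="{_NS}" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
      <userParam name="hrmscreen:run_metadata" value="{meta_attr}"/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="hrmscreen" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="hrmscreen"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="hrmscreen">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{md.run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="DP1">
"""
        )
        for i, s in enumerate(run.spectra):
            fh.write(_spectrum_xml(i, s))
        fh.write("""    </spectrumList>
  </run>
</mzML>
""")


def _decode_binary(bda: etree._Element) -> Tuple[str, np.ndarray]:
    dtype = None
    compressed = False
    kind = None
    text = ""
    for child in bda:
        tag = etree.QName(child).localname
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    if dtype is None:
        raise ValueError("binary array without a float-type cvParam")
    return kind or "", np.frombuffer(raw, dtype=dtype).astype(float)


def read_run(path) -> Run:
    """Read a centroid mzML file written by :func:`write_run` (or any
    centroid mzML using 32/64-bit float arrays with zlib or no compression).

    Raises on profile-mode spectra, an empty spectrum list, or non-monotone
    scan times.  A file containing only one scan event yields a Run whose
    ``single_event`` flag is set; fragment-based screening refuses such runs.
    """
    spectra: List[CentroidSpectrum] = []
    metadata = RunMetadata()
    for _, elem in etree.iterparse(str(path), events=("end",), tag=(f"{{{_NS}}}spectrum", f"{{{_NS}}}userParam")):
        tag = etree.QName(elem).localname
        if tag == "userParam":
            if elem.get("name") == "hrmscreen:run_metadata":
                d = json.loads(elem.get("value", "{}"))
                metadata = RunMetadata(
                    run_id=d.get("run_id", "run"),
                    matrix=d.get("matrix", ""),
                    resolving_power=d.get("resolving_power", 50000.0),
                    scan_range=tuple(d.get("scan_range", (55.0, 1000.0))),
                    scan_period_s=d.get("scan_period_s", 1.0),
                    extra=d.get("extra", {}),
                )
            continue
        level = 1
        time_min: Optional[float] = None
        arrays: Dict[str, np.ndarray] = {}
        for cv in elem.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession", "")
            if acc == "MS:1000511":
                level = int(cv.get("value", "1"))
            elif acc == "MS:1000128":
                raise ValueError("profile-mode spectrum: centroided data required")
            elif acc == "MS:1000016":
                t = float(cv.get("value", "nan"))
                unit = (cv.get("unitName") or "").lower()
                time_min = t / 60.0 if unit.startswith("sec") else t
        for bda in elem.iter(f"{{{_NS}}}binaryDataArray"):
            kind, values = _decode_binary(bda)
            if kind:
                arrays[kind] = values
        if time_min is None:
            raise ValueError("spectrum without a scan start time")
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError("spectrum missing m/z or intensity array")
        spectra.append(
            CentroidSpectrum(
                time_min=time_min,
                event=1 if level == 1 else 2,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
            )
        )
        elem.clear()
        while elem.getprevious() is not None:
            del elem.getparent()[0]
    if not spectra:
        raise ValueError("empty run")
    return Run(spectra=spectra, metadata=metadata)


def extract_eic(run: Run, mz: float, ppm: float = 5.0, event: int = 1) -> EIC:
    """Extracted ion chromatogram: per spectrum of the chosen event, the sum
    of centroid intensities with ``|obs - mz| / mz * 1e6 <= ppm``.

    The window is symmetric and multiplicative around the *theoretical* mass,
    matching screening against database masses.  One trace point is produced
    per spectrum of the event.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    lo_range, hi_range = run.metadata.scan_range
    if not (lo_range <= mz <= hi_range):
        raise ValueError(f"target m/z {mz} outside scan range {run.metadata.scan_range}")
    specs = run.spectra_of_event(event)
    if not specs:
        raise ValueError(f"run has no event-{event} spectra")
    half = mz * ppm * 1e-6
    lo, hi = mz - half, mz + half
    times = np.empty(len(specs))
    total = np.zeros(len(specs))
    mz_obs = np.full(len(specs), np.nan)
    for i, s in enumerate(specs):
        times[i] = s.time_min
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        if b > a:
            inten = s.intensity[a:b]
            total[i] = inten.sum()
            if total[i] > 0:
                mz_obs[i] = float(np.average(s.mz[a:b], weights=inten))
    return EIC(target_mz=mz, ppm=ppm, event=event, time_min=times, intensity=total, mz_observed=mz_obs)


def eic_to_tsv(eic: EIC, path) -> None:
    """Flat TSV export of a trace (time_min, intensity)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_min\tintensity\n")
        for t, y in zip(eic.time_min, eic.intensity):
            fh.write(f"{t:.6f}\t{y:.6f}\n")
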