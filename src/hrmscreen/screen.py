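"""Database-driven analyte detection from two-event LC-HRMS runs.

Three screening strategies are provided, mirroring how routine labs post-
process full-scan data:

* one-ion screening, either "max-scan" (report the most intense in-window
  scan of the primary ion, no chromatographic-peak requirement — the mode
  that produces the notorious false-positive load) or "peak" mode (the
  primary ion must form a chromatographic peak of at least three consecutive
  above-baseline scans, so single-scan spikes are rejected);
* response thresholding on top of one-ion hits, with either a fixed global
  cutoff or per-analyte thresholds derived from spiked reference runs; and
* two-ion screening, requiring the primary ion (event 1) and a secondary
  diagnostic ion — an isotope (event 1) or a fragment (event 2) — to peak
  within 0.05 min of each other.

Screening tolerances default to +/-5 ppm on mass and +/-0.5 min on retention
time.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import chem
from .chem import ADDUCTS, AdductSpec, Formula
from .msdata import EIC, Run, extract_eic

__all__ = [
    "DbEntry",
    "ScreenConfig",
    "PeakDetection",
    "ScreenHit",
    "read_db_csv",
    "write_db_csv",
    "detect_peaks",
    "screen_max_scan",
    "screen_one_ion",
    "screen_two_ion",
    "apply_threshold",
    "compute_individual_thresholds",
    "screen_batch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DbEntry:
    """One screening-database row.

    ``secondary_kind`` is ``"isotope"`` (value: a shift label like "M+1" or
    "M+2", measured in scan event 1) or ``"fragment"`` (value: the fragment
    cation formula, measured in scan event 2).
    """

    name: str
    rt_min: float
    formula: Formula
    adduct: AdductSpec
    secondary_kind: str
    secondary_value: str
    threshold: Optional[float] = None

    def __post_init__(self):
        if self.rt_min <= 0:
            raise ValueError(f"{self.name}: retention time must be > 0")
        if self.secondary_kind not in ("isotope", "fragment"):
            raise ValueError(f"{self.name}: secondary_kind must be isotope|fragment")
        self.secondary_mz()  # must resolve

    def primary_mz(self) -> float:
        return chem.ion_mz(self.formula, self.adduct)

    def secondary_mz(self) -> float:
        if self.secondary_kind == "isotope":
            shift = _parse_shift(self.secondary_value)
            return chem.isotope_ion_mz(self.formula, self.adduct, shift)
        frag = chem.parse_formula(self.secondary_value)
        return chem.ion_mz(frag, ADDUCTS["[frag]+"])

    @property
    def secondary_event(self) -> int:
        return 1 if self.secondary_kind == "isotope" else 2


def _parse_shift(label: str) -> int:
    s = label.strip().upper().replace(" ", "")
    if s.startswith("M+"):
        return int(s[2:])
    raise ValueError(f"cannot parse isotope shift label {label!r}")


@dataclass(frozen=True)
class ScreenConfig:
    """Tolerances and modes for screening.

    ``mode`` selects how the primary ion is detected ("max_scan" or "peak");
    two-ion screening always uses peak detection for both ions.
    ``min_height`` is the instrument noise floor below which a trace point
    does not count as signal.
    """

    ppm: float = 5.0
    rt_window_min: float = 0.5
    delta_rt_max_min: float = 0.05
    mode: str = "peak"
    threshold_mode: str = "none"  # none | fixed | individual
    fixed_threshold: float = 0.0
    min_scans: int = 3
    smooth_points: int = 3
    min_height: float = 100.0

    def __post_init__(self):
        if self.ppm <= 0 or self.rt_window_min <= 0 or self.delta_rt_max_min <= 0:
            raise ValueError("tolerances must be positive")
        if self.mode not in ("max_scan", "peak"):
            raise ValueError("mode must be max_scan|peak")


@dataclass
class PeakDetection:
    """One detected chromatographic peak (or max-scan report) for one ion."""

    role: str  # primary | secondary
    rt_min: float
    area: float
    height: float
    mz_observed: float
    mass_error_ppm: float


@dataclass
class ScreenHit:
    """Detection outcome for one analyte in one run."""

    analyte: str
    primary: PeakDetection
    secondary: Optional[PeakDetection] = None
    delta_rt_min: Optional[float] = None

    @property
    def response(self) -> float:
        return self.primary.area if self.primary.area > 0 else self.primary.height


# ---------------------------------------------------------------------------
# database CSV I/O


def read_db_csv(path) -> List[DbEntry]:
    """Read the screening database CSV (columns: name, rt_min, formula,
    adduct, secondary_kind, secondary_value, threshold[optional])."""
    entries: List[DbEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                thr = row.get("threshold", "")
                entries.append(
                    DbEntry(
                        name=row["name"],
                        rt_min=float(row["rt_min"]),
                        formula=chem.parse_formula(row["formula"]),
                        adduct=ADDUCTS[row["adduct"]],
                        secondary_kind=row["secondary_kind"],
                        secondary_value=row["secondary_value"],
                        threshold=float(thr) if thr not in ("", None) else None,
                    )
                )
            except Exception as exc:
                raise ValueError(f"malformed database row at line {i}: {exc}") from exc
    return entries


def write_db_csv(entries: Sequence[DbEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "rt_min", "formula", "adduct", "secondary_kind", "secondary_value", "threshold"])
        for e in entries:
            w.writerow(
                [
                    e.name,
                    f"{e.rt_min:.2f}",
                    chem.formula_to_string(e.formula),
                    e.adduct.label,
                    e.secondary_kind,
                    e.secondary_value,
                    "" if e.threshold is None else repr(e.threshold),
                ]
            )


# ---------------------------------------------------------------------------
# peak detection


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or y.size < width:
        return y.astype(float)
    return pd.Series(y).rolling(width, center=True, min_periods=1).mean().to_numpy()


def detect_peaks(eic: EIC, window: Tuple[float, float], config: ScreenConfig = ScreenConfig()) -> List[PeakDetection]:
    """Chromatographic peaks of an extracted ion trace within an RT window.

    A peak needs at least ``config.min_scans`` consecutive raw trace points
    above the local baseline (lower quartile of the smoothed in-window
    trace) and above the noise floor, so a single isolated scan — a spike
    rather than a chromatographic peak — is never reported.  Regions
    containing several local maxima of sufficient prominence (half the
    noise floor) are split at the interior minima, so a shoulder peak next
    to a larger co-eluting one is still resolved.  Area is the trapezoidal
    integral (intensity x minutes) over the peak bounds.
    """
    t0, t1 = window
    mask = (eic.time_min >= t0) & (eic.time_min <= t1)
    if not mask.any():
        return []
    t = eic.time_min[mask]
    y = eic.intensity[mask]
    mzo = eic.mz_observed[mask]
    smooth = _moving_average(y, config.smooth_points)
    baseline = float(np.percentile(smooth, 25))
    floor = max(baseline, config.min_height)
    above = y > floor
    peaks: List[PeakDetection] = []
    i = 0
    n = y.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= config.min_scans:
            peaks.extend(_split_region(t, y, mzo, i, j, eic.target_mz, config))
        i = j
    return peaks


def _split_region(t, y, mzo, i, j, target_mz, config: ScreenConfig) -> List[PeakDetection]:
    """Split one above-baseline region [i, j) at interior minima and emit one
    detection per local maximum of sufficient prominence."""
    seg = y[i:j]
    maxima = list(find_peaks(seg, prominence=0.5 * config.min_height)[0])
    if not maxima:
        maxima = [int(np.argmax(seg))]
    else:
        top = int(np.argmax(seg))
        if top not in maxima:  # the region apex may sit at the segment edge
            maxima = sorted(maxima + [top])
    bounds = [0]
    for a, b in zip(maxima, maxima[1:]):
        bounds.append(a + int(np.argmin(seg[a : b + 1])))
    bounds.append(len(seg))
    out = []
    for a, b, m in zip(bounds, bounds[1:], maxima):
        lo = i + a
        hi = i + b  # exclusive
        # extend one point each side toward baseline for integration
        ilo = max(lo - 1, 0)
        ihi = min(hi + 1, y.size)
        apex_rel = lo + int(np.argmax(y[lo:hi])) if hi > lo else i + m
        area = float(np.trapezoid(y[ilo:ihi], t[ilo:ihi]))
        obs = mzo[apex_rel]
        if not np.isfinite(obs):
            finite = np.isfinite(mzo[lo:hi])
            obs = float(np.average(mzo[lo:hi][finite])) if finite.any() else float("nan")
        err = (obs - target_mz) / target_mz * 1e6 if np.isfinite(obs) else float("nan")
        out.append(
            PeakDetection(
                role="",
                rt_min=float(t[apex_rel]),
                area=area,
                height=float(y[apex_rel]),
                mz_observed=float(obs),
                mass_error_ppm=float(err),
            )
        )
    return out


# ---------------------------------------------------------------------------
# screening strategies


def _window(entry: DbEntry, config: ScreenConfig) -> Tuple[float, float]:
    return (entry.rt_min - config.rt_window_min, entry.rt_min + config.rt_window_min)


def screen_max_scan(run: Run, entry: DbEntry, config: ScreenConfig) -> Optional[ScreenHit]:
    """One-ion screening without peak detection: report the scan with the
    highest in-window intensity of the primary ion (if any is nonzero).

    This intentionally reproduces the behaviour of naive max-scan screening:
    a single isolated spike in the window is reported as a hit.
    """
    eic = extract_eic(run, entry.primary_mz(), config.ppm, event=1)
    t0, t1 = _window(entry, config)
    mask = (eic.time_min >= t0) & (eic.time_min <= t1)
    if not mask.any():
        return None
    y = eic.intensity[mask]
    if y.max() <= 0:
        return None
    k = int(np.argmax(y))  # first-in-time on ties
    t = eic.time_min[mask][k]
    obs = eic.mz_observed[mask][k]
    err = (obs - eic.target_mz) / eic.target_mz * 1e6 if np.isfinite(obs) else float("nan")
    det = PeakDetection("primary", float(t), area=0.0, height=float(y[k]), mz_observed=float(obs), mass_error_ppm=float(err))
    return ScreenHit(analyte=entry.name, primary=det)


def screen_one_ion(run: Run, entry: DbEntry, config: ScreenConfig) -> Optional[ScreenHit]:
    """One-ion screening in the configured mode (max-scan or peak)."""
    if config.mode == "max_scan":
        return screen_max_scan(run, entry, config)
    eic = extract_eic(run, entry.primary_mz(), config.ppm, event=1)
    peaks = detect_peaks(eic, _window(entry, config), config)
    if not peaks:
        return None
    best = max(peaks, key=lambda p: p.area)
    best.role = "primary"
    return ScreenHit(analyte=entry.name, primary=best)


def screen_two_ion(run: Run, entry: DbEntry, config: ScreenConfig) -> Optional[ScreenHit]:
    """Two-ion screening: primary peak in event 1 and secondary diagnostic
    ion peak in its designated event (isotope: event 1; fragment: event 2),
    with apex retention times within ``config.delta_rt_max_min``.

    Among all primary/secondary peak pairings the one minimising the apex RT
    difference is chosen.
    """
    if entry.secondary_event == 2 and 2 not in run.events:
        raise ValueError(
            f"{entry.name}: fragment secondary ion requires an event-2 scan, "
            "but the run contains only one scan event"
        )
    window = _window(entry, config)
    eic1 = extract_eic(run, entry.primary_mz(), config.ppm, event=1)
    primary_peaks = detect_peaks(eic1, window, config)
    if not primary_peaks:
        return None
    eic2 = extract_eic(run, entry.secondary_mz(), config.ppm, event=entry.secondary_event)
    secondary_peaks = detect_peaks(eic2, window, config)
    if not secondary_peaks:
        return None
    best: Optional[Tuple[float, PeakDetection, PeakDetection]] = None
    for p in primary_peaks:
        for s in secondary_peaks:
            d = abs(p.rt_min - s.rt_min)
            if best is None or d < best[0]:
                best = (d, p, s)
    assert best is not None
    d, p, s = best
    if d > config.delta_rt_max_min:
        return None
    p.role, s.role = "primary", "secondary"
    return ScreenHit(analyte=entry.name, primary=p, secondary=s, delta_rt_min=d)


def compute_individual_thresholds(
    runs: Sequence[Run], db: Sequence[DbEntry], config: ScreenConfig
) -> Dict[str, float]:
    """Per-analyte response thresholds from a set of spiked reference runs at
    one level: half the lowest response observed in any matrix.

    Analytes never detected in any reference run get no threshold and are
    flagged with a warning.
    """
    responses: Dict[str, List[float]] = {e.name: [] for e in db}
    one_ion_cfg = replace(config, mode="peak")
    for run in runs:
        for entry in db:
            hit = screen_one_ion(run, entry, one_ion_cfg)
            if hit is not None:
                responses[entry.name].append(hit.response)
    out: Dict[str, float] = {}
    for name, vals in responses.items():
        if vals:
            out[name] = 0.5 * min(vals)
        else:
            log.warning("no reference response for %s: excluded from individual thresholding", name)
    return out


def apply_threshold(
    hits: Sequence[ScreenHit],
    config: ScreenConfig,
    individual: Optional[Mapping[str, float]] = None,
) -> List[ScreenHit]:
    """Filter hits by response threshold (strictly greater-than).

    ``threshold_mode="fixed"`` uses ``config.fixed_threshold`` for every
    analyte; ``"individual"`` uses the per-analyte map (hits for analytes
    without a threshold are dropped with a warning); ``"none"`` keeps all.
    """
    if config.threshold_mode == "none":
        return list(hits)
    out = []
    for h in hits:
        if config.threshold_mode == "fixed":
            thr = config.fixed_threshold
        elif config.threshold_mode == "individual":
            if individual is None or h.analyte not in individual:
                log.warning("no individual threshold for %s: hit dropped", h.analyte)
                continue
            thr = individual[h.analyte]
        else:
            raise ValueError(f"unknown threshold mode {config.threshold_mode!r}")
        if h.response > thr:
            out.append(h)
    return out


def screen_batch(
    runs: Sequence[Run],
    db: Sequence[DbEntry],
    config: ScreenConfig,
    strategy: str = "two-ion",
    individual_thresholds: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Screen every analyte in every run with one strategy.

    ``strategy`` is one of ``one-ion``, ``threshold-fixed``,
    ``threshold-individual``, ``two-ion``.  Returns one row per analyte x
    run (deterministic ordering) with detection outcome, detected RT, mass
    error, responses, and the RT difference between the two diagnostic ions
    where applicable.
    """
    rows = []
    for run in runs:
        hits: Dict[str, ScreenHit] = {}
        raw: List[ScreenHit] = []
        for entry in db:
            if strategy == "two-ion":
                hit = screen_two_ion(run, entry, config)
            else:
                hit = screen_one_ion(run, entry, config)
            if hit is not None:
                raw.append(hit)
        if strategy == "threshold-fixed":
            cfg = replace(config, threshold_mode="fixed")
            raw = apply_threshold(raw, cfg)
        elif strategy == "threshold-individual":
            cfg = replace(config, threshold_mode="individual")
            raw = apply_threshold(raw, cfg, individual=individual_thresholds)
        elif strategy not in ("one-ion", "two-ion"):
            raise ValueError(f"unknown strategy {strategy!r}")
        hits = {h.analyte: h for h in raw}
        for entry in db:
            h = hits.get(entry.name)
            rows.append(
                {
                    "analyte": entry.name,
                    "run": run.metadata.run_id,
                    "matrix": run.metadata.matrix,
                    "level": run.metadata.extra.get("level", float("nan")),
                    "expected_rt": entry.rt_min,
                    "detected": h is not None,
                    "detected_rt": h.primary.rt_min if h else float("nan"),
                    "mass_error_ppm": h.primary.mass_error_ppm if h else float("nan"),
                    "response_primary": h.response if h else float("nan"),
                    "response_secondary": (h.secondary.area if h and h.secondary else float("nan")),
                    "delta_rt": (h.delta_rt_min if h and h.delta_rt_min is not None else float("nan")),
                    "secondary_kind": entry.secondary_kind,
                }
            )
    return pd.DataFrame(rows)
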