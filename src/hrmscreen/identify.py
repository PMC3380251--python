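"""Identification layer on top of two-ion screening.

Identification of a detected analyte by single-stage HRMS requires at least
two diagnostic ions including at least one fragment ion, mass accuracy
within 5 ppm, an ion ratio (fragment area from the fragmentation event over
precursor area from the unfragmented event) compliant with a tolerance
scheme, and a retention-time criterion expressed as the relative retention
time (RRT) against an internal reference compound.

Two ion-ratio tolerance schemes are implemented:

* the EU tiered scheme, where the relative tolerance depends on the
  *reference* ratio expressed in percent — (50, inf] -> 20 %,
  (20, 50] -> 25 %, (10, 20] -> 30 %, (0, 10] -> 50 % (boundaries fall to
  the wider tolerance); and
* a generic flat +/-50 % tolerance, independent of the relative intensity.

Ratios above 1 (fragment more intense than precursor, which does occur) are
accepted and fall in the >50 % tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

from .screen import DbEntry, ScreenConfig, ScreenHit, screen_two_ion

__all__ = [
    "IonRatio",
    "RatioToleranceScheme",
    "EU_TIERED",
    "GENERIC_50",
    "IdentificationResult",
    "tolerance_for_ratio",
    "check_ion_ratio",
    "rrt_deviation",
    "identify",
    "identify_batch",
]

#: RRT pass criteria in percent: the established 2.5 % and the stricter 1.0 %.
RRT_TOLERANCE_DEFAULT = 2.5
RRT_TOLERANCE_STRICT = 1.0

MASS_ACCURACY_PPM = 5.0


@dataclass(frozen=True)
class IonRatio:
    """Fragment/precursor area ratio with its reference value.

    ``value`` = fragment area (event 2) / precursor area (event 1);
    ``reference`` has the same semantics, from solvent standards or a matrix
    average (``source`` records which).
    """

    value: float
    reference: float
    source: str = "solvent"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("ion ratio must be >= 0")


@dataclass(frozen=True)
class RatioToleranceScheme:
    """Tolerance scheme kind: ``eu`` (tiered) or ``generic`` (flat 50 %)."""

    kind: str

    def __post_init__(self):
        if self.kind not in ("eu", "generic"):
            raise ValueError("scheme kind must be eu|generic")


EU_TIERED = RatioToleranceScheme("eu")
GENERIC_50 = RatioToleranceScheme("generic")

# (lower bound exclusive on reference ratio in percent, relative tolerance)
_EU_TIERS = ((50.0, 0.20), (20.0, 0.25), (10.0, 0.30), (0.0, 0.50))


def tolerance_for_ratio(reference: float, scheme: RatioToleranceScheme) -> float:
    """Relative ion-ratio tolerance (fraction) for a given reference ratio.

    The tier is decided by the reference ratio, expressed in percent; exact
    tier boundaries get the wider tolerance (a reference of exactly 10 %
    gets +/-50 %).
    """
    if reference <= 0:
        raise ValueError("reference ratio must be positive")
    if scheme.kind == "generic":
        return 0.50
    pct = reference * 100.0
    for lower, tol in _EU_TIERS:
        if pct > lower:
            return tol
    raise AssertionError("unreachable")


def check_ion_ratio(observed: Optional[IonRatio], scheme: RatioToleranceScheme) -> bool:
    """Ion-ratio compliance: |observed - reference| / reference <= tolerance.

    ``observed=None`` (no fragment peak) fails.  The check is invariant to a
    common rescaling of both areas since only the ratio enters.
    """
    if observed is None:
        return False
    tol = tolerance_for_ratio(observed.reference, scheme)
    return abs(observed.value - observed.reference) / observed.reference <= tol


def rrt_deviation(
    rt_analyte: float, rt_reference: float, rt_analyte_expected: float, rt_reference_expected: float
) -> float:
    """Percent deviation of the observed relative retention time from the
    expected one: 100 * |RRT_obs - RRT_exp| / RRT_exp with RRT = RT_analyte
    / RT_reference."""
    if min(rt_analyte, rt_reference, rt_analyte_expected, rt_reference_expected) <= 0:
        raise ValueError("retention times must be positive")
    rrt_obs = rt_analyte / rt_reference
    rrt_exp = rt_analyte_expected / rt_reference_expected
    return 100.0 * abs(rrt_obs - rrt_exp) / rrt_exp


@dataclass
class IdentificationResult:
    """Outcome of applying the identification criteria to one detection."""

    analyte: str
    detected: bool
    identified: bool
    ratio: Optional[float]
    reference: Optional[float]
    tolerance: Optional[float]
    ratio_pass: bool
    mass_accuracy_pass: bool
    fragment_present: bool
    rrt_deviation_pct: Optional[float]
    rrt_pass: bool
    failure_reason: str = ""


def identify(
    hit: Optional[ScreenHit],
    reference_ratio: Optional[float],
    scheme: RatioToleranceScheme = EU_TIERED,
    secondary_kind: str = "fragment",
    rt_reference: Optional[float] = None,
    rt_reference_expected: Optional[float] = None,
    rrt_tolerance_pct: float = RRT_TOLERANCE_DEFAULT,
    expected_rt: Optional[float] = None,
) -> IdentificationResult:
    """Apply the full identification criteria set to a two-ion screen hit.

    ``identified`` requires: detection with two diagnostic ions, the
    secondary being a fragment ion, mass accuracy of the primary ion within
    5 ppm, a compliant ion ratio against ``reference_ratio`` under
    ``scheme``, and (when reference-compound RTs are supplied) an RRT
    deviation within ``rrt_tolerance_pct``.  Isotope-only hits are
    detectable but never identifiable.
    """
    if hit is None:
        return IdentificationResult(
            analyte="", detected=False, identified=False, ratio=None, reference=reference_ratio,
            tolerance=None, ratio_pass=False, mass_accuracy_pass=False, fragment_present=False,
            rrt_deviation_pct=None, rrt_pass=False, failure_reason="not detected",
        )
    two_ions = hit.secondary is not None and hit.delta_rt_min is not None
    is_fragment = two_ions and secondary_kind == "fragment"
    ratio = None
    if hit.secondary is not None and hit.primary.area > 0:
        ratio = hit.secondary.area / hit.primary.area
    mass_ok = abs(hit.primary.mass_error_ppm) <= MASS_ACCURACY_PPM
    tol = None
    ratio_ok = False
    if reference_ratio is not None and reference_ratio > 0 and ratio is not None:
        tol = tolerance_for_ratio(reference_ratio, scheme)
        ratio_ok = check_ion_ratio(IonRatio(ratio, reference_ratio), scheme)
    rrt_dev = None
    rrt_ok = True
    if rt_reference is not None and rt_reference_expected is not None and expected_rt is not None:
        rrt_dev = rrt_deviation(hit.primary.rt_min, rt_reference, expected_rt, rt_reference_expected)
        rrt_ok = rrt_dev <= rrt_tolerance_pct
    identified = bool(is_fragment and mass_ok and ratio_ok and rrt_ok)
    reason = ""
    if not identified:
        if not is_fragment:
            reason = "no fragment ion"
        elif not mass_ok:
            reason = "mass accuracy > 5 ppm"
        elif not ratio_ok:
            reason = "ion ratio outside tolerance"
        elif not rrt_ok:
            reason = "relative retention time outside tolerance"
    return IdentificationResult(
        analyte=hit.analyte,
        detected=True,
        identified=identified,
        ratio=ratio,
        reference=reference_ratio,
        tolerance=tol,
        ratio_pass=ratio_ok,
        mass_accuracy_pass=mass_ok,
        fragment_present=bool(is_fragment),
        rrt_deviation_pct=rrt_dev,
        rrt_pass=rrt_ok,
        failure_reason=reason,
    )


def identify_batch(
    runs: Sequence,
    db: Sequence[DbEntry],
    config: ScreenConfig,
    references: Mapping[str, float],
    scheme: RatioToleranceScheme = EU_TIERED,
    rrt_reference: Optional[str] = "diuron",
    rrt_tolerance_pct: float = RRT_TOLERANCE_DEFAULT,
) -> pd.DataFrame:
    """Two-ion screening plus identification for every analyte x run.

    ``references`` maps analyte name to its reference fragment/precursor
    ratio (typically the solvent-standard mean).  When ``rrt_reference``
    names a panel analyte and it is detected in a run, the relative
    retention time criterion is applied against it; otherwise the RRT check
    is skipped for that run.  Returns one row per analyte x run with the
    detected/identified flags and every criterion outcome.
    """
    ref_entry = next((e for e in db if e.name == rrt_reference), None)
    rows = []
    for run in runs:
        hits: Dict[str, Optional[ScreenHit]] = {
            e.name: screen_two_ion(run, e, config) for e in db
        }
        ref_rt = None
        if ref_entry is not None and hits.get(ref_entry.name) is not None:
            ref_rt = hits[ref_entry.name].primary.rt_min
        for entry in db:
            hit = hits[entry.name]
            res = identify(
                hit,
                references.get(entry.name),
                scheme=scheme,
                secondary_kind=entry.secondary_kind,
                rt_reference=ref_rt,
                rt_reference_expected=ref_entry.rt_min if ref_entry is not None else None,
                rrt_tolerance_pct=rrt_tolerance_pct,
                expected_rt=entry.rt_min,
            )
            rows.append(
                {
                    "analyte": entry.name,
                    "run": run.metadata.run_id,
                    "commodity": run.metadata.matrix,
                    "level": run.metadata.extra.get("level", float("nan")),
                    "detected": res.detected,
                    "identified": res.identified,
                    "ratio": res.ratio,
                    "reference": res.reference,
                    "tolerance": res.tolerance,
                    "ratio_pass": res.ratio_pass,
                    "mass_accuracy_pass": res.mass_accuracy_pass,
                    "fragment_present": res.fragment_present,
                    "rrt_deviation_pct": res.rrt_deviation_pct,
                    "rrt_pass": res.rrt_pass,
                    "failure_reason": res.failure_reason,
                }
            )
    return pd.DataFrame(rows)
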