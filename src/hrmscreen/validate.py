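"""Qualitative-validation statistics for a screening method.

Given a detection/identification matrix over analytes x commodities x spike
levels, this module computes false-positive and false-negative counts, the
screening detection limit (SDL: the lowest spike level at which an analyte
is detected with 95 % confidence across the commodity set), the limit of
identification (LOI: same rule on the identified flags), and per-level
summary rates.

The 95 %-confidence rule follows the qualitative-screening validation
guidance: with N samples an analyte must be found in at least ceil(0.95 N)
of them (19 of 20; 20 of 21).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ValidationDesign",
    "SDLReport",
    "confidence_threshold",
    "confusion_counts",
    "sdl",
    "loi",
    "summarize",
]


@dataclass
class ValidationDesign:
    """Commodities x spike levels x analyte panel, with the ground-truth
    spike map (which analyte was fortified in which commodity at which
    level).  Level 0.0 denotes the blank."""

    commodities: List[str]
    levels: List[float]
    panel: List[str]
    spike_map: Set[Tuple[str, str, float]] = field(default_factory=set)

    def __post_init__(self):
        if len(self.commodities) < 20:
            raise ValueError("validation requires at least 20 commodities")
        if 0.0 not in self.levels:
            raise ValueError("validation design must include a blank level (0.0)")
        if not self.spike_map:
            self.spike_map = {
                (a, c, lv)
                for a in self.panel
                for c in self.commodities
                for lv in self.levels
                if lv > 0
            }

    @property
    def nonzero_levels(self) -> List[float]:
        return sorted(lv for lv in set(self.levels) if lv > 0)


def confidence_threshold(n: int) -> int:
    """Minimum number of detections out of ``n`` samples for 95 % confidence:
    ceil(0.95 n) (19 for n=20, 20 for n=21)."""
    if n < 1:
        raise ValueError("sample count must be >= 1")
    return math.ceil(0.95 * n - 1e-9)


def _require_columns(dm: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in dm.columns]
    if missing:
        raise ValueError(f"detection matrix missing columns {missing}")


def confusion_counts(dm: pd.DataFrame, design: ValidationDesign) -> pd.DataFrame:
    """False positives and false negatives per level.

    A false positive is a detection in a blank (level-0) run of an analyte
    that was not present; a false negative is a spiked analyte x commodity x
    level combination with no detection.  Returns one row per level with
    columns fp, fn, n_combinations.
    """
    _require_columns(dm, ("analyte", "commodity", "level", "detected"))
    rows = []
    blanks = dm[dm["level"] == 0.0]
    fp = int(blanks["detected"].sum())
    rows.append({"level": 0.0, "fp": fp, "fn": 0, "n_combinations": len(blanks)})
    for lv in design.nonzero_levels:
        sub = dm[dm["level"] == lv]
        mask = np.array(
            [(a, c, lv) in design.spike_map for a, c in zip(sub["analyte"], sub["commodity"])],
            dtype=bool,
        )
        spiked = sub[mask] if len(sub) else sub
        fn = int((~spiked["detected"].astype(bool)).sum())
        rows.append({"level": lv, "fp": 0, "fn": fn, "n_combinations": len(spiked)})
    return pd.DataFrame(rows)


def _lowest_passing_level(
    dm: pd.DataFrame, analyte: str, design: ValidationDesign, flag: str
) -> Optional[float]:
    n = len(design.commodities)
    need = confidence_threshold(n)
    sub = dm[(dm["analyte"] == analyte) & (dm["level"] > 0)]
    for lv in design.nonzero_levels:
        count = int(sub[sub["level"] == lv][flag].astype(bool).sum())
        if count >= need:
            return lv
    return None


def sdl(dm: pd.DataFrame, analyte: str, design: ValidationDesign) -> Optional[float]:
    """Screening detection limit: the lowest spike level at which the analyte
    is detected in at least ceil(0.95 N) of the N commodities; None when no
    level qualifies (reported as "> max level")."""
    _require_columns(dm, ("analyte", "level", "detected"))
    return _lowest_passing_level(dm, analyte, design, "detected")


def loi(dm: pd.DataFrame, analyte: str, design: ValidationDesign) -> Optional[float]:
    """Limit of identification: as :func:`sdl` but on the identified flags.
    Since identified implies detected, LOI >= SDL whenever both exist."""
    _require_columns(dm, ("analyte", "level", "identified"))
    return _lowest_passing_level(dm, analyte, design, "identified")


@dataclass
class SDLReport:
    """Per-analyte SDL/LOI and per-level summary statistics."""

    per_analyte: pd.DataFrame  # analyte, sdl, loi (NaN = not established)
    per_level: pd.DataFrame  # level, detection_rate_pct, pct_95_detected, identification_rate_pct, pct_95_identified
    blank_false_positives: int

    def to_csv(self, per_analyte_path, per_level_path) -> None:
        self.per_analyte.to_csv(per_analyte_path, index=False)
        self.per_level.to_csv(per_level_path, index=False)


def summarize(dm: pd.DataFrame, design: ValidationDesign) -> SDLReport:
    """Validation summary over a complete detection matrix.

    Per level: the overall detection (identification) rate as a percentage
    of all spiked analyte x commodity combinations, and the percentage of
    panel analytes meeting the 95 %-confidence rule.  Results are invariant
    to commodity ordering and deterministically sorted.
    """
    if not design.panel:
        raise ValueError("empty analyte panel")
    _require_columns(dm, ("analyte", "commodity", "level", "detected", "identified"))
    bad = dm[dm["identified"].astype(bool) & ~dm["detected"].astype(bool)]
    if len(bad):
        raise ValueError("identified implies detected violated")
    n = len(design.commodities)
    need = confidence_threshold(n)
    rows_a = []
    for analyte in sorted(design.panel):
        s = sdl(dm, analyte, design)
        l = loi(dm, analyte, design)
        rows_a.append(
            {
                "analyte": analyte,
                "sdl": s if s is not None else float("nan"),
                "loi": l if l is not None else float("nan"),
            }
        )
    rows_l = []
    for lv in design.nonzero_levels:
        sub = dm[dm["level"] == lv]
        mask = np.array(
            [(a, c, lv) in design.spike_map for a, c in zip(sub["analyte"], sub["commodity"])],
            dtype=bool,
        )
        spiked = sub[mask] if len(sub) else sub
        total = len(spiked)
        det = int(spiked["detected"].astype(bool).sum())
        idn = int(spiked["identified"].astype(bool).sum())
        conf_det = sum(
            1
            for a in design.panel
            if int(spiked[spiked["analyte"] == a]["detected"].astype(bool).sum()) >= need
        )
        conf_idn = sum(
            1
            for a in design.panel
            if int(spiked[spiked["analyte"] == a]["identified"].astype(bool).sum()) >= need
        )
        rows_l.append(
            {
                "level": lv,
                "detection_rate_pct": 100.0 * det / total if total else float("nan"),
                "pct_95_detected": 100.0 * conf_det / len(design.panel),
                "identification_rate_pct": 100.0 * idn / total if total else float("nan"),
                "pct_95_identified": 100.0 * conf_idn / len(design.panel),
            }
        )
    blanks = dm[dm["level"] == 0.0]
    return SDLReport(
        per_analyte=pd.DataFrame(rows_a),
        per_level=pd.DataFrame(rows_l),
        blank_false_positives=int(blanks["detected"].astype(bool).sum()),
    )
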