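"""Molecular-formula arithmetic for HRMS screening.

Monoisotopic masses, electrospray adduct and fragment-cation m/z values, and
aggregated isotope patterns (M, M+1, M+2, ...) computed by exact polynomial
expansion over each element's natural isotope distribution.  The aggregation
collapses isotopologues into nominal mass shifts, which is the appropriate
granularity for Orbitrap acquisition at resolving power ~50,000 where the
fine structure within one nominal shift (e.g. 13C2 vs 34S) is not resolved.

The isotope masses and abundances are pinned to one published compilation
(CIAAW 2013, shipped as ``data/isotopes.csv``) so that every exact mass the
package prints is reproducible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Sequence, Tuple

__all__ = [
    "ELECTRON_MASS",
    "ElementIsotopeTable",
    "AdductSpec",
    "ADDUCTS",
    "IsotopePattern",
    "parse_formula",
    "formula_to_string",
    "combine_formulas",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_pattern",
    "most_abundant_isotope",
    "isotope_ion_mz",
]

#: Rest mass of the electron in Da, subtracted once per removed electron when
#: converting a neutral composition to a cation m/z.
ELECTRON_MASS = 0.00054858

Formula = Dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementIsotopeTable:
    """Per-element list of ``(isotope mass, natural abundance)`` pairs.

    Masses are strictly increasing per element and abundances sum to one
    within 1e-6.  The default table is loaded once from the packaged CSV.
    """

    _default: "ElementIsotopeTable | None" = None

    def __init__(self, data: Mapping[str, Sequence[Tuple[float, float]]], version: str = "custom"):
        self.version = version
        self._data: Dict[str, List[Tuple[float, float]]] = {}
        for element, isotopes in data.items():
            isotopes = sorted(isotopes)
            masses = [m for m, _ in isotopes]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {element} not strictly increasing")
            total = sum(a for _, a in isotopes)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {element} sum to {total}, not 1")
            self._data[element] = list(isotopes)

    def __contains__(self, element: str) -> bool:
        return element in self._data

    def __getitem__(self, element: str) -> List[Tuple[float, float]]:
        return self._data[element]

    def elements(self) -> List[str]:
        return sorted(self._data)

    @classmethod
    def default(cls) -> "ElementIsotopeTable":
        if cls._default is None:
            data: Dict[str, List[Tuple[float, float]]] = {}
            version = "unknown"
            ref = resources.files("hrmscreen.data").joinpath("isotopes.csv")
            with ref.open("r", encoding="utf-8") as fh:
                rows = [ln for ln in fh if ln.strip()]
            for ln in rows:
                if ln.startswith("#"):
                    m = re.search(r"version:\s*(\S+)", ln)
                    if m:
                        version = m.group(1)
                    continue
                parts = next(csv.reader([ln]))
                if parts[0] == "element":
                    continue
                element, _, mass, ab = parts
                data.setdefault(element, []).append((float(mass), float(ab)))
            cls._default = cls(data, version=version)
        return cls._default


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style molecular formula string into an element-count map.

    Element order is irrelevant and repeated symbols are summed
    (``"CH3CH3"`` parses the same as ``"C2H6"``).  Unknown element symbols
    and explicit zero counts are rejected.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    table = ElementIsotopeTable.default()
    out: Formula = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in table:
            raise ValueError(f"unknown element {element!r} in formula {text!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise ValueError(f"non-positive count for {element} in formula {text!r}")
        out[element] = out.get(element, 0) + count
        pos = m.end()
    return out


def formula_to_string(f: Mapping[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    parts = []
    keys = sorted(f, key=lambda e: (e != "C", e != "H", e))
    for e in keys:
        n = f[e]
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


def combine_formulas(f: Mapping[str, int], delta: Mapping[str, int]) -> Formula:
    """Elementwise sum of a formula and a signed element delta.

    Raises if any resulting count is negative; zero-count elements are
    dropped.
    """
    out: Formula = dict(f)
    for e, n in delta.items():
        out[e] = out.get(e, 0) + n
        if out[e] < 0:
            raise ValueError(f"element delta drives {e} count negative")
        if out[e] == 0:
            del out[e]
    return out


def monoisotopic_mass(f: Mapping[str, int], table: ElementIsotopeTable | None = None) -> float:
    """Mass of the lowest-mass isotopologue in Da.

    For every element in scope (C, H, N, O, P, S, F, Cl, Br, I, Na) the
    lowest-mass isotope is also the most abundant one, so this coincides
    with the conventional monoisotopic mass.
    """
    table = table or ElementIsotopeTable.default()
    total = 0.0
    for e, n in f.items():
        if e not in table:
            raise ValueError(f"unknown element {e!r}")
        if n < 1:
            raise ValueError(f"non-positive count for element {e!r}")
        total += n * table[e][0][0]
    return total


@dataclass(frozen=True)
class AdductSpec:
    """Positive-electrospray ion species formed from a neutral molecule.

    ``delta`` holds the signed element counts added to the neutral formula
    (e.g. ``{"H": 1}`` for protonation), ``electrons_removed`` the number of
    electron masses to subtract, and ``isotope_shift`` selects an isotopologue
    of the adduct itself (used for "(M+2)+H"-style primary ions where the
    monoisotopic ion is not the most abundant one).
    """

    label: str
    delta: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1
    electrons_removed: int = 1
    isotope_shift: int = 0

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("positive-mode ions only: charge must be >= 1")


#: Supported adduct/ion species, matching the primary-ion vocabulary of the
#: screening database ([M+H]+, [M+NH4]+, [M+Na]+, isotope-shifted protonated
#: molecules, and bare fragment cations).
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}),
    "(M+2)+H": AdductSpec("(M+2)+H", {"H": 1}, isotope_shift=2),
    "(M+4)+H": AdductSpec("(M+4)+H", {"H": 1}, isotope_shift=4),
    "[frag]+": AdductSpec("[frag]+", {}),
}


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotope envelope of one composition.

    ``entries[k]`` is ``(centroid mass in Da, abundance relative to the
    monoisotopic isotopologue)`` for nominal shift ``k``; shifts are
    contiguous from 0 and entry 0 has relative abundance exactly 1.
    """

    entries: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if not self.entries or self.entries[0][1] != 1.0:
            raise ValueError("pattern must start at M with relative abundance 1")
        if any(a < 0 for _, a in self.entries):
            raise ValueError("negative relative abundance")

    @property
    def max_shift(self) -> int:
        return len(self.entries) - 1

    def relative_abundance(self, shift: int) -> float:
        return self.entries[shift][1]

    def centroid_mass(self, shift: int) -> float:
        return self.entries[shift][0]


def _element_shift_distribution(
    isotopes: Sequence[Tuple[float, float]], n: int, max_shift: int
) -> List[Tuple[float, float]]:
    """Distribution of (probability, probability-weighted mass) over nominal
    shift for ``n`` atoms of one element, truncated at ``max_shift``.

    The single-atom distribution assigns each isotope the integer shift
    ``round(mass - lightest mass)``; n-atom values follow by polynomial
    (convolution) expansion, which is exact for the aggregated bins kept.
    """
    m0 = isotopes[0][0]
    single: List[Tuple[float, float]] = [(0.0, 0.0)] * (max_shift + 1)
    for mass, ab in isotopes:
        k = round(mass - m0)
        if k <= max_shift:
            p, wm = single[k]
            single[k] = (p + ab, wm + ab * mass)
    dist: List[Tuple[float, float]] = [(1.0, 0.0)] + [(0.0, 0.0)] * max_shift
    for _ in range(n):
        nxt = [(0.0, 0.0)] * (max_shift + 1)
        for k1, (p1, wm1) in enumerate(dist):
            if p1 == 0.0:
                continue
            mean1 = wm1 / p1 if p1 else 0.0
            for k2, (p2, wm2) in enumerate(single):
                if p2 == 0.0 or k1 + k2 > max_shift:
                    continue
                mean2 = wm2 / p2
                p, wm = nxt[k1 + k2]
                nxt[k1 + k2] = (p + p1 * p2, wm + p1 * p2 * (mean1 + mean2))
        dist = nxt
    return dist


def isotope_pattern(
    f: Mapping[str, int], max_shift: int = 4, table: ElementIsotopeTable | None = None
) -> IsotopePattern:
    """Aggregated isotope pattern of a composition up to ``max_shift``.

    Relative abundances are isotopologue probabilities summed within each
    nominal shift, normalised to the monoisotopic isotopologue; centroid
    masses are the probability-weighted mean masses of the contributing
    isotopologues.  Computed by exact per-element polynomial expansion and
    cross-element convolution (no Gaussian approximation); the cost is
    linear in atom count and quadratic in ``max_shift``, so there is no
    practical size bound for small-molecule formulas.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    table = table or ElementIsotopeTable.default()
    dist: List[Tuple[float, float]] = [(1.0, 0.0)] + [(0.0, 0.0)] * max_shift
    for e, n in f.items():
        if e not in table:
            raise ValueError(f"unknown element {e!r}")
        edist = _element_shift_distribution(table[e], n, max_shift)
        nxt = [(0.0, 0.0)] * (max_shift + 1)
        for k1, (p1, wm1) in enumerate(dist):
            if p1 == 0.0:
                continue
            mean1 = wm1 / p1
            for k2, (p2, wm2) in enumerate(edist):
                if p2 == 0.0 or k1 + k2 > max_shift:
                    continue
                mean2 = wm2 / p2
                p, wm = nxt[k1 + k2]
                nxt[k1 + k2] = (p + p1 * p2, wm + p1 * p2 * (mean1 + mean2))
        dist = nxt
    p_mono = dist[0][0]
    if p_mono <= 0.0:
        raise ValueError("monoisotopic probability vanished; formula unsupported")
    entries = []
    for k, (p, wm) in enumerate(dist):
        if p > 0.0:
            entries.append((wm / p, p / p_mono))
        else:
            entries.append((monoisotopic_mass(f, table) + k * 1.00336, 0.0))
    entries[0] = (entries[0][0], 1.0)
    return IsotopePattern(tuple(entries))


def most_abundant_isotope(
    f: Mapping[str, int], max_shift: int = 4, table: ElementIsotopeTable | None = None
) -> Tuple[int, float]:
    """Most sensitive isotope ion: the shift k >= 1 with the highest relative
    abundance in the aggregated pattern (ties broken toward smaller k).

    Returns ``(shift, relative abundance)``; e.g. M+2 for Cl/Br-containing
    molecules, M+1 for most pure-CHNO molecules.
    """
    pat = isotope_pattern(f, max_shift=max_shift, table=table)
    best_k, best_a = 1, pat.relative_abundance(1)
    for k in range(2, pat.max_shift + 1):
        a = pat.relative_abundance(k)
        if a > best_a:
            best_k, best_a = k, a
    return best_k, best_a


def ion_mz(
    f: Mapping[str, int], adduct: AdductSpec, table: ElementIsotopeTable | None = None
) -> float:
    """m/z of the ion formed from neutral formula ``f`` under ``adduct``.

    ``(mass(f + delta) - electrons_removed * m_e) / charge``; when the adduct
    selects an isotope shift, the shifted centroid mass from the aggregated
    pattern of the ion composition is used instead of the monoisotopic mass.
    """
    table = table or ElementIsotopeTable.default()
    composition = combine_formulas(f, adduct.delta)
    if adduct.isotope_shift:
        pat = isotope_pattern(composition, max_shift=adduct.isotope_shift, table=table)
        mass = pat.centroid_mass(adduct.isotope_shift)
    else:
        mass = monoisotopic_mass(composition, table)
    return (mass - adduct.electrons_removed * ELECTRON_MASS) / adduct.charge


def isotope_ion_mz(
    f: Mapping[str, int],
    adduct: AdductSpec,
    shift: int,
    table: ElementIsotopeTable | None = None,
) -> float:
    """m/z of the ``M+shift`` isotopologue of the adduct ion of ``f``.

    The centroid comes from the aggregated isotope pattern of the full ion
    composition, not from ``monoisotopic + shift * 1.00336``.
    """
    table = table or ElementIsotopeTable.default()
    composition = combine_formulas(f, adduct.delta)
    base = adduct.isotope_shift
    pat = isotope_pattern(composition, max_shift=base + shift, table=table)
    mass = pat.centroid_mass(base + shift)
    return (mass - adduct.electrons_removed * ELECTRON_MASS) / adduct.charge
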