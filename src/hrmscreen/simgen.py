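"""Synthetic two-event LC-HRMS run generator with ground truth.

The generator emulates the statistical structure of real vegetable/fruit
screening data: Gaussian chromatographic peaks sampled at a 1 Hz alternating
two-event acquisition, theoretical isotope envelopes with the Orbitrap's
systematic under-estimation of relative isotope abundance (M+1 bias 0.47 at
C5 rising linearly to ~1.0 at C41+, M+2 bias 0.8-1.0), all-ion-fragmentation
scans carrying fragment ions whose fragment/precursor ratio is attenuated in
matrix (mean factor 0.83) with ~20 % run-to-run RSD, matrix ion suppression
(factor 1-10), near-isobaric matrix interferences, single-scan spike
artifacts, spectral-leakage satellite peaks flanking intense ions, and a
truncated-Gaussian mass-error model (sigma 1.5 ppm, never beyond 5 ppm).

Every planted signal is recorded in a ground-truth table, which makes the
generator the oracle for screening, identification, and validation tests.
All randomness flows from one integer seed through a documented
``numpy.random.SeedSequence`` spawn scheme (one child per run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import ADDUCTS
from .msdata import CentroidSpectrum, Run, RunMetadata
from .screen import DbEntry, ScreenConfig
from .validate import ValidationDesign

__all__ = [
    "Interference",
    "MatrixProfile",
    "AnalyteModel",
    "SimConfig",
    "make_demo_db",
    "make_panel",
    "solvent_reference_ratios",
    "simulate_run",
    "generate_validation_set",
    "generate_blank_set",
    "truth_two_ion_detectable",
    "COMMODITIES",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: 21 produce commodities of the kind a high-water-content validation set uses.
COMMODITIES = [
    "apple", "orange", "lemon", "grape", "melon", "banana", "strawberry",
    "tomato", "cucumber", "bell_pepper", "carrot", "potato", "white_cabbage",
    "lettuce", "spinach", "broccoli", "leek", "onion", "courgette",
    "aubergine", "pear",
]


@dataclass
class Interference:
    """A matrix compound planted as a chromatographic peak in event 1 only
    (it has no secondary diagnostic ion)."""

    mz: float
    rt_min: float
    height: float
    sigma_s: float = 3.0


@dataclass
class MatrixProfile:
    """Per-commodity matrix behaviour."""

    label: str
    suppression: float = 1.0  # >= 1; divides every analyte response
    interferences: List[Interference] = field(default_factory=list)
    spike_rate: float = 2.0  # expected single-scan spike artifacts per run
    fragment_matrix_factor: float = 0.83  # attenuation of fragment/precursor ratio
    leakage_fraction: float = 0.002  # satellite height as fraction of parent
    leakage_threshold: float = 5e5  # parent intensity needed to leak
    leakage_offset_da: float = 0.0165

    def __post_init__(self):
        if self.suppression < 1:
            raise ValueError("suppression factor must be >= 1")
        if self.spike_rate < 0 or self.leakage_fraction < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class AnalyteModel:
    """Response model for one database analyte.

    ``response_factor`` is peak area (intensity x minutes) per mg/kg in a
    suppression-free matrix; across a realistic panel it spans a factor of
    ~600.  The RIA bias factors multiply the theoretical relative isotope
    abundances; the M+1 bias is tied to carbon count (strongest deviation
    for small molecules).  ``frag_ratio_solvent`` is the fragment/precursor
    area ratio in solvent standards.
    """

    entry: DbEntry
    response_factor: float
    sigma_s: float = 3.0
    m1_bias: float = 0.8
    m2_bias: float = 0.9
    frag_ratio_solvent: float = 0.3
    iso_ratio_rsd: float = 0.08
    frag_ratio_rsd: float = 0.20
    event2_precursor_fraction: float = 0.5
    split_peak: bool = False

    def __post_init__(self):
        if self.response_factor <= 0:
            raise ValueError("response factor must be > 0")
        if not (0.4 <= self.m1_bias <= 1.0 and 0.7 <= self.m2_bias <= 1.05):
            raise ValueError("RIA bias factor outside plausible range")


@dataclass
class SimConfig:
    """Acquisition and noise parameters shared by all simulated runs."""

    run_length_min: float = 20.0
    scan_period_s: float = 1.0  # one full event-1 + event-2 cycle
    mz_range: Tuple[float, float] = (55.0, 1000.0)
    mass_error_sigma_ppm: float = 1.5
    mass_error_max_ppm: float = 5.0
    noise_peaks_per_spectrum: float = 15.0
    noise_intensity_mean: float = 30.0
    response_rsd: float = 0.05
    levels: Tuple[float, ...] = (0.01, 0.05, 0.20)
    n_commodities: int = 21

    def __post_init__(self):
        if self.mass_error_sigma_ppm >= 5.0:
            raise ValueError("mass error sigma must stay below 5 ppm")


# ---------------------------------------------------------------------------
# demo database and analyte panel

# (name, rt_min, formula, adduct, secondary_kind, secondary_value)
_CATALOG = [
    ("diuron", 9.88, "C9H10Cl2N2O", "[M+H]+", "isotope", "M+2"),
    ("imazalil", 10.75, "C14H14Cl2N2O", "[M+H]+", "fragment", "C7H5Cl2"),
    ("carbendazim", 7.70, "C9H9N3O2", "[M+H]+", "fragment", "C8H6N3O"),
    ("atrazine", 9.74, "C8H14ClN5", "[M+H]+", "isotope", "M+2"),
    ("methomyl", 6.14, "C5H10N2O2S", "[M+H]+", "isotope", "M+1"),
    ("carbaryl", 8.98, "C12H11NO2", "[M+H]+", "fragment", "C10H9O"),
    ("propamocarb", 5.20, "C9H20N2O2", "[M+H]+", "fragment", "C4H8NO2"),
    ("promecarb", 10.57, "C12H17NO2", "[M+H]+", "fragment", "C7H9O"),
    ("thiocyclam", 5.00, "C5H11NS3", "[M+H]+", "isotope", "M+2"),
    ("methoxyfenozide", 10.52, "C22H28N2O3", "[M+H]+", "fragment", "C9H9O2"),
    ("pirimicarb", 9.49, "C11H18N4O2", "[M+H]+", "isotope", "M+1"),
    ("methamidophos", 4.50, "C2H8NO2PS", "[M+H]+", "isotope", "M+2"),
]


def make_demo_db(n: int = 10, seed: int = 0) -> List[DbEntry]:
    """A small demo screening database of real pesticides (name, retention
    time, formula, adduct, secondary diagnostic ion).

    Deterministic for a fixed seed; the first entries always include diuron
    (the relative-retention-time reference compound) and imazalil.  ``n`` is
    capped at the catalogue size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(_CATALOG):
        raise ValueError(f"demo database holds at most {len(_CATALOG)} analytes")
    rng = np.random.default_rng(seed)
    head, tail = list(_CATALOG[:3]), list(_CATALOG[3:])
    rng.shuffle(tail)
    chosen = (head + tail)[:n]
    return [
        DbEntry(
            name=name,
            rt_min=rt,
            formula=chem.parse_formula(f),
            adduct=ADDUCTS[adduct],
            secondary_kind=kind,
            secondary_value=value,
        )
        for name, rt, f, adduct, kind, value in chosen
    ]


def _m1_bias_for_carbon(n_carbon: int) -> float:
    """Orbitrap M+1 RIA bias: 0.47 at C5 rising linearly to 1.0 at C41+."""
    return float(np.clip(0.47 + (n_carbon - 5) * (1.0 - 0.47) / (41 - 5), 0.47, 1.0))


def make_panel(
    entries: Sequence[DbEntry],
    seed: int = 0,
    response_factor_max: float = 6e6,
    response_factor_span: float = 600.0,
) -> List[AnalyteModel]:
    """Attach response models to database entries.

    Response factors are log-spaced over ``response_factor_span`` (the
    sensitivity spread observed across real pesticide panels) and assigned
    in a seed-determined order; fragment/precursor solvent ratios are drawn
    uniform 0.1-0.8, M+2 bias uniform 0.8-1.0, M+1 bias from carbon count.
    """
    rng = np.random.default_rng(seed)
    n = len(entries)
    rfs = response_factor_max / response_factor_span ** (np.arange(n) / max(n - 1, 1))
    order = rng.permutation(n)
    panel = []
    for i, entry in enumerate(entries):
        panel.append(
            AnalyteModel(
                entry=entry,
                response_factor=float(rfs[order[i]]),
                m1_bias=_m1_bias_for_carbon(entry.formula.get("C", 0)),
                m2_bias=float(rng.uniform(0.8, 1.0)),
                frag_ratio_solvent=float(rng.uniform(0.1, 0.8)),
            )
        )
    return panel


def solvent_reference_ratios(panel: Sequence[AnalyteModel]) -> Dict[str, float]:
    """Reference fragment/precursor ion ratios from solvent standards.

    In solvent the matrix attenuation factor is 1, so the mean observed
    ratio equals the configured solvent ratio; analytes with an isotope
    secondary get no fragment reference.
    """
    return {
        m.entry.name: m.frag_ratio_solvent
        for m in panel
        if m.entry.secondary_kind == "fragment"
    }


# ---------------------------------------------------------------------------
# run simulation


def _gaussian_trace(times: np.ndarray, rt: float, sigma_min: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((times - rt) / sigma_min) ** 2)


def simulate_run(
    panel: Sequence[AnalyteModel],
    matrix: MatrixProfile,
    level: float,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    run_id: Optional[str] = None,
) -> Tuple[Run, pd.DataFrame]:
    """Simulate one two-event run of the panel spiked at ``level`` mg/kg into
    the given matrix, returning the Run and its ground-truth table.

    Event-1 spectra carry each analyte's adduct ion plus its isotope
    envelope (theoretical pattern x RIA bias x per-run ratio noise), scaled
    by ``response_factor x level / suppression``; event-2 spectra carry a
    residual precursor and, for fragment-secondary analytes, the fragment
    ion at the solvent ratio x matrix factor x lognormal noise.  Matrix
    interferences, single-scan spikes, leakage satellites, and sparse
    baseline noise are added on top.  Identical seeds give bit-identical
    runs.
    """
    if level < 0:
        raise ValueError("spike level must be >= 0")
    rng = np.random.default_rng(seed)
    run_id = run_id or f"{matrix.label}_{level:g}"
    period_min = cfg.scan_period_s / 60.0
    n_cycles = int(round(cfg.run_length_min / period_min))
    t1 = np.arange(n_cycles) * period_min
    t2 = t1 + 0.5 * period_min
    sigma_default = 3.0 / 60.0

    # contributions[event][scan index] -> list of (theoretical mz, intensity)
    contributions: Dict[int, Dict[int, List[Tuple[float, float]]]] = {1: {}, 2: {}}

    def plant(event: int, times: np.ndarray, mz: float, rt: float, sigma_min: float, height: float, split: bool):
        if height <= 0:
            return
        if split:
            trace = _gaussian_trace(times, rt - 0.05, sigma_min, 0.6 * height) + _gaussian_trace(
                times, rt + 0.05, sigma_min, 0.6 * height
            )
        else:
            trace = _gaussian_trace(times, rt, sigma_min, height)
        idx = np.nonzero(trace > 1e-3 * height)[0]
        store = contributions[event]
        for i in idx:
            store.setdefault(int(i), []).append((mz, float(trace[i])))

    truth_rows = []
    for model in panel:
        if level <= 0:
            continue
        entry = model.entry
        sigma_min = model.sigma_s / 60.0
        response_noise = float(rng.lognormal(0.0, cfg.response_rsd))
        area = model.response_factor * level / matrix.suppression * response_noise
        height = area / (sigma_min * SQRT_2PI)
        ion_formula = chem.combine_formulas(entry.formula, entry.adduct.delta)
        pattern = chem.isotope_pattern(ion_formula, max_shift=4)
        primary_mz = entry.primary_mz()
        # event 1: monoisotopic adduct ion + isotope envelope with RIA bias
        plant(1, t1, primary_mz, entry.rt_min, sigma_min, height, model.split_peak)
        iso_ratio_planted = {}
        for k in range(1, pattern.max_shift + 1):
            ria = pattern.relative_abundance(k)
            if ria <= 1e-6:
                continue
            bias = model.m1_bias if k == 1 else model.m2_bias
            noise = float(rng.lognormal(0.0, model.iso_ratio_rsd))
            ratio = ria * bias * noise
            iso_ratio_planted[k] = ratio
            mz_k = (pattern.centroid_mass(k) - chem.ELECTRON_MASS) / entry.adduct.charge
            plant(1, t1, mz_k, entry.rt_min, sigma_min, height * ratio, model.split_peak)
        # event 2: residual precursor + fragment
        plant(2, t2, primary_mz, entry.rt_min, sigma_min, height * model.event2_precursor_fraction, model.split_peak)
        frag_ratio_planted = float("nan")
        if entry.secondary_kind == "fragment":
            noise = float(rng.lognormal(0.0, model.frag_ratio_rsd))
            frag_ratio_planted = model.frag_ratio_solvent * matrix.fragment_matrix_factor * noise
            plant(2, t2, entry.secondary_mz(), entry.rt_min, sigma_min, height * frag_ratio_planted, model.split_peak)
        if entry.secondary_kind == "isotope":
            k = int(entry.secondary_value.strip().upper().replace(" ", "")[2:])
            sec_ratio = iso_ratio_planted.get(k, 0.0)
        else:
            sec_ratio = frag_ratio_planted
        truth_rows.append(
            {
                "analyte": entry.name,
                "run": run_id,
                "matrix": matrix.label,
                "level": level,
                "rt_min": entry.rt_min,
                "area_primary": area,
                "height_primary": height,
                "secondary_kind": entry.secondary_kind,
                "secondary_ratio": sec_ratio,
                "height_secondary": height * sec_ratio,
                "area_secondary": area * sec_ratio,
                "suppression": matrix.suppression,
                "response_factor": model.response_factor,
            }
        )

    for interf in matrix.interferences:
        plant(1, t1, interf.mz, interf.rt_min, interf.sigma_s / 60.0, interf.height, False)

    # single-scan spike artifacts at analyte masses near analyte RTs (event 1)
    n_spikes = int(rng.poisson(matrix.spike_rate))
    for _ in range(n_spikes):
        model = panel[int(rng.integers(len(panel)))]
        rt = model.entry.rt_min + float(rng.uniform(-0.4, 0.4))
        i = int(np.clip(round(rt / period_min), 0, n_cycles - 1))
        intensity = float(rng.lognormal(math.log(5e3), 0.6))
        contributions[1].setdefault(i, []).append((model.entry.primary_mz(), intensity))

    # assemble spectra
    lo, hi = cfg.mz_range
    clip = cfg.mass_error_max_ppm * 0.999
    spectra: List[CentroidSpectrum] = []
    for i in range(n_cycles):
        for event, times in ((1, t1), (2, t2)):
            peaks = list(contributions[event].get(i, []))
            n_noise = int(rng.poisson(cfg.noise_peaks_per_spectrum))
            noise_mz = rng.uniform(lo, hi, n_noise)
            noise_int = rng.exponential(cfg.noise_intensity_mean, n_noise)
            mzs = np.array([p[0] for p in peaks] + list(noise_mz))
            ints = np.array([p[1] for p in peaks] + list(noise_int))
            if mzs.size:
                err = np.clip(rng.normal(0.0, cfg.mass_error_sigma_ppm, mzs.size), -clip, clip)
                mzs = mzs * (1.0 + err * 1e-6)
                if event == 1 and matrix.leakage_fraction > 0:
                    big = ints > matrix.leakage_threshold
                    if big.any():
                        sat_mz = np.concatenate(
                            [mzs[big] - matrix.leakage_offset_da, mzs[big] + matrix.leakage_offset_da]
                        )
                        sat_int = np.concatenate([ints[big], ints[big]]) * matrix.leakage_fraction
                        mzs = np.concatenate([mzs, sat_mz])
                        ints = np.concatenate([ints, sat_int])
                keep = (mzs >= lo) & (mzs <= hi)
                mzs, ints = mzs[keep], ints[keep]
                order = np.argsort(mzs)
                mzs, ints = mzs[order], ints[order]
                # merge coincident centroids so m/z stays strictly ascending
                if mzs.size > 1:
                    dup = np.diff(mzs) < 1e-7
                    if dup.any():
                        keep_idx = np.concatenate([[True], ~dup])
                        groups = np.cumsum(keep_idx) - 1
                        merged_int = np.zeros(groups[-1] + 1)
                        np.add.at(merged_int, groups, ints)
                        mzs = mzs[keep_idx]
                        ints = merged_int
            spectra.append(CentroidSpectrum(time_min=float(times[i]), event=event, mz=mzs, intensity=ints))

    metadata = RunMetadata(
        run_id=run_id,
        matrix=matrix.label,
        scan_period_s=cfg.scan_period_s,
        scan_range=cfg.mz_range,
        extra={"level": level, "seed": int(seed)},
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "analyte", "run", "matrix", "level", "rt_min", "area_primary", "height_primary",
            "secondary_kind", "secondary_ratio", "height_secondary", "area_secondary",
            "suppression", "response_factor",
        ],
    )
    return Run(spectra=spectra, metadata=metadata), truth


# ---------------------------------------------------------------------------
# validation-set generation


def _draw_profile(label: str, panel: Sequence[AnalyteModel], rng: np.random.Generator) -> MatrixProfile:
    suppression = float(10.0 ** rng.uniform(0.0, 1.0))
    interferences = []
    for _ in range(int(rng.poisson(0.7))):
        model = panel[int(rng.integers(len(panel)))]
        mz = model.entry.primary_mz() * (1.0 + float(rng.uniform(-3.0, 3.0)) * 1e-6)
        rt = model.entry.rt_min + float(rng.uniform(-0.3, 0.3))
        height = float(rng.lognormal(math.log(2e4), 0.7))
        interferences.append(Interference(mz=mz, rt_min=rt, height=height))
    return MatrixProfile(label=label, suppression=suppression, interferences=interferences)


def generate_validation_set(
    panel: Sequence[AnalyteModel],
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
) -> Tuple[List[Run], ValidationDesign, pd.DataFrame, List[MatrixProfile]]:
    """The full validation experiment: N commodities x (blank + spike levels).

    Per-commodity matrix profiles (suppression 1-10, near-isobaric
    interferences, spike artifacts) are drawn from the configured ranges;
    every run and profile is reproducible from the seed.  Returns the runs,
    the validation design consumed by the validate module, the concatenated
    ground truth, and the drawn profiles.
    """
    if not panel:
        raise ValueError("empty panel")
    if cfg.n_commodities < 20:
        raise ValueError("validation requires at least 20 commodities")
    commodities = [COMMODITIES[i % len(COMMODITIES)] + ("" if i < len(COMMODITIES) else f"_{i}") for i in range(cfg.n_commodities)]
    root = np.random.SeedSequence(seed)
    profile_seed, *run_seeds = root.spawn(1 + cfg.n_commodities * (1 + len(cfg.levels)))
    prng = np.random.default_rng(profile_seed)
    profiles = [_draw_profile(c, panel, prng) for c in commodities]
    levels = [0.0] + list(cfg.levels)
    runs: List[Run] = []
    truths = []
    k = 0
    for profile in profiles:
        for level in levels:
            child = np.random.default_rng(run_seeds[k]).integers(0, 2**31 - 1)
            run, truth = simulate_run(
                panel, profile, level, cfg, seed=int(child), run_id=f"{profile.label}_{level:g}"
            )
            runs.append(run)
            truths.append(truth)
            k += 1
    design = ValidationDesign(
        commodities=commodities,
        levels=levels,
        panel=[m.entry.name for m in panel],
    )
    truth = pd.concat([t for t in truths if len(t)], ignore_index=True) if any(len(t) for t in truths) else pd.DataFrame()
    return runs, design, truth, profiles


def generate_blank_set(
    panel: Sequence[AnalyteModel],
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    min_interferences: int = 5,
) -> Tuple[List[Run], List[MatrixProfile]]:
    """N blank commodity runs with matrix interferences and spike artifacts,
    for false-positive assessment.

    Guarantees at least ``min_interferences`` near-isobaric interference
    peaks across the set by drawing additional ones if the random draw falls
    short.
    """
    root = np.random.SeedSequence(seed)
    profile_seed, *run_seeds = root.spawn(1 + cfg.n_commodities)
    prng = np.random.default_rng(profile_seed)
    commodities = [COMMODITIES[i % len(COMMODITIES)] for i in range(cfg.n_commodities)]
    profiles = [_draw_profile(c, panel, prng) for c in commodities]
    total = sum(len(p.interferences) for p in profiles)
    while total < min_interferences:
        p = profiles[int(prng.integers(len(profiles)))]
        model = panel[int(prng.integers(len(panel)))]
        p.interferences.append(
            Interference(
                mz=model.entry.primary_mz() * (1.0 + float(prng.uniform(-3.0, 3.0)) * 1e-6),
                rt_min=model.entry.rt_min + float(prng.uniform(-0.3, 0.3)),
                height=float(prng.lognormal(math.log(2e4), 0.7)),
            )
        )
        total += 1
    runs = []
    for profile, ss in zip(profiles, run_seeds):
        child = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        run, _ = simulate_run(panel, profile, 0.0, cfg, seed=child, run_id=f"{profile.label}_blank")
        runs.append(run)
    return runs, profiles


def _expected_detected(
    model: AnalyteModel,
    row: pd.Series,
    profile: Optional[MatrixProfile],
    config: ScreenConfig,
    cfg: SimConfig,
) -> Tuple[bool, bool, bool]:
    """Expected two-ion detection outcome for one planted analyte, derived
    from the noiseless analytic traces.

    The planted chromatography is fully known (Gaussian heights, retention
    times, scan grid, and any co-eluting matrix interferences inside the
    primary mass window), so the expected outcome follows by evaluating the
    noise-free expected EIC on the scan grid and applying the same
    detection rule — floor, minimum consecutive scans, peak splitting, and
    apex-coincidence pairing.  Baseline noise and per-scan mass error are
    deliberately left out: they are small compared to the floor and the
    mass window by construction.
    """
    from .msdata import EIC as _EIC
    from .screen import detect_peaks as _detect_peaks

    entry = model.entry
    period_min = cfg.scan_period_s / 60.0
    n = int(round(cfg.run_length_min / period_min))
    t1 = np.arange(n) * period_min
    t2 = t1 + 0.5 * period_min
    sigma_min = model.sigma_s / 60.0
    rt = entry.rt_min
    primary = row["height_primary"] * np.exp(-0.5 * ((t1 - rt) / sigma_min) ** 2)
    mz = entry.primary_mz()
    half = mz * config.ppm * 1e-6
    if profile is not None:
        for interf in profile.interferences:
            if abs(interf.mz - mz) <= half:
                primary = primary + interf.height * np.exp(
                    -0.5 * ((t1 - interf.rt_min) / (interf.sigma_s / 60.0)) ** 2
                )
    t_sec = t1 if entry.secondary_event == 1 else t2
    secondary = row["height_secondary"] * np.exp(-0.5 * ((t_sec - rt) / sigma_min) ** 2)
    window = (rt - config.rt_window_min, rt + config.rt_window_min)
    nanmz = np.full(n, np.nan)
    p1 = _detect_peaks(_EIC(mz, config.ppm, 1, t1, primary, nanmz), window, config)
    p2 = _detect_peaks(_EIC(0.0, config.ppm, entry.secondary_event, t_sec, secondary, nanmz), window, config)
    if not p1 or not p2:
        return bool(p1), bool(p2), False
    delta = min(abs(a.rt_min - b.rt_min) for a in p1 for b in p2)
    return True, True, delta <= config.delta_rt_max_min


def truth_two_ion_detectable(
    truth: pd.DataFrame,
    config: ScreenConfig,
    profiles: Optional[Sequence[MatrixProfile]] = None,
    models: Optional[Sequence[AnalyteModel]] = None,
    cfg: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Annotate a ground-truth table with the expected two-ion detectability.

    The expectation is derived from the planted signal heights alone (see
    :func:`_expected_detected`): the noise-free analytic chromatograms —
    including any co-eluting matrix interferences that fall inside the
    primary mass window and can merge with or displace the analyte peak —
    are evaluated on the acquisition grid and passed through the detection
    rule.  With ``models`` (and optionally ``profiles``) omitted, a simple
    floor comparison on the planted apex heights is used instead.
    """
    out = truth.copy()
    if models is None:
        out["detectable_primary"] = out["height_primary"] > config.min_height
        out["detectable_secondary"] = out["height_secondary"] > config.min_height
        out["detectable_two_ion"] = out["detectable_primary"] & out["detectable_secondary"]
        return out
    by_name = {m.entry.name: m for m in models}
    by_label = {p.label: p for p in profiles} if profiles is not None else {}
    cols = {"detectable_primary": [], "detectable_secondary": [], "detectable_two_ion": []}
    for _, row in out.iterrows():
        model = by_name[row["analyte"]]
        ok1, ok2, both = _expected_detected(model, row, by_label.get(row["matrix"]), config, cfg)
        cols["detectable_primary"].append(ok1)
        cols["detectable_secondary"].append(ok2)
        cols["detectable_two_ion"].append(both)
    for k, v in cols.items():
        out[k] = v
    return out
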