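"""Shared fixtures.

The full synthetic validation experiment (21 commodities x blank + 3 spike
levels, 10-analyte panel) is generated once per session and shared by the
screening, identification, validation, and acceptance tests; its seed is
fixed so every run of the suite sees identical data.
"""

from __future__ import annotations

import numpy as np
import pytest

from hrmscreen import screen, simgen

SEED = 1


@pytest.fixture(scope="session")
def demo_db():
    return simgen.make_demo_db(10, seed=SEED)


@pytest.fixture(scope="session")
def panel(demo_db):
    return simgen.make_panel(demo_db, seed=SEED)


@pytest.fixture(scope="session")
def sim_config():
    return simgen.SimConfig()


@pytest.fixture(scope="session")
def screen_config():
    return screen.ScreenConfig()


@pytest.fixture(scope="session")
def validation_set(panel, sim_config):
    """(runs, design, truth, profiles) for the default validation design."""
    return simgen.generate_validation_set(panel, sim_config, seed=SEED)


@pytest.fixture(scope="session")
def two_ion_results(validation_set, demo_db, screen_config):
    runs, _, _, _ = validation_set
    return screen.screen_batch(runs, demo_db, screen_config, strategy="two-ion")


@pytest.fixture(scope="session")
def blank_set(panel, sim_config):
    """(runs, profiles) of 21 blank commodity runs with injected
    near-isobaric interferences and spike artifacts."""
    return simgen.generate_blank_set(panel, sim_config, seed=SEED, min_interferences=5)


def gaussian_run(
    ions,
    run_length_min: float = 4.0,
    sigma_s: float = 3.0,
    period_s: float = 1.0,
    mz_range=(55.0, 1000.0),
    run_id: str = "toy",
):
    """Small noise-free two-event run with Gaussian traces.

    ``ions`` is a list of (event, mz, rt_min, height).  Used by tests that
    need exact, hand-computable chromatograms.
    """
    from hrmscreen.msdata import CentroidSpectrum, Run, RunMetadata

    period_min = period_s / 60.0
    n = int(round(run_length_min / period_min))
    sigma_min = sigma_s / 60.0
    spectra = []
    for i in range(n):
        for event, offset in ((1, 0.0), (2, 0.5 * period_min)):
            t = i * period_min + offset
            peaks = []
            for ev, mz, rt, h in ions:
                if ev != event:
                    continue
                y = h * np.exp(-0.5 * ((t - rt) / sigma_min) ** 2)
                if y > 1e-6 * h:
                    peaks.append((mz, y))
            peaks.sort()
            spectra.append(
                CentroidSpectrum(
                    time_min=t,
                    event=event,
                    mz=np.array([p[0] for p in peaks]),
                    intensity=np.array([p[1] for p in peaks]),
                )
            )
    return Run(spectra, RunMetadata(run_id=run_id, scan_range=mz_range))
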