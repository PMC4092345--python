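"""Shared fixtures: small simulated screens reused across test modules.

Screens are generated once per session; individual tests slice what they
need. ``full_run`` executes the complete pipeline at library scale and
backs the end-to-end property tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from qhts_er import ScreenConfig, NoiseModel, generate_library, assemble_runs
from qhts_er.activity_call import call_screen, replicate_calls
from qhts_er.curve_fit import fit_screen
from qhts_er.normalize_qc import normalize_screen
from qhts_er.synthetic_screen import library_frame, truth_table

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class Screen:
    """One simulated screen with all intermediate tables."""

    def __init__(self, config: ScreenConfig):
        self.config = config
        self.library = generate_library(config)
        self.library_df = library_frame(self.library)
        self.truth = truth_table(self.library)
        self.raw = assemble_runs(self.library, config)
        self.normalized, self.plate_stats = normalize_screen(self.raw)
        self.fits = fit_screen(self.normalized, config)
        self.calls = call_screen(self.fits, self.normalized, config)
        self.replicates = replicate_calls(self.fits)


@pytest.fixture(scope="session")
def screen_default() -> Screen:
    """Default-noise screen at reduced library size."""
    return Screen(ScreenConfig(n_compounds=150, n_duplicates=40, seed=5))


@pytest.fixture(scope="session")
def screen_zero() -> Screen:
    """Noise-free screen: every downstream stage should be exact."""
    return Screen(
        ScreenConfig(n_compounds=150, n_duplicates=40, seed=7, noise=NoiseModel(0, 0, 0))
    )


@pytest.fixture(scope="session")
def full_run(tmp_path_factory) -> dict:
    """Full pipeline at the default library size (1,000 compounds)."""
    from qhts_er.pipeline import run_all

    outdir = tmp_path_factory.mktemp("full_run")
    config = ScreenConfig(seed=11)
    manifest = run_all(config, outdir)
    return {"config": config, "outdir": outdir, "manifest": manifest}


@pytest.fixture()
def grid15() -> np.ndarray:
    from qhts_er import concentration_grid

    return concentration_grid(15, 1.1e-9, 9.2e-5)


def load_csv(outdir, name, **kw) -> pd.DataFrame:
    if name == "fits.csv":
        kw.setdefault("dtype", {"curve_class": str})
    return pd.read_csv(outdir / name, **kw)
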