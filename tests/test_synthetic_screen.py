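"""Generator: concentration grid, library ground truth, plate assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qhts_er import (
    NoiseModel,
    ScreenConfig,
    assemble_runs,
    concentration_grid,
    generate_library,
    simulate_response,
)
from qhts_er.assays import ASSAY_PARAMS
from qhts_er.config import ConfigurationError, DEFAULT_MIXTURE, TRUTH_CLASSES
from qhts_er.curve_fit import fit_hill
from qhts_er.synthetic_screen import (
    SizingError,
    fingerprint_frame,
    library_frame,
    mean_signal,
)


# ------------------------------------------------------------------ grid
class TestConcentrationGrid:
    def test_titration_endpoints_and_step_ratio(self, grid15):
        assert grid15[0] == pytest.approx(1.1e-9)
        assert grid15[-1] == pytest.approx(9.2e-5)
        expected_ratio = (9.2e-5 / 1.1e-9) ** (1 / 14)
        assert grid15[1] / grid15[0] == pytest.approx(expected_ratio, rel=1e-12)
        assert round(expected_ratio, 3) == 2.247

    def test_two_points_is_exactly_the_endpoints(self):
        assert np.allclose(concentration_grid(2, 1e-9, 1e-4), [1e-9, 1e-4])

    @given(
        n=st.integers(3, 40),
        lo=st.floats(1e-12, 1e-6),
        fold=st.floats(10.0, 1e6),
    )
    def test_series_is_geometric(self, n, lo, fold):
        g = concentration_grid(n, lo, lo * fold)
        ratios = g[1:] / g[:-1]
        assert np.all(np.abs(ratios / ratios[0] - 1) < 1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            concentration_grid(1, 1e-9, 1e-4)
        with pytest.raises(ValueError):
            concentration_grid(5, 1e-4, 1e-9)


# --------------------------------------------------------------- library
class TestLibrary:
    def test_same_seed_reproduces_identical_library(self):
        cfg = ScreenConfig(n_compounds=200, n_duplicates=20, seed=7)
        a, b = generate_library(cfg), generate_library(cfg)
        pd.testing.assert_frame_equal(library_frame(a), library_frame(b))
        pd.testing.assert_frame_equal(fingerprint_frame(a), fingerprint_frame(b))

    def test_all_inactive_mixture_yields_no_pharmacology(self):
        mixture = {c: 0.0 for c in TRUTH_CLASSES}
        mixture["inactive"] = 1.0
        cfg = ScreenConfig(
            n_compounds=60, n_duplicates=6, mixture=mixture, seed=1,
            planted_agonist_family=0, planted_confound_family=0,
        )
        lib = generate_library(cfg)
        assert all(r.truth_class == "inactive" for r in lib)
        for r in lib:
            assert r.log_rba is None or r.log_rba < -3

    def test_class_counts_match_independent_redraw(self):
        # oracle: replay the generator's class draw with the same seeded
        # stream and compare the multinomial outcome
        cfg = ScreenConfig(n_compounds=1000, seed=7)
        lib = generate_library(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([7, 1]))
        classes = [c for c in TRUTH_CLASSES if c in cfg.mixture]
        probs = np.array([cfg.mixture[c] for c in classes])
        expected = rng.choice(len(classes), size=1000, p=probs / probs.sum())
        observed = [r.truth_class for r in lib]
        assert observed == [classes[k] for k in expected]

    def test_mixture_must_sum_to_one(self):
        bad = dict(DEFAULT_MIXTURE)
        bad["inactive"] = 0.5
        with pytest.raises(ConfigurationError):
            ScreenConfig(mixture=bad)

    def test_ground_truth_invariants(self):
        cfg = ScreenConfig(n_compounds=400, n_duplicates=40, seed=3)
        lib = generate_library(cfg)
        bits = {len(r.fingerprint) for r in lib}
        assert bits == {cfg.fingerprint_bits}
        assert sum(r.is_duplicate_control for r in lib) == 40
        for r in lib:
            for assay_id, t in r.channel_truth.items():
                assert 0.1 * cfg.c_min <= t["ac50"] <= 10 * cfg.c_max
                assert abs(t["efficacy"]) <= 150
            if r.cytotox_ac50 is not None:
                assert 0.1 * cfg.c_min <= r.cytotox_ac50 <= 10 * cfg.c_max

    def test_selective_modulators_flip_direction_between_platforms(self):
        cfg = ScreenConfig(n_compounds=600, seed=9)
        selmod = [r for r in generate_library(cfg)
                  if r.truth_class == "selective_modulator"]
        assert selmod
        for r in selmod:
            assert r.channel_truth["luc_agonist"]["efficacy"] > 0
            assert r.channel_truth["bla_antagonist"]["efficacy"] < 0

    def test_reference_set_composition(self):
        cfg = ScreenConfig(n_compounds=1000, seed=4)
        lib = generate_library(cfg)
        counts = library_frame(lib)["reference_label"].value_counts()
        assert counts["strong"] == 3
        assert counts["moderate_antagonist"] == 6
        assert counts["weak"] == 15
        assert counts["negative"] == 5
        assert counts.drop("none").sum() == 39


# ------------------------------------------------------------- responses
class TestResponses:
    def test_inactive_compound_is_flat_at_control_level(self, grid15):
        cfg = ScreenConfig(n_compounds=30, n_duplicates=3, seed=2)
        rec = next(r for r in generate_library(cfg) if r.truth_class == "inactive")
        tit = simulate_response(rec, "bla_agonist", grid15, NoiseModel(0, 0, 0),
                                np.random.default_rng(0))
        assert np.allclose(tit.signal, ASSAY_PARAMS["bla_agonist"].background)

    def test_agonist_half_maximal_at_its_ac50(self, grid15):
        cfg = ScreenConfig(n_compounds=200, n_duplicates=20, seed=2)
        rec = next(r for r in generate_library(cfg)
                   if r.truth_class == "full_agonist")
        truth = rec.channel_truth["luc_agonist"]
        sig = mean_signal(rec, "luc_agonist", np.array([truth["ac50"]]))
        base = ASSAY_PARAMS["luc_agonist"].background
        span = base * (ASSAY_PARAMS["luc_agonist"].s_b - 1)
        top_effect = span * truth["efficacy"] / 100.0
        assert sig[0] - base == pytest.approx(top_effect / 2, rel=1e-9)

    def test_cytotoxicity_shares_ac50_across_channels(self, grid15):
        cfg = ScreenConfig(n_compounds=300, n_duplicates=30, seed=2)
        rec = next(r for r in generate_library(cfg)
                   if r.truth_class == "cytotoxic_only")
        fits = {}
        for assay in ("luc_antagonist", "luc_viability"):
            tit = simulate_response(rec, assay, grid15, NoiseModel(0, 0, 0),
                                    np.random.default_rng(0))
            p = ASSAY_PARAMS[assay]
            act = 100.0 * (tit.signal - p.top_signal) / (p.top_signal - p.background)
            fits[assay] = fit_hill(grid15, act)
        ratio = fits["luc_antagonist"].ac50 / fits["luc_viability"].ac50
        assert max(ratio, 1 / ratio) < 1.05

    def test_autofluorescent_offset_only_in_flagged_channels(self, grid15):
        cfg = ScreenConfig(n_compounds=400, seed=2)
        rec = next(r for r in generate_library(cfg)
                   if r.truth_class == "autofluorescent"
                   and set(r.autofluor_channels) == {"blue", "green"})
        bla = mean_signal(rec, "bla_agonist", grid15)
        luc = mean_signal(rec, "luc_agonist", grid15)
        assert bla[-1] > ASSAY_PARAMS["bla_agonist"].background * 1.2
        assert np.allclose(luc, ASSAY_PARAMS["luc_agonist"].background)


# ---------------------------------------------------------------- plates
class TestPlateAssembly:
    def test_duplicates_plated_twice_per_run(self, screen_default):
        raw = screen_default.raw
        dup_ids = set(
            screen_default.library_df.loc[
                screen_default.library_df["is_duplicate_control"], "compound_id"
            ]
        )
        one_assay = raw[(raw["assay_id"] == "bla_agonist") & (raw["role"] == "sample")]
        per_run = one_assay.groupby(["compound_id", "run", "conc_idx"]).size()
        for cid in dup_ids:
            assert per_run.loc[cid].eq(2).all()
        across = one_assay[one_assay["conc_idx"] == 0].groupby("compound_id").size()
        for cid in dup_ids:
            assert across[cid] == 2 * screen_default.config.n_runs

    def test_well_positions_permuted_between_runs(self, screen_default):
        raw = screen_default.raw
        sample = raw[(raw["assay_id"] == "bla_agonist") & (raw["role"] == "sample")
                     & (raw["conc_idx"] == 0) & (raw["instance"] == 0)]
        wells = {
            run: grp.set_index("compound_id")["well"].to_dict()
            for run, grp in sample.groupby("run")
        }
        assert wells[1] != wells[2] != wells[3]
        assert wells[1] != wells[3]

    def test_same_seed_reproduces_identical_plates(self):
        cfg = ScreenConfig(n_compounds=40, n_duplicates=4, seed=13)
        lib = generate_library(cfg)
        pd.testing.assert_frame_equal(assemble_runs(lib, cfg), assemble_runs(lib, cfg))

    def test_control_layout_present_on_every_plate(self, screen_default):
        raw = screen_default.raw
        by_plate = raw.groupby("plate_id")["role"].value_counts().unstack(fill_value=0)
        assert (by_plate["pos"] == 32).all()
        assert (by_plate["neg"] >= 16).all()

    def test_raw_signals_strictly_positive(self, screen_default):
        assert (screen_default.raw["signal"] > 0).all()

    def test_oversized_library_raises_sizing_error(self):
        cfg = ScreenConfig(n_compounds=30, n_duplicates=3, seed=1,
                           plate_rows=4, plate_cols=12)
        with pytest.raises(SizingError):
            assemble_runs(generate_library(cfg), cfg)
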