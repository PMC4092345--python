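"""Decision tree, replicate reconciliation, duplicate concordance."""

import numpy as np
import pytest

from qhts_er.activity_call import (
    OUTCOMES,
    call_assay,
    duplicate_concordance,
    outcome_distribution,
    reconcile_replicates,
)


def rep(curve_class, direction="activation", ac50=1e-7, eff=100.0,
        converged=None, max_resp=None):
    """Fit-table row for one replicate."""
    if converged is None:
        converged = curve_class != "4"
    # bottom is the low-concentration asymptote, top the high-concentration one
    top = eff if direction == "activation" else -eff
    bottom = 0.0
    if curve_class == "4":
        direction, top, bottom, ac50 = "none", 0.0, 0.0, float("nan")
    return {
        "curve_class": curve_class, "direction": direction, "ac50_M": ac50,
        "hill_coef": 1.2, "top": top, "bottom": bottom,
        "efficacy": abs(top - bottom), "converged": converged,
        "max_abs_resp": max_resp if max_resp is not None else abs(top - bottom),
    }


CLEAN_VIABILITY = [rep("4")] * 3


def cytotox_viability(ac50=1e-7):
    return [rep("1.1", "inhibition", ac50, 100.0)] * 3


class TestCallAssay:
    def test_three_clean_activation_curves_are_active_agonist(self):
        out = call_assay("bla_agonist", [rep("1.1")] * 3, CLEAN_VIABILITY)
        assert out.outcome == "active_agonist"
        assert out.potency == pytest.approx(1e-7)

    def test_three_flat_curves_are_inactive(self):
        assert call_assay("luc_agonist", [rep("4")] * 3).outcome == "inactive"

    def test_antagonism_with_matched_cytotoxicity_is_demoted(self):
        reps = [rep("1.1", "inhibition", 1e-7)] * 3
        out = call_assay("bla_antagonist", reps, cytotox_viability(2e-7))
        assert out.outcome == "inconclusive_antagonist_cytotox"

    def test_antagonism_with_distant_cytotoxicity_stays_active(self):
        reps = [rep("1.1", "inhibition", 1e-8)] * 3
        out = call_assay("bla_antagonist", reps, cytotox_viability(5e-5))
        assert out.outcome == "active_antagonist"

    def test_agonist_mode_never_uses_cytotox_category(self):
        # no viability readout is multiplexed with agonist-mode assays
        reps = [rep("1.1", "inhibition", 1e-7)] * 3
        out = call_assay("bla_agonist", reps, viability=None)
        assert out.outcome == "active_antagonist"

    def test_fluorescent_activation_in_bla_is_demoted(self):
        profile = (np.geomspace(1.1e-9, 9.2e-5, 15), np.linspace(0, 80, 15))
        out = call_assay("bla_agonist", [rep("1.1")] * 3,
                         autofluor_profile=profile)
        assert out.outcome == "inconclusive_agonist_autofluor"

    def test_luminescent_platform_ignores_autofluorescence(self):
        out = call_assay("luc_agonist", [rep("1.1")] * 3, autofluor_profile=None)
        assert out.outcome == "active_agonist"

    def test_single_active_against_two_flat_is_curve_inconclusive(self):
        out = call_assay("bla_agonist", [rep("1.1"), rep("4"), rep("4")])
        assert out.outcome == "inconclusive_agonist_curve"

    def test_weak_curves_are_curve_inconclusive_with_direction(self):
        out = call_assay("bla_antagonist",
                         [rep("2.2", "inhibition"), rep("3", "inhibition"), rep("4")],
                         CLEAN_VIABILITY)
        assert out.outcome == "inconclusive_antagonist_curve"

    def test_conflicting_conclusive_directions_are_inconclusive(self):
        reps = [rep("1.1", "activation"), rep("1.1", "inhibition"),
                rep("1.1", "activation")]
        assert call_assay("luc_agonist", reps).outcome == "inconclusive"

    def test_activation_in_antagonist_mode_uses_agonist_labels(self):
        out = call_assay("luc_antagonist", [rep("1.1", "activation")] * 3,
                         CLEAN_VIABILITY)
        assert out.outcome == "active_agonist"
        out2 = call_assay("luc_antagonist", [rep("1.1", "activation", 1e-7)] * 3,
                          cytotox_viability(1e-7))
        assert out2.outcome == "inconclusive_agonist_cytotox"

    def test_no_replicates_rejected(self):
        with pytest.raises(ValueError):
            call_assay("bla_agonist", [])


class TestDecisionTreeExhaustive:
    CLASSES = ("1.1", "1.2", "2.1", "2.2", "3", "4")

    def all_outcomes(self, assay_id, viability, profile):
        import itertools

        results = {}
        for triple in itertools.product(self.CLASSES, repeat=3):
            reps = [
                rep(c, "inhibition", 1e-7, 90.0) if c != "4" else rep("4")
                for c in triple
            ]
            out = call_assay(assay_id, reps, viability, profile)
            results[triple] = out.outcome
        return results

    def test_every_combination_maps_to_exactly_one_outcome(self):
        profiles = [None, (np.geomspace(1e-9, 9e-5, 15), np.full(15, 60.0))]
        viabilities = [None, CLEAN_VIABILITY, cytotox_viability(1e-7)]
        for viability in viabilities:
            for profile in profiles:
                results = self.all_outcomes("bla_antagonist", viability, profile)
                assert len(results) == 216
                assert set(results.values()) <= set(OUTCOMES)

    def test_counter_screens_never_promote(self):
        clean = self.all_outcomes("bla_antagonist", CLEAN_VIABILITY, None)
        demoted_via = self.all_outcomes("bla_antagonist", cytotox_viability(1e-7), None)
        profile = (np.geomspace(1e-9, 9e-5, 15), np.full(15, 60.0))
        demoted_af = self.all_outcomes("bla_antagonist", CLEAN_VIABILITY, profile)
        active = {"active_agonist", "active_antagonist"}
        for triple, base in clean.items():
            for stressed in (demoted_via[triple], demoted_af[triple]):
                if base not in active:
                    assert stressed not in active
                elif stressed != base:
                    assert stressed.startswith("inconclusive")


class TestReconcile:
    def test_three_identical_actives_match_with_unit_fold(self):
        call = reconcile_replicates([rep("1.1", ac50=1e-7)] * 3)
        assert call.category == "active_match"
        assert call.ac50_fold_change == pytest.approx(1.0)

    def test_three_inactives_match(self):
        assert reconcile_replicates([rep("4")] * 3).category == "inactive_match"

    def test_high_quality_active_against_flats_is_mismatch(self):
        call = reconcile_replicates([rep("1.1"), rep("4"), rep("4")])
        assert call.category == "mismatch"

    def test_incomplete_active_against_flats_is_inconclusive(self):
        call = reconcile_replicates([rep("2.1"), rep("4"), rep("4")])
        assert call.category == "inconclusive"

    def test_fold_change_spans_replicate_ac50s(self):
        call = reconcile_replicates(
            [rep("1.1", ac50=1e-7), rep("1.1", ac50=4e-7), rep("1.2", ac50=2e-7)]
        )
        assert call.ac50_fold_change == pytest.approx(4.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            reconcile_replicates([rep("1.1")])


class TestDuplicates:
    def test_zero_noise_duplicates_all_match_with_perfect_correlation(self, screen_zero):
        table, _ = duplicate_concordance(
            screen_zero.fits, screen_zero.library_df,
            screen_zero.normalized, screen_zero.config,
        )
        assert set(table["category"]) <= {"active_match", "inactive_match", "inconclusive"}
        assert (table["category"] == "mismatch").sum() == 0
        pairs = table.dropna(subset=["log_ac50_0", "log_ac50_1"])
        assert len(pairs) >= 20
        r2 = np.corrcoef(pairs["log_ac50_0"], pairs["log_ac50_1"])[0, 1] ** 2
        assert r2 > 0.999

    def test_default_noise_duplicates_correlate(self, screen_default):
        table, _ = duplicate_concordance(
            screen_default.fits, screen_default.library_df,
            screen_default.normalized, screen_default.config,
        )
        pairs = table.dropna(subset=["log_ac50_0", "log_ac50_1"])
        assert len(pairs) >= 50
        r2 = np.corrcoef(pairs["log_ac50_0"], pairs["log_ac50_1"])[0, 1] ** 2
        assert r2 > 0.7

    def test_cytotox_demoted_member_makes_pair_inconclusive(self, screen_zero):
        table, _ = duplicate_concordance(
            screen_zero.fits, screen_zero.library_df,
            screen_zero.normalized, screen_zero.config,
        )
        cyto = screen_zero.library_df.query(
            "is_duplicate_control and truth_class == 'cytotoxic_only'"
        )["compound_id"]
        sub = table[table["compound_id"].isin(cyto)
                    & table["assay_id"].str.endswith("antagonist")]
        assert len(sub) > 0
        assert (sub["category"] == "inconclusive").all()


class TestOutcomeDistribution:
    def test_percentages_sum_to_100(self, screen_default):
        dist = outcome_distribution(screen_default.calls)
        sums = dist.groupby("assay_id")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_all_inactive_screen_is_100_percent_inactive(self):
        import pandas as pd

        calls = pd.DataFrame({
            "compound_id": [f"C{i}" for i in range(5)],
            "assay_id": ["bla_agonist"] * 5,
            "outcome": ["inactive"] * 5,
        })
        dist = outcome_distribution(calls)
        assert dist.loc[0, "percent"] == 100.0

    def test_active_fraction_tracks_truth_mixture(self, screen_default):
        cfg = screen_default.config
        truth_active = (cfg.mixture["full_agonist"] + cfg.mixture["partial_agonist"]
                        + cfg.mixture["selective_modulator"]) * 100
        calls = screen_default.calls
        luc = calls[calls["assay_id"] == "luc_agonist"]
        observed = 100 * (luc["outcome"] == "active_agonist").mean()
        assert abs(observed - truth_active) <= 5.0
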