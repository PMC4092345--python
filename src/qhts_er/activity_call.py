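"""Activity-outcome assignment and replicate reconciliation.

Each (compound, assay) is assigned exactly one outcome by a decision tree
over the triplicate curve classes, with two counter-screens: a multiplexed
cell-viability readout demotes antagonist-mode calls explained by
cytotoxicity, and a three-wavelength autofluorescence profile demotes
apparent activation in the fluorescence-based (bla) channels. Demotions
only ever move a call from active to inconclusive, never the reverse.

Outcome vocabulary (antagonist-mode assays use the full set; agonist-mode
assays never see the cytotoxicity category because no viability readout is
multiplexed with them):

    active_agonist, inconclusive_agonist_curve, inconclusive_agonist_autofluor,
    inconclusive_agonist_cytotox, active_antagonist,
    inconclusive_antagonist_curve, inconclusive_antagonist_cytotox,
    inconclusive, inactive
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import AUTOFLUOR_CHANNELS_FOR, MAIN_ASSAYS, MODE_ASSAYS, VIABILITY_FOR, mode_of, platform_of
from .config import CallConfig, ScreenConfig
from .curve_fit import CONCLUSIVE_ACTIVE, HIGH_QUALITY

OUTCOMES = (
    "active_agonist",
    "inconclusive_agonist_curve",
    "inconclusive_agonist_autofluor",
    "inconclusive_agonist_cytotox",
    "active_antagonist",
    "inconclusive_antagonist_curve",
    "inconclusive_antagonist_cytotox",
    "inconclusive",
    "inactive",
)

REPLICATE_CATEGORIES = ("active_match", "inactive_match", "inconclusive", "mismatch")

#: minimum autofluorescence response (percent) treated as real even when the
#: configured noise level is zero
AUTOFLUOR_FLOOR = 5.0


@dataclass
class ActivityOutcome:
    compound_id: str
    assay_id: str
    outcome: str
    potency: float | None = None   # molar, median over conclusive replicates
    efficacy: float | None = None  # signed percent, median over replicates


@dataclass
class ReplicateCall:
    category: str
    ac50_fold_change: float | None = None


def _hill_value(row: dict, c: float) -> float:
    """Fitted model response at concentration c for a fit-table row."""
    return row["bottom"] + (row["top"] - row["bottom"]) / (
        1.0 + (row["ac50_M"] / c) ** row["hill_coef"]
    )


def _geomedian(values) -> float | None:
    vals = [v for v in values if v and np.isfinite(v)]
    if not vals:
        return None
    return float(10 ** np.median(np.log10(vals)))


def _viability_conflict(
    ac50: float, viability: list[dict], noise_sd: float, cfg: CallConfig
) -> bool:
    """Does the viability readout explain an antagonist-mode signal?

    True when the (replicate-median) viability curve shows real inhibition
    with an AC50 within the configured fold-window of the candidate AC50,
    or with >= the configured viability loss at the candidate AC50.
    """
    threshold = max(3.0 * noise_sd, 20.0)
    real = [
        v for v in viability
        if v.get("converged") and v.get("direction") == "inhibition"
        and v.get("max_abs_resp", 0.0) >= threshold
    ]
    if len(real) < 2:  # viability loss must itself be reproducible
        return False
    v_ac50 = _geomedian(v["ac50_M"] for v in real)
    if v_ac50 is not None and ac50 is not None:
        ratio = max(v_ac50, ac50) / min(v_ac50, ac50)
        if ratio <= cfg.cytotox_ac50_window:
            return True
    if ac50 is not None:
        losses = [_hill_value(v, ac50) for v in real]
        if np.median(losses) <= -cfg.viability_loss_pct:
            return True
    return False


def _autofluor_conflict(
    ac50: float | None,
    profile: tuple[np.ndarray, np.ndarray] | None,
    noise_sd: float,
    cfg: CallConfig,
) -> bool:
    """Is the compound fluorescent in the assay's detection channels at the
    concentrations where it appears active?"""
    if profile is None:
        return False
    conc, resp = profile
    mask = np.ones(len(conc), bool) if ac50 is None else conc >= ac50 / 3.0
    if not mask.any():
        mask[-1] = True
    threshold = max(cfg.autofluor_sd_multiplier * noise_sd, AUTOFLUOR_FLOOR)
    return bool(np.nanmax(np.asarray(resp)[mask]) > threshold)


def call_assay(
    assay_id: str,
    replicates: list[dict],
    viability: list[dict] | None = None,
    autofluor_profile: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 7.0,
    cfg: CallConfig | None = None,
    compound_id: str = "",
) -> ActivityOutcome:
    """Assign one activity outcome from triplicate curve classes.

    ``replicates`` / ``viability`` are fit-table rows (dicts with
    curve_class, direction, ac50_M, hill_coef, top, bottom, efficacy,
    converged, max_abs_resp). ``autofluor_profile`` is (concentrations,
    percent response) in the platform's detection channels, or None for
    luminescent platforms.
    """
    if not replicates:
        raise ValueError("no replicate fits supplied")
    cfg = cfg or CallConfig()
    mode = mode_of(assay_id)

    concl_up = [r for r in replicates
                if r["curve_class"] in CONCLUSIVE_ACTIVE and r["direction"] == "activation"]
    concl_dn = [r for r in replicates
                if r["curve_class"] in CONCLUSIVE_ACTIVE and r["direction"] == "inhibition"]
    n_inactive = sum(r["curve_class"] == "4" for r in replicates)
    majority = max(2, (len(replicates) + 1) // 2) if len(replicates) > 1 else 1

    def summarize(reps):
        pot = _geomedian(r["ac50_M"] for r in reps)
        effs = [r["top"] - r["bottom"] for r in reps if r.get("converged")]
        eff = float(np.median(effs)) if effs else None
        return pot, eff

    if concl_up and concl_dn:
        # conclusive but conflicting directions across replicates
        return ActivityOutcome(compound_id, assay_id, "inconclusive")

    if len(concl_up) >= majority:
        pot, eff = summarize(concl_up)
        outcome = "active_agonist"
        if mode == "antagonist" and viability and _viability_conflict(
            pot, viability, noise_sd, cfg
        ):
            outcome = "inconclusive_agonist_cytotox"
        elif _autofluor_conflict(pot, autofluor_profile, noise_sd, cfg):
            outcome = "inconclusive_agonist_autofluor"
        return ActivityOutcome(compound_id, assay_id, outcome, pot, eff)

    if len(concl_dn) >= majority:
        pot, eff = summarize(concl_dn)
        outcome = "active_antagonist"
        if mode == "antagonist" and viability and _viability_conflict(
            pot, viability, noise_sd, cfg
        ):
            outcome = "inconclusive_antagonist_cytotox"
        return ActivityOutcome(compound_id, assay_id, outcome, pot, eff)

    if n_inactive >= majority and not concl_up and not concl_dn:
        return ActivityOutcome(compound_id, assay_id, "inactive")

    # weak/conflicting evidence: poor-curve-quality inconclusive in the
    # direction the non-flat replicates point to
    directions = {r["direction"] for r in replicates if r["curve_class"] != "4"}
    directions.discard("none")
    if directions == {"activation"}:
        return ActivityOutcome(compound_id, assay_id, "inconclusive_agonist_curve")
    if directions == {"inhibition"}:
        return ActivityOutcome(compound_id, assay_id, "inconclusive_antagonist_curve")
    return ActivityOutcome(compound_id, assay_id, "inconclusive")


# --------------------------------------------------------------------------
# replicate reconciliation
# --------------------------------------------------------------------------

def reconcile_replicates(replicates: list[dict]) -> ReplicateCall:
    """Reproducibility category for one compound's replicate fits.

    mismatch requires a genuine high-confidence conflict: a complete
    high-quality curve (1.1/1.2) in one replicate against a flat class-4 in
    another, or opposed high-quality directions.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to reconcile")
    hq_up = [r for r in replicates
             if r["curve_class"] in HIGH_QUALITY and r["direction"] == "activation"]
    hq_dn = [r for r in replicates
             if r["curve_class"] in HIGH_QUALITY and r["direction"] == "inhibition"]
    concl_up = [r for r in replicates
                if r["curve_class"] in CONCLUSIVE_ACTIVE and r["direction"] == "activation"]
    concl_dn = [r for r in replicates
                if r["curve_class"] in CONCLUSIVE_ACTIVE and r["direction"] == "inhibition"]
    n_inactive = sum(r["curve_class"] == "4" for r in replicates)

    if ((hq_up or hq_dn) and n_inactive > 0) or (hq_up and hq_dn):
        return ReplicateCall("mismatch")
    for group in (concl_up, concl_dn):
        if len(group) >= 2:
            ac50s = [g["ac50_M"] for g in group if np.isfinite(g["ac50_M"])]
            fold = max(ac50s) / min(ac50s) if len(ac50s) >= 2 else None
            return ReplicateCall("active_match", fold)
    if n_inactive >= 2 and not concl_up and not concl_dn:
        return ReplicateCall("inactive_match")
    return ReplicateCall("inconclusive")


ACTIVE_OUTCOMES = {"active_agonist", "active_antagonist"}


def _viability_instance_call(reps: list[dict]) -> tuple[str, float | None]:
    """Outcome-style verdict for a viability channel instance (3 run fits)."""
    call = reconcile_replicates(reps) if len(reps) >= 2 else ReplicateCall("inconclusive")
    if call.category == "active_match":
        pot = _geomedian(
            r["ac50_M"] for r in reps if r["curve_class"] in CONCLUSIVE_ACTIVE
        )
        return "active_antagonist", pot
    if call.category == "inactive_match":
        return "inactive", None
    return "inconclusive", None


def duplicate_concordance(
    fits: pd.DataFrame,
    library: pd.DataFrame,
    normalized: pd.DataFrame | None = None,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reproducibility of the intra-plate duplicated compounds.

    Each plate instance of a duplicated compound gets its own outcome-level
    call (full decision tree, counter-screens included, over its three run
    fits); the pair is then categorized: both active in the same direction
    -> active_match, both inactive -> inactive_match, conclusive active vs
    conclusive inactive -> mismatch, anything touched by a demotion or weak
    curve -> inconclusive. Returns the pair table and per-assay R^2 of
    log10 AC50 over active-matched pairs.
    """
    config = config or ScreenConfig()
    noise_sd = config.noise.percent_sd
    profiles = autofluor_profiles(normalized) if normalized is not None else {}
    dup_ids = sorted(set(library.loc[library["is_duplicate_control"], "compound_id"]))
    sub = fits[fits["compound_id"].isin(dup_ids)]
    fit_map: dict[tuple, list[dict]] = {}
    for row in sub.to_dict("records"):
        key = (row["compound_id"], row["assay_id"], row["instance"])
        fit_map.setdefault(key, []).append(row)

    rows = []
    for cid in dup_ids:
        for assay_id in MAIN_ASSAYS:
            per_instance = []
            for inst in (0, 1):
                reps = fit_map.get((cid, assay_id, inst))
                if not reps:
                    per_instance = []
                    break
                if assay_id in VIABILITY_FOR.values():
                    per_instance.append(_viability_instance_call(reps))
                else:
                    via = fit_map.get((cid, VIABILITY_FOR.get(assay_id, ""), inst))
                    profile = profiles.get(platform_of(assay_id), {}).get(cid)
                    res = call_assay(
                        assay_id, reps, viability=via, autofluor_profile=profile,
                        noise_sd=noise_sd, cfg=config.call, compound_id=cid,
                    )
                    per_instance.append((res.outcome, res.potency))
            if not per_instance:
                continue
            (out0, pot0), (out1, pot1) = per_instance
            if out0 in ACTIVE_OUTCOMES and out0 == out1:
                category = "active_match"
            elif out0 == out1 == "inactive":
                category = "inactive_match"
            elif {out0, out1} <= ACTIVE_OUTCOMES | {"inactive"} and out0 != out1:
                category = "mismatch"
            else:
                category = "inconclusive"
            matched = category == "active_match" and pot0 and pot1
            rows.append({
                "compound_id": cid, "assay_id": assay_id, "category": category,
                "outcome_0": out0, "outcome_1": out1,
                "ac50_fold_change": (
                    max(pot0, pot1) / min(pot0, pot1) if matched else np.nan
                ),
                "log_ac50_0": np.log10(pot0) if matched else np.nan,
                "log_ac50_1": np.log10(pot1) if matched else np.nan,
            })
    table = pd.DataFrame(rows, columns=[
        "compound_id", "assay_id", "category", "outcome_0", "outcome_1",
        "ac50_fold_change", "log_ac50_0", "log_ac50_1",
    ])

    def _r2(grp: pd.DataFrame) -> float:
        g = grp.dropna(subset=["log_ac50_0", "log_ac50_1"])
        if len(g) < 3 or g["log_ac50_0"].std() == 0:
            return float("nan")
        return float(np.corrcoef(g["log_ac50_0"], g["log_ac50_1"])[0, 1] ** 2)

    r2 = (
        table.groupby("assay_id").apply(_r2, include_groups=False)
        if len(table) else pd.Series(dtype=float)
    )
    return table, r2


def outcome_distribution(calls: pd.DataFrame) -> pd.DataFrame:
    """Percent of the library in each outcome category, per assay."""
    out = (
        calls.groupby("assay_id")["outcome"]
        .value_counts(normalize=True)
        .mul(100.0)
        .rename("percent")
        .reset_index()
    )
    return out


# --------------------------------------------------------------------------
# screen-level driver
# --------------------------------------------------------------------------

def autofluor_profiles(normalized: pd.DataFrame) -> dict[str, dict]:
    """Per-compound autofluorescence profile for each platform.

    Combines the platform's detection wavelengths (max across channels) and
    medians over runs. Returns {platform: {compound_id: (conc, resp)}}.
    """
    out: dict[str, dict] = {}
    af = normalized[normalized["assay_id"].str.startswith("autofluor")]
    if af.empty:
        return out
    for plat, channels in AUTOFLUOR_CHANNELS_FOR.items():
        if not channels:
            continue
        ids = [f"autofluor_{ch}" for ch in channels]
        sub = af[af["assay_id"].isin(ids)]
        prof = (
            sub.groupby(["compound_id", "conc_idx"])
            .agg(conc=("concentration_M", "first"), resp=("activity", "median"))
            .reset_index()
        )
        out[plat] = {
            cid: (g["conc"].to_numpy(float), g["resp"].to_numpy(float))
            for cid, g in prof.groupby("compound_id")
        }
    return out


def call_screen(
    fits: pd.DataFrame, normalized: pd.DataFrame, config: ScreenConfig
) -> pd.DataFrame:
    """Final per-(compound, mode-assay) outcomes for a whole screen."""
    noise_sd = config.noise.percent_sd
    profiles = autofluor_profiles(normalized)
    primary = fits[fits["instance"] == 0]
    fit_map: dict[tuple[str, str], list[dict]] = {}
    for row in primary.to_dict("records"):
        fit_map.setdefault((row["compound_id"], row["assay_id"]), []).append(row)

    compounds = sorted({cid for cid, _ in fit_map})
    rows = []
    for cid in compounds:
        for assay_id in MODE_ASSAYS:
            reps = fit_map.get((cid, assay_id))
            if not reps:
                continue
            via = fit_map.get((cid, VIABILITY_FOR.get(assay_id, "")), None)
            profile = profiles.get(platform_of(assay_id), {}).get(cid)
            res = call_assay(
                assay_id, reps, viability=via, autofluor_profile=profile,
                noise_sd=noise_sd, cfg=config.call, compound_id=cid,
            )
            rows.append({
                "compound_id": cid, "assay_id": assay_id,
                "outcome": res.outcome, "potency_M": res.potency,
                "efficacy_pct": res.efficacy,
            })
    return pd.DataFrame(rows)


def replicate_calls(fits: pd.DataFrame) -> pd.DataFrame:
    """Triplicate-run reproducibility categories for every main channel."""
    primary = fits[(fits["instance"] == 0) & fits["assay_id"].isin(MAIN_ASSAYS)]
    rows = []
    for (cid, assay_id), grp in primary.groupby(["compound_id", "assay_id"], sort=False):
        if len(grp) < 2:
            continue
        call = reconcile_replicates(grp.to_dict("records"))
        rows.append({
            "compound_id": cid, "assay_id": assay_id,
            "category": call.category, "ac50_fold_change": call.ac50_fold_change,
        })
    return pd.DataFrame(rows)
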