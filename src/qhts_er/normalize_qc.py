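"""Control-based plate normalization and plate-performance statistics.

Raw signals are mapped to percent activity relative to the intra-plate
controls: in agonist mode 0% is the negative control and 100% the
positive-control maximum; in antagonist and viability modes 0% is the
stimulated / untreated control and -100% full suppression to baseline.
Plate quality is summarized by the signal-to-background ratio, the
negative-control coefficient of variation, and the Z' factor
1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg|, with the embedded 16-point
duplicate positive-control titration refit on every plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import ASSAY_PARAMS
from .curve_fit import HillFit, fit_hill

#: conventional pass thresholds; failing plates are flagged, never dropped
QC_THRESHOLDS = {"s_b": 3.0, "cv": 10.0, "z_prime": 0.5}


class QCError(ValueError):
    """Raised when a plate lacks the controls needed for normalization."""


@dataclass
class PlateStats:
    plate_id: str
    assay_id: str
    run: int
    s_b: float
    cv: float
    z_prime: float
    control_ac50: float
    control_converged: bool
    passes_qc: bool
    z_prime_defined: bool = True


def _control_levels(plate: pd.DataFrame):
    neg = plate.loc[plate["role"] == "neg", "signal"].to_numpy(float)
    pos = plate[plate["role"] == "pos"]
    if len(neg) == 0 or len(pos) == 0:
        raise QCError("plate is missing negative and/or positive control wells")
    # "positive" level = wells at the top two control concentrations
    top_concs = np.sort(pos["concentration_M"].unique())[-2:]
    pos_top = pos.loc[
        pos["concentration_M"].isin(top_concs), "signal"
    ].to_numpy(float)
    return neg, pos, pos_top


def normalize_plate(plate: pd.DataFrame) -> tuple[pd.DataFrame, PlateStats]:
    """Normalize one plate's wells and compute its performance statistics.

    ``plate`` is the long-format slice for a single plate_id (columns
    role, signal, concentration_M, ...). Returns the plate with an added
    ``activity`` column (percent) and the :class:`PlateStats`.
    """
    assay_id = plate["assay_id"].iloc[0]
    kind = ASSAY_PARAMS[assay_id].kind
    neg, pos, pos_top = _control_levels(plate)

    mu_neg, sd_neg = float(neg.mean()), float(neg.std(ddof=1))
    mu_pos, sd_pos = float(pos_top.mean()), float(pos_top.std(ddof=1))

    window = mu_pos - mu_neg
    z_defined = window != 0
    if z_defined:
        z_prime = 1.0 - 3.0 * (sd_pos + sd_neg) / abs(window)
    else:
        z_prime = float("nan")
    hi, lo = max(mu_pos, mu_neg), min(mu_pos, mu_neg)
    s_b = hi / lo if lo > 0 else float("inf")
    cv = 100.0 * sd_neg / mu_neg if mu_neg != 0 else float("nan")

    denom = window if kind == "activation" else -window
    out = plate.copy()
    if denom == 0:
        out["activity"] = float("nan")
    else:
        out["activity"] = 100.0 * (out["signal"] - mu_neg) / denom

    # refit the embedded control titration on the normalized scale
    ctrl = out[out["role"] == "pos"].sort_values("concentration_M")
    ctrl_act = ctrl["activity"].to_numpy(float)
    if np.isfinite(ctrl_act).all():
        fit = fit_hill(ctrl["concentration_M"].to_numpy(float), ctrl_act)
    else:
        fit = HillFit()
    stats = PlateStats(
        plate_id=plate["plate_id"].iloc[0],
        assay_id=assay_id,
        run=int(plate["run"].iloc[0]),
        s_b=s_b,
        cv=cv,
        z_prime=z_prime,
        control_ac50=fit.ac50 if fit.converged else float("nan"),
        control_converged=fit.converged,
        passes_qc=bool(
            z_defined
            and s_b > QC_THRESHOLDS["s_b"]
            and cv < QC_THRESHOLDS["cv"]
            and z_prime > QC_THRESHOLDS["z_prime"]
        ),
        z_prime_defined=z_defined,
    )
    return out, stats


def normalize_screen(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize every plate of a raw screen table.

    Returns (normalized sample rows, per-plate stats table).
    """
    normed, stats = [], []
    for _, plate in raw.groupby("plate_id", sort=False):
        out, st = normalize_plate(plate)
        normed.append(out[out["role"] == "sample"])
        stats.append(st)
    normalized = pd.concat(normed, ignore_index=True)[
        ["compound_id", "assay_id", "run", "instance", "plate_id",
         "conc_idx", "concentration_M", "activity"]
    ]
    stats_df = pd.DataFrame([vars(s) for s in stats])
    return normalized, stats_df


def control_titration_ac50(plate: pd.DataFrame) -> float:
    """AC50 of one plate's embedded positive-control titration (molar)."""
    _, st = normalize_plate(plate)
    if not st.control_converged:
        raise QCError(f"control titration did not converge on {st.plate_id}")
    return st.control_ac50


def control_sd_fold(stats: pd.DataFrame) -> pd.Series:
    """Per-assay geometric SD (fold) of the control AC50 across plates.

    1.0 means perfectly replicated controls; values under ~3-fold indicate
    a stable screen.
    """
    def fold(s: pd.Series) -> float:
        vals = np.log10(s.dropna().to_numpy(float))
        if len(vals) < 2:
            return 1.0
        return float(10 ** vals.std(ddof=1))

    return stats.groupby("assay_id")["control_ac50"].apply(fold)
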