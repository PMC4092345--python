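"""Four-parameter Hill fitting and categorical curve grading.

Model: y = bottom + (top - bottom) / (1 + (AC50/c)^hill), fit by bounded
nonlinear least squares on the percent-activity scale with three starts
(AC50 initialized at the quartiles of the log-concentration grid). Each fit
is graded into the qHTS curve-class convention used by the Tox21 program:

======  ==========================================================
class   meaning
======  ==========================================================
1.1     complete curve (both asymptotes in range), high efficacy
1.2     complete curve, low efficacy
2.1     incomplete curve (lower asymptote only), high efficacy
2.2     incomplete curve, low efficacy
3       single-point activity or poor fit despite real response
4       inactive (no significant response)
==========================================================================

The class drives downstream activity calling: 1.1/1.2/2.1 are treated as
conclusive activity, 2.2/3 as weak evidence, 4 as conclusive inactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .assays import MAIN_ASSAYS
from .config import ClassifyConfig, ScreenConfig

CURVE_CLASSES = ("1.1", "1.2", "2.1", "2.2", "3", "4")

CURVE_CLASS_MEANING = {
    "1.1": "complete curve, high efficacy",
    "1.2": "complete curve, low efficacy",
    "2.1": "incomplete curve, high efficacy",
    "2.2": "incomplete curve, low efficacy",
    "3": "single-point or poor-fit activity",
    "4": "inactive",
}

#: conclusive-activity classes for calling purposes
CONCLUSIVE_ACTIVE = ("1.1", "1.2", "2.1")
HIGH_QUALITY = ("1.1", "1.2")


@dataclass
class HillFit:
    ac50: float = float("nan")
    hill: float = float("nan")
    top: float = 0.0
    bottom: float = 0.0
    r2: float = 0.0
    converged: bool = False
    direction: str = "none"  # activation | inhibition | none
    masked_points: tuple = field(default_factory=tuple)
    rss: float = float("nan")
    n_points: int = 0

    def model(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ac50 / c) ** self.hill
        )


def efficacy(fit: HillFit) -> float:
    """Response span |top - bottom| in percent of the control maximum."""
    if not fit.converged:
        return 0.0
    return abs(fit.top - fit.bottom)


def potency(fit: HillFit) -> float:
    """Fitted AC50 in molar (NaN when the fit did not converge)."""
    return fit.ac50 if fit.converged else float("nan")


def _hill_curve(params: np.ndarray, logc: np.ndarray) -> np.ndarray:
    la, h, top, bottom = params
    return bottom + (top - bottom) / (1.0 + 10 ** (h * (la - logc)))


_LN10 = np.log(10.0)


def _jacobian(params: np.ndarray, logc: np.ndarray) -> np.ndarray:
    la, h, top, bottom = params
    u = 10 ** (h * (la - logc))
    f = 1.0 / (1.0 + u)
    g = u * f * f  # u / (1+u)^2
    span = top - bottom
    return np.column_stack([
        -span * _LN10 * h * g,
        -span * _LN10 * (la - logc) * g,
        f,
        1.0 - f,
    ])


def _grid_init(logc: np.ndarray, y: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Best starting point from a profiled coarse grid: for each candidate
    (log AC50, slope) shape the asymptotes are solved by linear least
    squares, which makes the search cheap and direction-agnostic."""
    slopes = np.array([0.5, 1.0, 1.5, 2.5, 4.0])
    best, best_rss = None, np.inf
    for la in starts:
        for h in slopes:
            f = 1.0 / (1.0 + 10 ** (h * (la - logc)))
            # y ~ bottom * (1 - f) + top * f
            a = np.column_stack([f, 1.0 - f])
            coef, *_ = np.linalg.lstsq(a, y, rcond=None)
            rss = float(np.sum((a @ coef - y) ** 2))
            if rss < best_rss:
                best_rss = rss
                best = np.array([la, h, coef[0], coef[1]])
    return best


def _solve(logc: np.ndarray, y: np.ndarray, bounds, x0) -> tuple[np.ndarray, float]:
    res = least_squares(
        lambda p: _hill_curve(p, logc) - y, x0,
        jac=lambda p: _jacobian(p, logc),
        bounds=bounds, method="trf", max_nfev=80,
    )
    return res.x, float(np.sum(res.fun**2))


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    allow_mask: bool = True,
    min_improvement: float = 0.2,
) -> HillFit:
    """Fit the Hill model to one titration.

    ``converged`` is False when the fit does not beat a flat (constant)
    model by at least ``min_improvement`` relative residual reduction, in
    which case direction is 'none'. One outlier point may be masked when
    doing so raises r2 by >= 0.2.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    order = np.argsort(c)
    c, y = c[order], y[order]
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")
    if not (np.isfinite(y).all() and np.isfinite(c).all() and (c > 0).all()):
        raise ValueError("responses must be finite and concentrations positive")
    logc = np.log10(c)

    la_lo, la_hi = logc[0] - 2.0, logc[-1] + 2.0
    bounds = ([la_lo, 0.3, -150.0, -150.0], [la_hi, 8.0, 150.0, 150.0])

    # multi-start: candidate AC50s spanning the grid quartiles, refined from
    # the best profiled coarse-grid shape by bounded least squares
    starts = np.quantile(logc, np.linspace(0.05, 0.95, 12))
    x0 = np.clip(_grid_init(logc, y, starts), bounds[0], bounds[1])
    try:
        best, best_rss = _solve(logc, y, bounds, x0)
    except Exception:  # pragma: no cover - optimizer failure
        best, best_rss = None, np.inf

    flat_rss = float(np.sum((y - y.mean()) ** 2))
    fit = _package(best, best_rss, flat_rss, y, min_improvement, mask=())

    if allow_mask and fit.converged and fit.r2 < 0.9 and len(c) > 4:
        resid = np.abs(_hill_curve(best, logc) - y)
        worst = int(np.argmax(resid))
        keep = np.ones(len(c), bool)
        keep[worst] = False
        try:
            x2, rss2 = _solve(logc[keep], y[keep], bounds, best)
        except Exception:  # pragma: no cover
            x2 = None
        if x2 is not None:
            flat2 = float(np.sum((y[keep] - y[keep].mean()) ** 2))
            fit2 = _package(x2, rss2, flat2, y[keep], min_improvement,
                            mask=(worst,))
            if fit2.converged and fit2.r2 - fit.r2 >= 0.2:
                fit = fit2
    return fit


def _package(x, rss, flat_rss, y, min_improvement, mask) -> HillFit:
    if x is None:
        return HillFit(n_points=len(y))
    la, h, top, bottom = x
    improvement = (flat_rss - rss) / flat_rss if flat_rss > 0 else 0.0
    converged = bool(improvement >= min_improvement and abs(top - bottom) > 1e-9)
    r2 = 1.0 - rss / flat_rss if flat_rss > 0 else 0.0
    if not converged:
        return HillFit(r2=max(r2, 0.0), converged=False, direction="none",
                       masked_points=mask, rss=rss, n_points=len(y))
    return HillFit(
        ac50=float(10**la), hill=float(h), top=float(top), bottom=float(bottom),
        r2=float(r2), converged=True,
        direction="activation" if top > bottom else "inhibition",
        masked_points=mask, rss=rss, n_points=len(y),
    )


# --------------------------------------------------------------------------
# curve classification
# --------------------------------------------------------------------------

def classify_curve(
    fit: HillFit,
    concentrations: np.ndarray,
    responses: np.ndarray,
    noise_sd: float,
    cfg: ClassifyConfig | None = None,
) -> str:
    """Grade one fitted titration into a curve class.

    ``noise_sd`` is the response noise on the percent scale; the significance
    threshold is max(noise_multiplier * noise_sd, min_response).
    """
    cfg = cfg or ClassifyConfig()
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    order = np.argsort(c)
    c, y = c[order], y[order]

    threshold = max(cfg.noise_multiplier * noise_sd, cfg.min_response)
    significant = np.abs(y) >= threshold
    if not significant.any():
        return "4"
    if significant.sum() == 1 and significant[-1]:
        return "3"  # single top-concentration response
    if not fit.converged or fit.r2 < cfg.r2_min:
        return "3"

    span = fit.top - fit.bottom
    y_lo, y_hi = fit.model(c[0]), fit.model(c[-1])
    lower_ok = abs(y_lo - fit.bottom) <= cfg.asymptote_tol * abs(span)
    upper_ok = abs(y_hi - fit.top) <= cfg.asymptote_tol * abs(span)

    eff = abs(span)
    sub = "1" if eff >= cfg.efficacy_split else "2"
    if lower_ok and upper_ok and fit.r2 >= cfg.r2_complete:
        return f"1.{sub}"
    if lower_ok:
        return f"2.{sub}"
    return "3"


# --------------------------------------------------------------------------
# screen-level fitting
# --------------------------------------------------------------------------

def _prescreen(y: np.ndarray, threshold: float) -> bool:
    """True when a series can never be graded above class 4 (its largest
    excursion is below the significance threshold), so no fit is needed."""
    return bool(np.max(np.abs(y)) < threshold)


def fit_screen(normalized: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Fit and classify every (compound, assay, run, instance) titration.

    Only the six reporter/viability channels are fit; autofluorescence
    channels are used directly as concentration profiles by the calling
    stage. Flat series are short-circuited without an optimizer call.
    """
    noise_sd = config.noise.percent_sd
    cls_cfg = config.classify
    threshold = max(cls_cfg.noise_multiplier * noise_sd, cls_cfg.min_response)
    rows = []
    sub = normalized[normalized["assay_id"].isin(MAIN_ASSAYS)]
    for (assay_id, run), grp in sub.groupby(["assay_id", "run"], sort=False):
        wide = grp.pivot_table(
            index=["compound_id", "instance"], columns="conc_idx",
            values="activity", sort=True,
        )
        conc = np.sort(grp["concentration_M"].unique())
        mat = wide.to_numpy(float)
        for (cid, inst), y in zip(wide.index, mat):
            ok = np.isfinite(y)
            if ok.sum() < 4:
                continue
            if _prescreen(y[ok], threshold):
                fit = HillFit(n_points=int(ok.sum()))
            else:
                fit = fit_hill(conc[ok], y[ok])
            klass = classify_curve(fit, conc[ok], y[ok], noise_sd, cls_cfg)
            rows.append({
                "compound_id": cid, "assay_id": assay_id, "run": run,
                "instance": inst, "ac50_M": fit.ac50, "hill_coef": fit.hill,
                "top": fit.top, "bottom": fit.bottom, "r2": fit.r2,
                "converged": fit.converged, "direction": fit.direction,
                "curve_class": klass, "efficacy": efficacy(fit),
                "max_abs_resp": float(np.max(np.abs(y[ok]))),
            })
    return pd.DataFrame(rows)
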