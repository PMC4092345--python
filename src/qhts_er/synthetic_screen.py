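"""In-silico qHTS screen with known ground truth.

Generates a Tox21-style compound library (full and partial agonists,
antagonists, cytotoxic and autofluorescent artifact compounds, selective
modulators, inactives), 512-bit structural fingerprints organized into
families, reference-activity and binding-affinity (logRBA) labels, and raw
plate readouts for nine assay channels screened as three independent runs
with permuted well positions.

The plate design mirrors qHTS practice: each compound is titrated across a
15-point geometric concentration series (one concentration per plate, so a
titration spans 15 plates read at the same well position), every plate
carries a 16-point positive-control titration in duplicate plus negative
controls, and a configurable number of library compounds (default 88) are
plated twice per run as intra-plate duplicates.

Raw signal model per channel: a background level, a control window (S/B
fold), the compound's Hill-shaped effect on the normalized scale mapped back
to raw units, multiplicative cytotoxicity coupling on cell-based reporter
channels, and a concentration-proportional autofluorescence offset on
fluorescent channels. Noise is multiplicative log-normal per well plus a
per-plate random effect and a small additive term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import (
    ALL_ASSAYS,
    ASSAY_PARAMS,
    AUTOFLUOR_CHANNELS_FOR,
    platform_of,
)
from .config import ConfigurationError, NoiseModel, ScreenConfig, TRUTH_CLASSES

#: reference-set composition: 3 strong, 1 strong-moderate, 11 moderate
#: (6 of them antagonists), 15 weak, 4 very weak, 5 negative = 39
REFERENCE_COMPOSITION = {
    "strong": 3,
    "strong_moderate": 1,
    "moderate": 5,
    "moderate_antagonist": 6,
    "weak": 15,
    "very_weak": 4,
    "negative": 5,
}

E2_AC50 = 3.0e-10  # potency scale anchor for the logRBA model


class SizingError(ValueError):
    """Raised when the library does not fit the configured plate geometry."""


@dataclass
class CompoundRecord:
    """One library member with its full ground truth."""

    compound_id: str
    truth_class: str
    #: per-assay normalized-scale truth: assay -> dict(ac50, efficacy, hill);
    #: efficacy is signed percent activity (negative = inhibition)
    channel_truth: dict = field(default_factory=dict)
    cytotox_ac50: float | None = None
    cytotox_hill: float = 2.0
    autofluor_channels: tuple = ()
    autofluor_strength: float = 0.0
    log_rba: float | None = None
    reference_label: str = "none"
    fingerprint: np.ndarray | None = None
    family_id: int = -1
    is_duplicate_control: bool = False


@dataclass
class Titration:
    """One (compound, assay, run) concentration/response series."""

    compound_id: str
    assay_id: str
    run_index: int
    concentrations: np.ndarray
    signal: np.ndarray
    instance: int = 0


def concentration_grid(
    config_or_n: ScreenConfig | int,
    c_min: float | None = None,
    c_max: float | None = None,
) -> np.ndarray:
    """Geometric concentration series between the titration endpoints."""
    if isinstance(config_or_n, ScreenConfig):
        n, lo, hi = config_or_n.n_concentrations, config_or_n.c_min, config_or_n.c_max
    else:
        n, lo, hi = config_or_n, c_min, c_max
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    if not 0 < lo < hi:
        raise ValueError("require 0 < c_min < c_max")
    return np.geomspace(lo, hi, n)


def hill(c: np.ndarray, ac50: float, slope: float) -> np.ndarray:
    """Fractional Hill occupancy, 0 at c=0 rising to 1."""
    c = np.asarray(c, dtype=float)
    return 1.0 / (1.0 + (ac50 / c) ** slope)


# --------------------------------------------------------------------------
# library generation
# --------------------------------------------------------------------------

def _draw_potency(rng: np.random.Generator, cfg: ScreenConfig, weak_tail: bool = True) -> float:
    """AC50 for an active: mostly well inside the grid so curves complete,
    with a 10% weak tail whose upper asymptote falls outside the range."""
    lo, hi = 5.0 * cfg.c_min, cfg.c_max / 20.0
    if weak_tail and rng.random() < 0.10:
        lo, hi = cfg.c_max / 20.0, cfg.c_max / 3.0
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _platform_jitter(rng: np.random.Generator) -> float:
    return float(10 ** rng.normal(0.0, 0.1))


def _agonist_channels(rng, cfg, record, efficacy, platforms=("bla", "luc")) -> None:
    """Fill agonist-mode truth and the displacement effect it causes in
    antagonist mode (a partial agonist pulls the pre-stimulated signal toward
    its own efficacy level)."""
    base_ac50 = _draw_potency(rng, cfg)
    slope = float(rng.uniform(0.9, 2.2))
    stim = 100.0 * cfg.stimulation_fraction
    for plat in platforms:
        ac50 = base_ac50 * _platform_jitter(rng)
        record.channel_truth[f"{plat}_agonist"] = {
            "ac50": ac50, "efficacy": efficacy, "hill": slope,
        }
        displaced = (efficacy - stim) / cfg.stimulation_fraction
        record.channel_truth[f"{plat}_antagonist"] = {
            "ac50": ac50, "efficacy": displaced, "hill": slope,
        }


def _antagonist_channels(rng, cfg, record, inhibition, platforms=("bla", "luc")) -> None:
    base_ac50 = _draw_potency(rng, cfg)
    slope = float(rng.uniform(0.9, 2.2))
    for plat in platforms:
        record.channel_truth[f"{plat}_antagonist"] = {
            "ac50": base_ac50 * _platform_jitter(rng),
            "efficacy": -inhibition,
            "hill": slope,
        }


def _cytotox_channels(rng, cfg, record) -> None:
    """Cytotoxicity kills the reporter signal in every cell-based channel:
    full loss in the viability readout, over-suppression past -100% in
    antagonist mode (dead wells fall below the unstimulated baseline), and
    partial suppression of the agonist-mode baseline."""
    record.cytotox_ac50 = float(
        np.exp(rng.uniform(np.log(10.0 * cfg.c_min), np.log(cfg.c_max / 10.0)))
    )
    record.cytotox_hill = float(rng.uniform(1.2, 2.5))


def _assign_truth(rng: np.random.Generator, cfg: ScreenConfig, record: CompoundRecord) -> None:
    cls = record.truth_class
    if cls == "full_agonist":
        eff = float(np.clip(rng.normal(100.0, 12.0), 85.0, 130.0))
        _agonist_channels(rng, cfg, record, eff)
    elif cls == "partial_agonist":
        eff = float(rng.uniform(30.0, 60.0))
        _agonist_channels(rng, cfg, record, eff)
    elif cls == "antagonist":
        _antagonist_channels(rng, cfg, record, float(rng.uniform(70.0, 110.0)))
    elif cls == "cytotoxic_only":
        _cytotox_channels(rng, cfg, record)
    elif cls == "autofluorescent":
        record.autofluor_strength = float(rng.uniform(0.5, 1.2))
        r = rng.random()
        if r < 0.70:
            record.autofluor_channels = ("blue", "green")
        elif r < 0.85:
            record.autofluor_channels = ("green",)
        else:
            record.autofluor_channels = ("red",)
    elif cls == "selective_modulator":
        # flavonoid-like: agonist through the full-length receptor (luc),
        # antagonist through the isolated ligand-binding domain (bla)
        _agonist_channels(rng, cfg, record, float(rng.uniform(40.0, 100.0)),
                          platforms=("luc",))
        _antagonist_channels(rng, cfg, record, float(rng.uniform(60.0, 100.0)),
                             platforms=("bla",))
    elif cls != "inactive":  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown truth class {cls!r}")


def _primary_potency(record: CompoundRecord) -> float | None:
    """The potency that a binding assay would track (agonist AC50 if present,
    else antagonist AC50), geometric-averaged across platforms."""
    for mode in ("agonist", "antagonist"):
        vals = [
            t["ac50"]
            for a, t in record.channel_truth.items()
            if a.endswith(mode) and abs(t["efficacy"]) >= 20.0
        ]
        if vals:
            return float(np.exp(np.mean(np.log(vals))))
    return None


def _partition_families(rng, indices: list[int], mean_size: float) -> list[list[int]]:
    """Split a class's compounds into structural families of random size."""
    indices = list(indices)
    rng.shuffle(indices)
    families, i = [], 0
    while i < len(indices):
        size = 1 + int(rng.poisson(max(mean_size - 1.0, 0.0)))
        families.append(indices[i : i + size])
        i += size
    return families


def _assign_reference_labels(rng, cfg, library: list[CompoundRecord]) -> None:
    """Mark a 39-compound reference set with expert-style potency classes,
    consistent with the underlying truth (strong = most potent agonists,
    moderate antagonists = true antagonists, negatives = inactives)."""
    by_class: dict[str, list[CompoundRecord]] = {}
    for rec in library:
        by_class.setdefault(rec.truth_class, []).append(rec)

    def agonist_ac50(rec):
        t = rec.channel_truth.get("luc_agonist") or rec.channel_truth.get("bla_agonist")
        return t["ac50"] if t else np.inf

    agonists = sorted(
        by_class.get("full_agonist", []) + by_class.get("partial_agonist", []),
        key=agonist_ac50,
    )
    antagonists = list(by_class.get("antagonist", []))
    inactives = list(by_class.get("inactive", []))

    def take(pool, k):
        taken = [r for r in pool[:k]]
        del pool[: len(taken)]
        return taken

    comp = REFERENCE_COMPOSITION
    for rec in take(agonists, comp["strong"]):
        rec.reference_label = "strong"
    for rec in take(agonists, comp["strong_moderate"]):
        rec.reference_label = "strong_moderate"
    for rec in take(agonists, comp["moderate"]):
        rec.reference_label = "moderate"
    for rec in take(antagonists, comp["moderate_antagonist"]):
        rec.reference_label = "moderate_antagonist"
    # weak / very weak: least potent agonists
    weak_pool = agonists[::-1]
    for rec in take(weak_pool, comp["weak"]):
        rec.reference_label = "weak"
    for rec in take(weak_pool, comp["very_weak"]):
        rec.reference_label = "very_weak"
    rng.shuffle(inactives)
    for rec in take(inactives, comp["negative"]):
        rec.reference_label = "negative"


def _assign_binding(rng, cfg, library: list[CompoundRecord]) -> None:
    for rec in library:
        covered = rec.reference_label != "none" or rng.random() < cfg.binding_coverage
        if not covered:
            continue
        potency = _primary_potency(rec)
        if potency is not None:
            # functional potency overstates binding affinity (receptor
            # reserve / amplification), hence the sub-unit slope
            rec.log_rba = float(
                0.75 * np.log10(E2_AC50 / potency) + rng.normal(0.0, 0.3)
            )
        else:
            # non-binders: below the 1/1000-of-estradiol activity floor
            rec.log_rba = float(rng.uniform(-6.0, -3.05))


def _select_duplicates(rng, cfg, library: list[CompoundRecord]) -> None:
    """Stratified duplicate-control pick, weighted toward actives so the
    duplicate AC50 correlation is estimated from a usable number of pairs."""
    quota = {
        "full_agonist": 25, "partial_agonist": 15, "antagonist": 15,
        "selective_modulator": 5, "cytotoxic_only": 5, "autofluorescent": 3,
        "inactive": 20,
    }
    scale = cfg.n_duplicates / sum(quota.values())
    by_class: dict[str, list[CompoundRecord]] = {}
    for rec in library:
        by_class.setdefault(rec.truth_class, []).append(rec)
    chosen: list[CompoundRecord] = []
    for cls in TRUTH_CLASSES:
        pool = list(by_class.get(cls, []))
        rng.shuffle(pool)
        want = int(round(quota.get(cls, 0) * scale))
        chosen.extend(pool[:want])
    # top up / trim to the exact configured count
    if len(chosen) < cfg.n_duplicates:
        seen = {id(r) for r in chosen}
        rest = [r for r in library if id(r) not in seen]
        rng.shuffle(rest)
        chosen.extend(rest[: cfg.n_duplicates - len(chosen)])
    for rec in chosen[: cfg.n_duplicates]:
        rec.is_duplicate_control = True


def generate_library(config: ScreenConfig) -> list[CompoundRecord]:
    """Deterministically generate the compound library for a config."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    classes = [c for c in TRUTH_CLASSES if c in config.mixture]
    probs = np.array([config.mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(len(classes), size=config.n_compounds, p=probs)

    library = [
        CompoundRecord(compound_id=f"C{i:05d}", truth_class=classes[k])
        for i, k in enumerate(drawn)
    ]
    for rec in library:
        _assign_truth(rng, config, rec)

    # ---- structural families; two planted families anchor the enrichment
    # analysis (one pure agonist family, one antagonist family half-mixed
    # with cytotoxic members that confound the antagonist-mode readout)
    by_class: dict[str, list[int]] = {c: [] for c in TRUTH_CLASSES}
    for i, rec in enumerate(library):
        by_class[rec.truth_class].append(i)

    families: list[list[int]] = []
    n_ag_plant = min(config.planted_agonist_family, len(by_class["full_agonist"]))
    if n_ag_plant:
        families.append(by_class["full_agonist"][:n_ag_plant])
        by_class["full_agonist"] = by_class["full_agonist"][n_ag_plant:]
    half = config.planted_confound_family // 2
    n_ant = min(half, len(by_class["antagonist"]))
    n_cyt = min(half, len(by_class["cytotoxic_only"]))
    if n_ant and n_cyt:
        families.append(by_class["antagonist"][:n_ant] + by_class["cytotoxic_only"][:n_cyt])
        by_class["antagonist"] = by_class["antagonist"][n_ant:]
        by_class["cytotoxic_only"] = by_class["cytotoxic_only"][n_cyt:]
    for cls in TRUTH_CLASSES:
        families.extend(_partition_families(rng, by_class[cls], config.family_size_mean))

    for fam_id, members in enumerate(families):
        proto = rng.random(config.fingerprint_bits) < config.fingerprint_density
        for i in members:
            flips = rng.random(config.fingerprint_bits) < config.bit_flip_rate
            library[i].fingerprint = (proto ^ flips).astype(np.uint8)
            library[i].family_id = fam_id

    _assign_reference_labels(rng, config, library)
    _assign_binding(rng, config, library)
    _select_duplicates(rng, config, library)
    return library


# --------------------------------------------------------------------------
# response model
# --------------------------------------------------------------------------

def _is_fluorescent(assay_id: str, record: CompoundRecord) -> bool:
    plat = platform_of(assay_id)
    if plat == "autofluor":
        return assay_id.split("_")[1] in record.autofluor_channels
    channels = AUTOFLUOR_CHANNELS_FOR.get(plat, ())
    return bool(set(channels) & set(record.autofluor_channels))


def mean_signal(record: CompoundRecord, assay_id: str, concentrations: np.ndarray) -> np.ndarray:
    """Noise-free raw signal for one compound in one channel."""
    p = ASSAY_PARAMS[assay_id]
    c = np.asarray(concentrations, dtype=float)
    span = p.background * (p.s_b - 1.0)

    if p.kind == "activation":
        ref, scale = p.background, span
    else:  # stimulated (antagonist mode) or untreated (viability) level
        ref, scale = p.top_signal, span

    truth = record.channel_truth.get(assay_id)
    effect = np.zeros_like(c)
    if truth is not None:
        effect = (truth["efficacy"] / 100.0) * hill(c, truth["ac50"], truth["hill"])

    if assay_id.endswith("viability"):
        if record.cytotox_ac50 is not None:
            effect = -hill(c, record.cytotox_ac50, record.cytotox_hill)
        s = ref + scale * effect
    else:
        s = ref + scale * effect
        # dead cells lose reporter signal in every cell-based channel
        if record.cytotox_ac50 is not None and platform_of(assay_id) != "autofluor":
            s = s * (1.0 - hill(c, record.cytotox_ac50, record.cytotox_hill))

    if record.autofluor_strength and _is_fluorescent(assay_id, record):
        c_top = c.max()
        s = s + record.autofluor_strength * span * (c / c_top)
    return s


def simulate_response(
    record: CompoundRecord,
    assay_id: str,
    concentrations: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> Titration:
    """Raw titration for one compound in one channel (no plate effect)."""
    mean = mean_signal(record, assay_id, concentrations)
    s = mean * np.exp(rng.normal(0.0, noise.multiplicative_sd, mean.shape))
    s = s + rng.normal(0.0, noise.additive_sd, mean.shape)
    return Titration(
        compound_id=record.compound_id,
        assay_id=assay_id,
        run_index=1,
        concentrations=np.asarray(concentrations, dtype=float),
        signal=np.maximum(s, 1e-6),
    )


# --------------------------------------------------------------------------
# plate assembly
# --------------------------------------------------------------------------

def _control_grid(assay_id: str) -> np.ndarray:
    p = ASSAY_PARAMS[assay_id]
    return np.geomspace(p.control_ac50 / 3000.0, p.control_ac50 * 300.0, 16)


def control_mean_signal(assay_id: str, concentrations: np.ndarray) -> np.ndarray:
    """Noise-free positive-control titration signal."""
    p = ASSAY_PARAMS[assay_id]
    h = hill(concentrations, p.control_ac50, p.control_hill)
    if p.kind == "activation":
        return p.background + (p.top_signal - p.background) * h
    return p.top_signal - (p.top_signal - p.background) * h


def _reserved_columns(cfg: ScreenConfig) -> int:
    need = 32 + 16  # 2x16 positive-control titration + >=16 negative controls
    ncols = int(np.ceil(need / cfg.plate_rows))
    # round up so negative controls fill at least 16 wells
    while cfg.plate_rows * ncols - 32 < 16:
        ncols += 1
    return ncols


def _well_name(row: int, col: int) -> str:
    r1, r2 = divmod(row, 26)
    prefix = (chr(ord("A") + r1 - 1) if r1 else "") + chr(ord("A") + r2)
    return f"{prefix}{col + 1:02d}"


def assemble_runs(library: list[CompoundRecord], config: ScreenConfig) -> pd.DataFrame:
    """Raw readouts for all channels, runs, and plates as one long table.

    Columns: plate_id, assay_id, run, plate_set, conc_idx, well, row, col,
    role, compound_id, instance, concentration_M, signal.
    """
    if not library:
        raise ValueError("library is empty")
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    grid = concentration_grid(cfg)
    n_conc = len(grid)

    n_res = _reserved_columns(cfg)
    capacity = cfg.plate_rows * (cfg.plate_cols - n_res)
    if capacity < 2:
        raise SizingError("plate geometry leaves no sample wells")

    # sample list: every compound once, duplicates twice; pair members kept
    # adjacent so both copies land on the same plate set
    samples: list[tuple[int, int]] = []
    for i, rec in enumerate(library):
        samples.append((i, 0))
        if rec.is_duplicate_control:
            samples.append((i, 1))
    chunks = [samples[i : i + capacity] for i in range(0, len(samples), capacity)]

    # per-run well permutations (shared by all assays within a run)
    sample_slots = [
        (r, c) for c in range(n_res, cfg.plate_cols) for r in range(cfg.plate_rows)
    ]
    run_perms = {
        (run, ci): rng.permutation(len(chunk))
        for run in range(1, cfg.n_runs + 1)
        for ci, chunk in enumerate(chunks)
    }

    arrays = _response_arrays(library)
    frames = []
    for assay_id in ALL_ASSAYS:
        p = ASSAY_PARAMS[assay_id]
        ctrl_grid = _control_grid(assay_id)
        ctrl_mean = control_mean_signal(assay_id, ctrl_grid)
        neg_level = p.top_signal if p.kind == "inhibition" else p.background
        for run in range(1, cfg.n_runs + 1):
            for ci, chunk in enumerate(chunks):
                comp_idx = np.array([i for i, _ in chunk])
                instances = np.array([inst for _, inst in chunk])
                mean = _mean_matrix(arrays, assay_id, comp_idx, grid)  # (n, n_conc)
                perm = run_perms[(run, ci)]
                rows_ = np.array([sample_slots[j][0] for j in perm])
                cols_ = np.array([sample_slots[j][1] for j in perm])
                for k in range(n_conc):
                    plate_id = f"{assay_id}_r{run}_s{ci}_c{k:02d}"
                    plate_eff = float(np.exp(rng.normal(0.0, cfg.noise.plate_sd)))
                    n_s = len(chunk)
                    sig = mean[:, k] * plate_eff
                    # control wells: 32 pos titration + negatives
                    n_neg = cfg.plate_rows * n_res - 32
                    pos_sig = np.tile(ctrl_mean, 2) * plate_eff
                    neg_sig = np.full(n_neg, neg_level) * plate_eff
                    allsig = np.concatenate([sig, pos_sig, neg_sig])
                    allsig = allsig * np.exp(
                        rng.normal(0.0, cfg.noise.multiplicative_sd, allsig.shape)
                    )
                    allsig = np.maximum(
                        allsig + rng.normal(0.0, cfg.noise.additive_sd, allsig.shape),
                        1e-6,
                    )
                    ctrl_slots = [
                        (r, c) for c in range(n_res) for r in range(cfg.plate_rows)
                    ]
                    pos_rc = ctrl_slots[:32]
                    neg_rc = ctrl_slots[32 : 32 + n_neg]
                    frames.append(pd.DataFrame({
                        "plate_id": plate_id,
                        "assay_id": assay_id,
                        "run": run,
                        "plate_set": ci,
                        "conc_idx": (
                            [k] * n_s + list(range(16)) * 2 + [-1] * n_neg
                        ),
                        "row": np.concatenate([rows_, [rc[0] for rc in pos_rc],
                                               [rc[0] for rc in neg_rc]]),
                        "col": np.concatenate([cols_, [rc[1] for rc in pos_rc],
                                               [rc[1] for rc in neg_rc]]),
                        "role": ["sample"] * n_s + ["pos"] * 32 + ["neg"] * n_neg,
                        "compound_id": (
                            [library[i].compound_id for i in comp_idx]
                            + [""] * (32 + n_neg)
                        ),
                        "instance": np.concatenate([instances, np.zeros(32 + n_neg, int)]),
                        "concentration_M": np.concatenate(
                            [np.full(n_s, grid[k]), np.tile(ctrl_grid, 2),
                             np.zeros(n_neg)]
                        ),
                        "signal": allsig,
                    }))
    raw = pd.concat(frames, ignore_index=True)
    raw["well"] = [
        _well_name(r, c) for r, c in zip(raw["row"].to_numpy(), raw["col"].to_numpy())
    ]
    return raw


def _response_arrays(library: list[CompoundRecord]) -> dict:
    """Vectorized per-compound response parameters for every channel."""
    n = len(library)
    out: dict = {"n": n}
    out["cyto_ac50"] = np.array(
        [r.cytotox_ac50 if r.cytotox_ac50 is not None else np.nan for r in library]
    )
    out["cyto_hill"] = np.array([r.cytotox_hill for r in library])
    for assay_id in ALL_ASSAYS:
        eff = np.zeros(n)
        ac50 = np.full(n, np.nan)
        slope = np.ones(n)
        afu = np.zeros(n)
        for i, rec in enumerate(library):
            t = rec.channel_truth.get(assay_id)
            if t is not None:
                eff[i], ac50[i], slope[i] = t["efficacy"], t["ac50"], t["hill"]
            if rec.autofluor_strength and _is_fluorescent(assay_id, rec):
                afu[i] = rec.autofluor_strength
        out[assay_id] = (eff, ac50, slope, afu)
    return out


def _mean_matrix(arrays: dict, assay_id: str, comp_idx: np.ndarray,
                 grid: np.ndarray) -> np.ndarray:
    p = ASSAY_PARAMS[assay_id]
    eff, ac50, slope, afu = (a[comp_idx] for a in arrays[assay_id])
    span = p.background * (p.s_b - 1.0)
    ref = p.top_signal if p.kind == "inhibition" else p.background
    c = grid[None, :]
    with np.errstate(invalid="ignore"):
        h = np.where(
            np.isnan(ac50[:, None]), 0.0,
            1.0 / (1.0 + (ac50[:, None] / c) ** slope[:, None]),
        )
    s = ref + span * (eff[:, None] / 100.0) * h

    if assay_id.endswith("viability"):
        ca, ch = arrays["cyto_ac50"][comp_idx], arrays["cyto_hill"][comp_idx]
        with np.errstate(invalid="ignore"):
            hv = np.where(np.isnan(ca[:, None]), 0.0,
                          1.0 / (1.0 + (ca[:, None] / c) ** ch[:, None]))
        s = ref - (ref - p.background) * hv
    elif platform_of(assay_id) != "autofluor":
        ca, ch = arrays["cyto_ac50"][comp_idx], arrays["cyto_hill"][comp_idx]
        with np.errstate(invalid="ignore"):
            hv = np.where(np.isnan(ca[:, None]), 0.0,
                          1.0 / (1.0 + (ca[:, None] / c) ** ch[:, None]))
        s = s * (1.0 - hv)

    s = s + afu[:, None] * span * (c / grid.max())
    return s


# --------------------------------------------------------------------------
# ground truth / export
# --------------------------------------------------------------------------

def library_frame(library: list[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for rec in library:
        rows.append({
            "compound_id": rec.compound_id,
            "truth_class": rec.truth_class,
            "cytotox_ac50": rec.cytotox_ac50,
            "autofluor_channels": "|".join(rec.autofluor_channels),
            "autofluor_strength": rec.autofluor_strength,
            "log_rba": rec.log_rba,
            "reference_label": rec.reference_label,
            "family_id": rec.family_id,
            "is_duplicate_control": rec.is_duplicate_control,
        })
    return pd.DataFrame(rows)


def truth_table(library: list[CompoundRecord]) -> pd.DataFrame:
    """Long table of per-channel generating parameters."""
    rows = []
    for rec in library:
        for assay_id, t in rec.channel_truth.items():
            rows.append({
                "compound_id": rec.compound_id,
                "assay_id": assay_id,
                "true_ac50": t["ac50"],
                "true_efficacy": t["efficacy"],
                "true_hill": t["hill"],
            })
    return pd.DataFrame(rows, columns=[
        "compound_id", "assay_id", "true_ac50", "true_efficacy", "true_hill",
    ])


def fingerprint_frame(library: list[CompoundRecord]) -> pd.DataFrame:
    mat = np.stack([rec.fingerprint for rec in library])
    df = pd.DataFrame(mat, columns=[f"b{i}" for i in range(mat.shape[1])])
    df.insert(0, "compound_id", [rec.compound_id for rec in library])
    return df


def write_screen(outdir: str | Path, library: list[CompoundRecord],
                 raw: pd.DataFrame, config: ScreenConfig) -> dict[str, Path]:
    """Persist library, fingerprints, raw readouts and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": outdir / "library.csv",
        "fingerprints": outdir / "fingerprints.csv",
        "raw": outdir / "raw.csv",
        "truth": outdir / "ground_truth.json",
    }
    library_frame(library).to_csv(paths["library"], index=False)
    fingerprint_frame(library).to_csv(paths["fingerprints"], index=False)
    raw.to_csv(paths["raw"], index=False)
    truth = {
        rec.compound_id: {
            "truth_class": rec.truth_class,
            "channels": rec.channel_truth,
            "cytotox_ac50": rec.cytotox_ac50,
            "log_rba": rec.log_rba,
            "reference_label": rec.reference_label,
            "family_id": rec.family_id,
        }
        for rec in library
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
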