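"""End-to-end orchestration: simulate -> normalize -> fit -> call ->
evaluate -> enrich, with plain-file handoff between stages.

Every stage reads and writes CSV/JSON in one output directory, so any
stage can be re-run in isolation or swapped for a real-data import with
the same column contract. ``run_all`` executes the full chain and emits a
manifest with the config hash, seed, per-file SHA-256 digests and stage
timings; identical config and seed reproduce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_call import call_screen, duplicate_concordance, outcome_distribution, replicate_calls
from .assays import MODE_ASSAYS
from .config import ScreenConfig
from .curve_fit import fit_screen
from .enrichment import endpoint_enrichment, enrichment_matrix, train_som
from .evaluation import binding_concordance, reference_performance, reproducibility_summary
from .normalize_qc import control_sd_fold, normalize_screen
from .synthetic_screen import assemble_runs, generate_library, truth_table, write_screen

#: truth classes that a perfect reviewer would call active, per mode
_TRUTH_ACTIVE = {
    "agonist": {"full_agonist", "partial_agonist", "selective_modulator"},
    "antagonist": {"antagonist", "selective_modulator"},
}


class MissingInputError(FileNotFoundError):
    """A stage input produced by an earlier stage is absent."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    def digests(self) -> dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage["files"])
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(outdir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            raise MissingInputError(
                f"required input '{name}' not found in {outdir}; run the earlier stages first"
            )
        paths.append(p)
    return paths


def _read_fits(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"curve_class": str})


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(config: ScreenConfig, outdir: Path) -> list[Path]:
    library = generate_library(config)
    raw = assemble_runs(library, config)
    paths = write_screen(outdir, library, raw, config)
    truth_table(library).to_csv(outdir / "truth_table.csv", index=False)
    return list(paths.values()) + [outdir / "truth_table.csv"]


def stage_normalize(config: ScreenConfig, outdir: Path) -> list[Path]:
    (raw_path,) = _require(outdir, "raw.csv")
    raw = pd.read_csv(raw_path)
    normalized, stats = normalize_screen(raw)
    sd_fold = control_sd_fold(stats).rename("control_ac50_sd_fold").reset_index()
    normalized.to_csv(outdir / "normalized.csv", index=False, float_format="%.6g")
    stats.to_csv(outdir / "plate_stats.csv", index=False)
    sd_fold.to_csv(outdir / "control_sd_fold.csv", index=False)
    return [outdir / "normalized.csv", outdir / "plate_stats.csv",
            outdir / "control_sd_fold.csv"]


def stage_fit(config: ScreenConfig, outdir: Path) -> list[Path]:
    (norm_path,) = _require(outdir, "normalized.csv")
    normalized = pd.read_csv(norm_path)
    fits = fit_screen(normalized, config)
    fits.to_csv(outdir / "fits.csv", index=False, float_format="%.8g")
    return [outdir / "fits.csv"]


def stage_call(config: ScreenConfig, outdir: Path) -> list[Path]:
    fit_path, norm_path, lib_path = _require(
        outdir, "fits.csv", "normalized.csv", "library.csv"
    )
    fits = _read_fits(fit_path)
    normalized = pd.read_csv(norm_path)
    library = pd.read_csv(lib_path)
    calls = call_screen(fits, normalized, config)
    reps = replicate_calls(fits)
    dups, dup_r2 = duplicate_concordance(fits, library, normalized, config)
    calls.to_csv(outdir / "calls.csv", index=False)
    reps.to_csv(outdir / "replicate_calls.csv", index=False)
    dups.to_csv(outdir / "duplicate_calls.csv", index=False)
    dup_r2.rename("ac50_r2").reset_index().to_csv(
        outdir / "duplicate_ac50_r2.csv", index=False
    )
    outcome_distribution(calls).to_csv(outdir / "outcome_distribution.csv", index=False)
    return [outdir / n for n in (
        "calls.csv", "replicate_calls.csv", "duplicate_calls.csv",
        "duplicate_ac50_r2.csv", "outcome_distribution.csv",
    )]


def truth_overrides(library: pd.DataFrame, assay_mode: str) -> dict[str, str]:
    """Review table resolving inconclusive reference calls from ground truth
    (stands in for the original study's manual expert review)."""
    active = _TRUTH_ACTIVE[assay_mode]
    ref = library[library["reference_label"] != "none"]
    return {
        row.compound_id: ("active" if row.truth_class in active else "inactive")
        for row in ref.itertuples()
    }


def stage_evaluate(config: ScreenConfig, outdir: Path) -> list[Path]:
    call_path, lib_path, rep_path = _require(
        outdir, "calls.csv", "library.csv", "replicate_calls.csv"
    )
    calls = pd.read_csv(call_path)
    library = pd.read_csv(lib_path)
    reps = pd.read_csv(rep_path)

    reference = library[library["reference_label"] != "none"][
        ["compound_id", "reference_label"]
    ]
    result: dict = {"reference": {}, "binding": {}}
    for assay_id in MODE_ASSAYS:
        mode = "antagonist" if assay_id.endswith("antagonist") else "agonist"
        sub = calls[calls["assay_id"] == assay_id]
        counts, metrics = reference_performance(sub, reference, assay_mode=mode)
        cnt_inc, met_inc = reference_performance(
            sub, reference, assay_mode=mode, mode="include_inconclusive",
            overrides=truth_overrides(library, mode),
        )
        result["reference"][assay_id] = {
            "counts": dataclasses.asdict(counts),
            "metrics": dataclasses.asdict(metrics),
            "counts_reviewed": dataclasses.asdict(cnt_inc),
            "metrics_reviewed": dataclasses.asdict(met_inc),
        }
    for platform in ("bla", "luc"):
        cc = binding_concordance(
            calls, library[["compound_id", "log_rba"]], platform
        )
        result["binding"][platform] = {
            **dataclasses.asdict(cc),
            "concordance": cc.concordance,
            "fisher_p": cc.fisher_p,
        }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    reproducibility_summary(reps).to_csv(outdir / "reproducibility.csv", index=False)
    return [outdir / "evaluation.json", outdir / "reproducibility.csv"]


def stage_enrich(config: ScreenConfig, outdir: Path) -> list[Path]:
    fp_path, call_path = _require(outdir, "fingerprints.csv", "calls.csv")
    fp = pd.read_csv(fp_path)
    calls = pd.read_csv(call_path)
    compound_ids = fp["compound_id"].tolist()
    mat = fp.drop(columns="compound_id").to_numpy(np.uint8)
    som = config.som
    model, assignments = train_som(
        mat, rows=som.rows, cols=som.cols, epochs=som.epochs,
        sigma_end=som.sigma_end, seed=config.seed,
        compounds_per_cluster=som.compounds_per_cluster, metric=som.metric,
    )
    pd.DataFrame({"compound_id": compound_ids, "cluster_id": assignments}).to_csv(
        outdir / "som_assignments.csv", index=False
    )
    table = endpoint_enrichment(
        assignments, calls, compound_ids, model.n_nodes, som.enrichment_p
    )
    table.to_csv(outdir / "cluster_enrichment.csv", index=False)
    enrichment_matrix(table).to_csv(outdir / "enrichment_matrix.csv")
    return [outdir / n for n in (
        "som_assignments.csv", "cluster_enrichment.csv", "enrichment_matrix.csv",
    )]


STAGES = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "fit": stage_fit,
    "call": stage_call,
    "evaluate": stage_evaluate,
    "enrich": stage_enrich,
}


def run_stage(name: str, config: ScreenConfig, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return STAGES[name](config, outdir)
    except MissingInputError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc


def run_all(config: ScreenConfig, outdir: str | Path) -> RunManifest:
    """Run the full pipeline and write manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.digest(), seed=config.seed, version=__version__
    )
    for name in STAGES:
        t0 = time.perf_counter()
        files = run_stage(name, config, outdir)
        manifest.stages[name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "files": {p.name: _sha256(p) for p in files},
        }
    manifest.to_json(outdir / "manifest.json")
    return manifest
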