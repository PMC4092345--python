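"""Performance scoring against reference chemicals and binding data.

Three evaluations mirror standard screening validation practice:

* reference_performance - sensitivity/specificity/accuracy of the activity
  calls against an expert-classified reference set (agonist-mode evaluation
  uses the agonist reference classes; antagonist-mode evaluation uses only
  the known antagonists plus the negatives). Inconclusive calls are either
  excluded or resolved by an explicit caller-supplied review table.
* binding_concordance - agreement of the functional calls (union of active
  agonists and antagonists per platform) with a receptor-binding assay,
  where logRBA < -3 (less than 1/1000 of estradiol's affinity) counts as
  binding-inactive. Counts are reported as concordant/discordant
  positives/negatives with overall concordance (CP+CN)/(CP+DP+CN+DN).
* reproducibility_summary - per-assay rates of the replicate categories and
  the geometric-mean AC50 fold change among active matches.

All association p-values come from the two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assays import MODE_ASSAYS

AGONIST_ACTIVE_LABELS = ("strong", "strong_moderate", "moderate", "weak", "very_weak")
ANTAGONIST_ACTIVE_LABELS = ("moderate_antagonist",)
NEGATIVE_LABELS = ("negative",)

LOG_RBA_INACTIVE_BELOW = -3.0


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "exclude_inconclusive"
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    fisher_p: float


@dataclass
class ConcordanceCounts:
    cp: int
    dp: int
    cn: int
    dn: int
    n_inconclusive: int = 0

    @property
    def concordance(self) -> float:
        total = self.cp + self.dp + self.cn + self.dn
        return (self.cp + self.cn) / total if total else float("nan")

    @property
    def fisher_p(self) -> float:
        return fisher_exact_2x2(self.cp, self.dp, self.dn, self.cn)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one.
    An empty margin makes the table degenerate; p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def performance_from_counts(counts: ConfusionCounts) -> PerformanceMetrics:
    if counts.total == 0:
        raise ValueError("no classified compounds")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return PerformanceMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / counts.total,
        fisher_p=fisher_exact_2x2(tp, fp, fn, tn),
    )


def reference_performance(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    assay_mode: str = "agonist",
    mode: str = "exclude_inconclusive",
    overrides: dict[str, str] | None = None,
) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Score one assay's calls against the reference set.

    ``calls``: one assay's rows (compound_id, outcome). ``reference``:
    compound_id + reference_label. ``assay_mode`` selects which reference
    classes count as true actives. ``overrides`` maps compound_id ->
    'active'/'inactive' for inconclusive calls reviewed manually; used only
    in include_inconclusive mode (unreviewed inconclusives stay excluded).
    """
    if assay_mode == "agonist":
        active_labels, call_active = AGONIST_ACTIVE_LABELS, "active_agonist"
    elif assay_mode == "antagonist":
        active_labels, call_active = ANTAGONIST_ACTIVE_LABELS, "active_antagonist"
    else:
        raise ValueError(f"unknown assay_mode {assay_mode!r}")
    overrides = overrides or {}

    ref = reference[reference["reference_label"].isin(active_labels + NEGATIVE_LABELS)]
    merged = ref.merge(calls[["compound_id", "outcome"]], on="compound_id", how="left")

    tp = fp = tn = fn = excluded = 0
    for row in merged.itertuples():
        truth_active = row.reference_label in active_labels
        outcome = row.outcome
        if pd.isna(outcome):
            excluded += 1
            continue
        if outcome == call_active:
            verdict = "active"
        elif outcome == "inactive":
            verdict = "inactive"
        elif mode == "include_inconclusive" and row.compound_id in overrides:
            verdict = overrides[row.compound_id]
        else:
            excluded += 1
            continue
        if verdict == "active":
            tp, fp = tp + (1 if truth_active else 0), fp + (0 if truth_active else 1)
        else:
            fn, tn = fn + (1 if truth_active else 0), tn + (0 if truth_active else 1)

    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, mode=mode, n_excluded=excluded)
    return counts, performance_from_counts(counts)


def binding_concordance(
    calls: pd.DataFrame,
    binding: pd.DataFrame,
    platform: str,
) -> ConcordanceCounts:
    """Concordance of one platform's functional calls with binding labels.

    A compound is functionally active when it is an active agonist or
    active antagonist in either mode of the platform, inactive when both
    modes call it inactive, and inconclusive (excluded, counted) otherwise.
    """
    assays = [a for a in MODE_ASSAYS if a.startswith(platform)]
    sub = calls[calls["assay_id"].isin(assays)]
    verdicts = {}
    for cid, grp in sub.groupby("compound_id"):
        outs = set(grp["outcome"])
        if outs & {"active_agonist", "active_antagonist"}:
            verdicts[cid] = "active"
        elif outs == {"inactive"}:
            verdicts[cid] = "inactive"
        else:
            verdicts[cid] = "inconclusive"

    cp = dp = cn = dn = n_inc = 0
    labeled = binding.dropna(subset=["log_rba"])
    for row in labeled.itertuples():
        verdict = verdicts.get(row.compound_id)
        if verdict is None:
            continue
        if verdict == "inconclusive":
            n_inc += 1
            continue
        bind_active = row.log_rba >= LOG_RBA_INACTIVE_BELOW
        if verdict == "active":
            cp, dp = cp + (1 if bind_active else 0), dp + (0 if bind_active else 1)
        else:
            dn, cn = dn + (1 if bind_active else 0), cn + (0 if bind_active else 1)
    return ConcordanceCounts(cp=cp, dp=dp, cn=cn, dn=dn, n_inconclusive=n_inc)


def reproducibility_summary(replicate_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-assay replicate-category percentages and mean AC50 fold change.

    The fold change is the geometric mean over active matches (1.0 = AC50s
    identical across replicates).
    """
    rows = []
    for assay_id, grp in replicate_calls.groupby("assay_id"):
        pct = grp["category"].value_counts(normalize=True) * 100.0
        folds = grp.loc[grp["category"] == "active_match", "ac50_fold_change"].dropna()
        rows.append({
            "assay_id": assay_id,
            "active_match": pct.get("active_match", 0.0),
            "inactive_match": pct.get("inactive_match", 0.0),
            "inconclusive": pct.get("inconclusive", 0.0),
            "mismatch": pct.get("mismatch", 0.0),
            "ac50_fold_change": (
                float(np.exp(np.mean(np.log(folds)))) if len(folds) else float("nan")
            ),
        })
    return pd.DataFrame(rows)
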