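"""Published benchmark counts from the Tox21 ERα 10K qHTS validation study.

These are the raw contingency counts the study reported when scoring its
two reporter-gene platforms (HEK293 ER-bla and BG1 ER-luc, agonist and
antagonist mode) against 39 expert-classified ER reference chemicals, and
when comparing the functional calls with a competitive ER binding assay.
Feeding them through :mod:`qhts_er.evaluation` reproduces the published
sensitivity/specificity/accuracy and concordance figures, which anchors
this package's metric definitions to the original analysis.

``main`` counts exclude reference chemicals whose qHTS outcome was
inconclusive; ``reviewed`` counts include them after manual review.
"""

from .evaluation import ConcordanceCounts, ConfusionCounts

#: reference-set confusion counts per assay: (tp, fp, tn, fn)
REFERENCE_COUNTS = {
    "bla_agonist": {
        "main": ConfusionCounts(tp=19, fp=0, tn=3, fn=5),
        "reviewed": ConfusionCounts(tp=28, fp=2, tn=3, fn=6, mode="include_inconclusive"),
    },
    "luc_agonist": {
        "main": ConfusionCounts(tp=26, fp=1, tn=2, fn=1),
        "reviewed": ConfusionCounts(tp=33, fp=3, tn=2, fn=1, mode="include_inconclusive"),
    },
    "bla_antagonist": {
        "main": ConfusionCounts(tp=6, fp=0, tn=4, fn=0),
        "reviewed": ConfusionCounts(tp=6, fp=1, tn=4, fn=0, mode="include_inconclusive"),
    },
    "luc_antagonist": {
        "main": ConfusionCounts(tp=6, fp=1, tn=4, fn=0),
        "reviewed": ConfusionCounts(tp=6, fp=1, tn=4, fn=0, mode="include_inconclusive"),
    },
}

#: binding-assay concordance counts per platform
BINDING_COUNTS = {
    "bla": ConcordanceCounts(cp=41, dp=24, cn=345, dn=13, n_inconclusive=169),
    "luc": ConcordanceCounts(cp=54, dp=74, cn=254, dn=1, n_inconclusive=209),
}
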